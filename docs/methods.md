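# Methods

This document describes the model implemented by `v1mgsm`, the numerical
choices made along the way, and the rationale behind the design decisions
that were not forced by the mathematics.

## 1. Model

### 1.1 Gaussian scale mixture (GSM)

A GSM random vector is `x = v · g`, where `g ~ N(0, Σ)` and `v ≥ 0` is a
scalar mixer independent of `g`. We use a Rayleigh mixer with unit scale,
`p(v) = v · exp(−v²/2)`. With this mixer the marginal density, the posterior
moments `E[1/v | x]` and `E[1/v² | x]`, and hence the posterior mean of the
Gaussian component

    E[g | x] = x · E[1/v | x]

all have closed forms in terms of the modified Bessel function of the second
kind `K_ν(λ)`, where `λ = √(xᵀ Σ⁻¹ x)` is the Mahalanobis norm of the input.
The three quantities reduce to ratios `K_{ν₁}(λ)/K_{ν₂}(λ)` at half-integer
offsets of `ν = 1 − d/2`, with `d` the dimension.

Two edge cases are handled explicitly:

* **`x → 0`.** The marginal density of a GSM is finite at the origin only
  for `d = 1` (where, with `Σ = 1`, it equals exactly `1/2`); for `d ≥ 2` it
  diverges logarithmically or polynomially. We clamp `λ` at a floor of
  `1e−12` and treat the posterior-mean gain as its (finite) `λ → 0` limit,
  so responses at exactly-zero input are zero rather than NaN.
* **Large `λ`.** `scipy.special.kve` (the exponentially scaled Bessel
  function) is accurate over an enormous range; above `λ = 1e8` we switch to
  the uniform asymptotic expansion of `log K_ν(λ)` computed directly in log
  space (`_log_kve`), which agrees with `log(kve)` to ~1e−13 relative at the
  switch point. This keeps log-likelihoods finite for inputs up to at least
  `1e12` in magnitude.

Each covariance is stored trace-normalized (`tr Σ = d`) with a separate
positive scale factor, so overall gain and correlation structure are kept
separate; the two multiply back together in every computation
(`effective_Σ = scale · Σ`). Validity (symmetry, positive definiteness) is
enforced at construction through a cached Cholesky factor.

### 1.2 Oracles

Before any closed form is trusted it is checked against a quadrature oracle:
the same moments computed by adaptive numerical integration over the mixer
(`scipy.integrate.quad` on a log-transformed axis, with explicit break
points at the integrand's peak so the adaptive subdivision cannot miss a
narrow mode). The test suite and the acceptance script both verify
agreement to 1e−6 relative error across dimensions 1–24 and input
magnitudes spanning six decades, and that the posterior weight normalizes
to 1.

### 1.3 Filter bank and response vector

Images are 40×40 grayscale patches. The feature vector has 72 dimensions:

* **Center**: 8 values — 4 orientations (0°, 45°, 90°, 135°) × 2 quadrature
  phases of an odd/even Gabor pair (13×13 kernels, σ = 3 px, spatial
  frequency 1/6 cycles/px) applied at the patch center. Kernels are
  zero-mean and unit-norm.
* **Surround**: 4 × 16 values — for each orientation, the same quadrature
  pair applied at 8 positions on a ring of radius 13 px around the center.

Layout: `[0:8]` center, then one 16-wide surround block per orientation.
The whole bank is a single 72×1600 analysis matrix, so filtering a batch is
one matrix product. The "small" test aperture (13 px, the kernel size)
drives the center filters while leaving < 5 % relative energy in the
surround; the "large" aperture is the full patch.

### 1.4 Mixture of GSMs

Following the center–surround MGSM architecture, the 72-dimensional
response is modeled as a mixture over five discrete assignments `ξ`:

* **ξ = non-shared**: the 8 center channels form one GSM with covariance
  `Σ_C`; each of the four 16-dim surround blocks forms its own independent
  GSM with covariance `Σ_Nθ`.
* **ξ = θ** (one per orientation): the center and the surround block at
  orientation θ share a single mixer — a 24-dim GSM with covariance
  `Σ_CNθ` — while the other three surround blocks remain independent GSMs.

The mixture prior `p(ξ)` has five entries. Co-sharing a mixer is the
model's formalization of "the surround participates in normalizing the
center": under a shared mixer the divisive gain `E[1/v | x]` applied to the
center is computed from the joint 24-dim input, so strong surround input at
the shared orientation suppresses the center's inferred `g`.

### 1.5 Two likelihoods: training vs. readout

The package deliberately uses two different per-component likelihoods:

* **Full generative likelihood** (used by EM, `score`, `loglik_dataset`):
  the proper density of all 72 channels under assignment ξ — the co-shared
  24-dim factor times the three remaining independent surround factors (or,
  for ξ = non-shared, the center factor times all four surround factors).
  This is the quantity EM must increase monotonically, and model comparison
  is only meaningful on a normalized joint density.
* **Truncated readout likelihood** (used by `predict_proba`, responses,
  and all tuning curves): the density of only the channels that co-share
  the mixer (24-dim for ξ = θ, 8-dim center for ξ = non-shared). The
  posterior over ξ is then `p(ξ) · GSM(x_ξ; Σ_ξ)` renormalized.

The readout truncation is what makes assignment inference express a
*competition between normalization pools* rather than a goodness-of-fit
contest over all 72 channels: a component is favored when the channels in
its pool look jointly co-assigned, irrespective of how well the unrelated
surround blocks happen to fit their own factors. Using the full likelihood
for readout would let the three untouched surround factors (48 of 72
dimensions) dominate the posterior. The two likelihoods never mix: training
and model scoring are fully generative, inference-for-response is pooled.

### 1.6 Response model

The unit studied prefers 90° (vertical), i.e. its center channel is the
odd-phase 90° Gabor. Responses to a test grating are phase-averaged over 8
grating phases:

* `mixture_response`: posterior-weighted average over ξ of the rectified
  posterior-mean Gaussian component of the preferred channel — the normal
  (pre-adaptation) readout.
* `wta_response`: the same quantity under the single maximum-posterior
  assignment (winner-take-all) — the post-adaptation readout, reflecting
  the hypothesis that adaptation commits the assignment.

Test gratings carry the same 1 % RMS pixel noise as training stimuli
(deterministic per orientation, seeded): a noiseless grating through the
filter bank can land exactly on the measure-zero silent-surround manifold
where the GSM density diverges.

## 2. Training

### 2.1 Rotation-equivariant surround pre-fit

The four surround covariances `Σ_Nθ` describe the same physical ring seen
at four orientations, so they are constrained to be rotations of one
canonical matrix: all surround blocks are permuted into a canonical frame
(rotating position and phase indices together by the orientation step),
pooled, fit as a single 16-dim GSM, and the result is carried back per
block by the inverse permutation. This quarters the parameter count of the
surround model and removes a spurious degree of freedom (independent fits
would differ only by sampling noise).

### 2.2 Two-stage EM

Stage 1 fits the equivariant `Σ_Nθ` on all data (every component's model
of a non-shared surround block is the same GSM, so this factor is common).
Stage 2 runs EM over the five-component mixture with `Σ_Nθ` frozen:

* **E-step**: responsibilities from the full generative likelihood.
* **M-step**: for each component, a responsibility-weighted GSM covariance
  update using the closed-form `E[1/v² | x]` (the expected complete-data
  sufficient statistic), with a small ridge (`1e−4` of the mean diagonal)
  and a guard that skips the update when a component's total responsibility
  vanishes.
* **Prior floor**: priors are constrained to a floor of `1e−4` by a
  water-filling projection (the KKT solution of maximizing the expected
  log-prior subject to the floor), preventing irreversible component
  death while keeping the M-step optimal within the constraint set.

Convergence is declared when the mean log-likelihood improves by less than
`1e−6` (relative); the trace is recorded and tested for monotonicity at
relative tolerance `1e−8`. Fitting is deterministic given the data and
`init_seed` — initialization draws from a dedicated `numpy` Generator and
all subsequent steps are deterministic linear algebra.

## 3. Stimuli

### 3.1 Surrogate naturalistic textures

Training uses synthetic textures rather than a natural-image corpus (the
deliverable is text-only): each patch is a sum of a few dozen randomly
placed, oriented, band-pass Gabor micro-elements with heavy-tailed
(lognormal) amplitudes, plus a small isotropic `1/f` background, globally
scaled by a lognormal contrast factor.

**What this reproduces** — the statistics the model is sensitive to:
heavy-tailed (positive excess kurtosis) filter outputs; contrast
covariation across space and orientation (the global scale factor and
element clustering), which is exactly what a shared mixer models; local
orientation coherence between center and surround (element orientations
cluster per patch), giving the co-shared components non-trivial prior mass
at every orientation, roughly balanced by symmetry.

**What it does not reproduce**: long, curved contours and occlusion
structure; the specific pairwise phase statistics of natural scenes; any
calibrated match to a particular image dataset. Absolute fitted priors and
covariances are therefore not comparable to fits on natural images — only
their symmetries and their responses to the adaptation manipulations are
meaningful. Defaults (25,000 patches; mixed ensembles of 26,000 at grating
fraction 0.3 with 5° orientation spread) are the study conditions and are
used as-is by the acceptance script.

### 3.2 Mixed adaptation ensembles

Adaptation-by-learning retrains the model from scratch on a mixture of the
same textures plus full-field adaptor gratings: orientations wrapped-normal
around the adaptor (σ = 5°), contrasts uniform on [0.2, 1], random phases,
1 % RMS pixel noise. The noise floor keeps the ensemble full-rank (ideal
sinusoids span a low-dimensional response manifold on which an ML density
fit is unbounded). Full-field adaptors are used for every paradigm — the
adaptation recipe is a property of the adapting stimulus, not of the later
test protocol; an aperture-matched variant (gratings windowed to the
center-filter diameter) remains available as an option.

## 4. Adaptation semantics

### 4.1 Prior substitution (default)

The default adapted state keeps the baseline, scene-trained covariances and
imports only the retrained mixture prior (`freeze_covariance=True`). The
retraining step exists to obtain the prior over assignments that the biased
ensemble induces; the readout model is the scene model evaluated under that
updated prior, with the likelihood unchanged. A fully retrained state
(covariances included) is available via `freeze_covariance=False` and the
`--no-freeze` CLI flag.

Empirically, adaptor-biased retraining moves the co-shared prior at the
adaptor orientation toward the grating fraction (0.3) and drives the
non-shared prior down by roughly an order of magnitude; the zero-grating
control leaves the priors balanced.

### 4.2 Covariance perturbations

Direct mechanistic manipulations operate entry-wise on the co-shared
covariance `Σ_CNθ` of the target (adaptor-orientation) component:

* **enhance_center_normalization**: multiply the center variances at the
  three non-adapted orientations by 2.0 (4.0 in the `combined_double`
  preset). The adaptor orientation's own center channels are untouched.
* **weaken_surround_normalization**: multiply the surround variances and
  all surround–center / surround–surround covariances by 0.5.

Both directions are provably SPD-safe: increasing diagonal entries adds a
positive semidefinite matrix, and scaling the surround block together with
the cross block by a common factor `s < 1` keeps the Schur complement
bounded below by `(s − s²)` times a PSD matrix. A general perturbation API
accepts arbitrary entry-wise scalings and repairs indefiniteness by
eigenvalue projection, flagging the repair in the state metadata.

A caveat recorded up front: in GSM algebra these literal manipulations
*facilitate* the affected channels — raising a channel's variance lowers
its contribution to the Mahalanobis norm, which raises `E[1/v | x]` and
hence the inferred response. The measured paradigms confirm this (the
perturbation paradigms shift tuning *away from* the adaptor). See the
package README for which qualitative phenomena reproduce and which do not.

## 5. Tuning curves and metrics

An orientation tuning curve (OTC) samples gratings at 13 relative
orientations (−90° … +90° in 15° steps) through the chosen aperture,
phase-averaged. `measure_otc` evaluates the before state with the mixture
readout and the after state with the WTA readout, then reports:

* `shift_deg`: change in preferred orientation, parabolic-interpolated
  around the grid argmax; **positive = toward the adaptor**;
* `peak_ratio`: after/before peak height;
* `response_ratio_at_adaptor`, `mean_response_ratio`;
* flat-curve flags (degenerate curves yield NaN shift rather than a
  spurious number);
* `winner_trace`: the modal winning component at each grid point.

Ten named paradigms (`v1mgsm.otc.PARADIGMS`) cover small/large aperture ×
adaptor at 0°/−45°/−90° relative, plus the four covariance-perturbation
strategies at the −45° flank.

## 6. Reproducibility

All randomness flows from explicit seeds (`numpy.random.default_rng` /
`SeedSequence`; derived seeds < 2³¹). Model states serialize to a
single-file `.npz` with a schema version; round-trips are bit-exact and a
schema mismatch raises a clear error. Two fits from the same seed are
bit-identical. The repository ships no binary fixtures; everything is
regenerated from seeds at run time.
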