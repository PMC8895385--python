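"""Adaptation as a change of model state.

Two strategies:

* **Prior update** (:func:`adapt_by_prior`): retrain the whole model from
  scratch on a mixed ensemble in which gratings near the adaptor orientation
  are over-represented.  The prior of the adaptor's co-shared component
  rises toward the grating fraction.  A ``freeze_covariance`` option keeps
  the baseline covariances and imports only the retrained priors — the
  source model's stated adaptation flow, in which only the prior differs
  between before and after while the likelihood is unchanged.

* **Covariance perturbation** (:func:`adapt_by_covariance`): directly scale
  designated variance/covariance entries of the adaptor's co-shared
  component, emulating a connectivity change between center and surround.

Perturbation presets follow the source's literal manipulations: "enhanced
suppression within CRFs" *increases* the center variances of the three
non-adapted orientations inside the adaptor's co-shared covariance, and
"weakening suppression from nCRFs" *decreases* the surround variances and
covariances (including the center-surround cross terms).  The magnitudes
are free parameters (the source gives none beyond "double-scaling"); the
presets use the minimal round factors 2x / 0.5x.  Both directions preserve
positive definiteness: raising diagonal entries adds a PSD matrix, and
scaling the surround block and cross terms by a common factor s < 1 keeps
the Schur complement positive (s*S_nn - s^2*S_nc*S_cc^-1*S_cn is bounded
below by (s - s^2) times a PSD matrix).  Perturbed matrices are not
re-normalised (the perturbation is the signal); should a perturbation ever
destroy positive definiteness the matrix is projected back by an
eigenvalue floor and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .estimator import EMConfig, FitReport, fit_mgsm
from .filterbank import CENTER_DIM, ORIENTATIONS, FilterBank
from .gsm import GSMComponent
from .state import MGSMState
from .stimuli import MixedDatasetSpec, sample_mixed_dataset

__all__ = [
    "CovariancePerturbation",
    "PERTURBATION_PRESETS",
    "adapt_by_prior",
    "adapt_by_covariance",
    "compare_states",
    "StateDiff",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariancePerturbation:
    """Declarative scaling of entries of one co-shared covariance.

    center_variance_scale
        orientation -> factor applied to that orientation's two center
        diagonal entries (both phases) inside the target component.
    surround_variance_scale
        factor on the 16 surround diagonal entries.
    surround_covariance_scale
        factor on surround off-diagonals and center-surround cross terms.
    """

    target_component: float
    center_variance_scale: Mapping[float, float] = field(default_factory=dict)
    surround_variance_scale: float = 1.0
    surround_covariance_scale: float = 1.0

    def __post_init__(self):
        if self.target_component not in ORIENTATIONS:
            raise ValueError(f"target must be one of {ORIENTATIONS}")
        for ori, fac in self.center_variance_scale.items():
            if ori not in ORIENTATIONS:
                raise ValueError(f"unknown center orientation {ori}")
            if fac <= 0:
                raise ValueError("scale factors must be positive")
        if self.surround_variance_scale <= 0 or \
                self.surround_covariance_scale <= 0:
            raise ValueError("scale factors must be positive")


def _preset(target: float, center: float | None, surround: bool):
    """Presets are defined relative to the adaptor's component; center
    factors apply to the three non-adapted orientations."""
    others = {o: center for o in ORIENTATIONS if o != target} if center else {}
    kw = {}
    if surround:
        kw = {"surround_variance_scale": 0.5, "surround_covariance_scale": 0.5}
    return CovariancePerturbation(target_component=target,
                                  center_variance_scale=others, **kw)


def PERTURBATION_PRESETS(target: float = 45.0):
    """The four covariance-update mechanisms, for an adaptor at ``target``.

    * ``enhance_center_normalization``: double the center variances of the
      three non-adapted orientations inside the adaptor's co-shared
      covariance (stronger non-specific suppression within the center).
    * ``weaken_surround_normalization``: halve the surround variances and
      the surround/cross covariances (weaker surround suppression).
    * ``combined``: both at once.
    * ``combined_double``: the center scaling applied twice (x4) on top of
      the surround change.
    """
    return {
        "enhance_center_normalization": _preset(target, 2.0, False),
        "weaken_surround_normalization": _preset(target, None, True),
        "combined": _preset(target, 2.0, True),
        "combined_double": _preset(target, 4.0, True),
    }


def adapt_by_prior(base_source, mixed_spec: MixedDatasetSpec,
                   bank: FilterBank, cfg: EMConfig | None = None,
                   freeze_covariance: bool = False,
                   baseline_state: MGSMState | None = None,
                   return_report: bool = False):
    """Retrain the model from scratch on the mixed ensemble.

    ``base_source`` overrides the texture parameters in ``mixed_spec`` when
    given (a TextureParams, or None to use the spec's own).  With
    ``freeze_covariance`` the retrained priors are imported into
    ``baseline_state`` (required), keeping its covariances.
    """
    if base_source is not None:
        mixed_spec = replace(mixed_spec, texture_params=base_source)
    if freeze_covariance and baseline_state is None:
        raise ValueError("freeze_covariance requires baseline_state")
    patches = sample_mixed_dataset(mixed_spec)
    state, report = fit_mgsm(patches, bank, cfg)
    state.metadata["adaptation"] = {
        "strategy": "prior",
        "adaptor_orientation_deg": mixed_spec.adaptor_orientation_deg,
        "grating_fraction": mixed_spec.grating_fraction,
        "n_patches": mixed_spec.n_patches,
        "rng_seed": mixed_spec.rng_seed,
        "freeze_covariance": freeze_covariance,
    }
    if freeze_covariance:
        state = baseline_state.replace_priors(state.priors)
        state.metadata["adaptation"] = {"strategy": "prior(frozen-covariance)",
                                        "adaptor_orientation_deg":
                                        mixed_spec.adaptor_orientation_deg}
    return (state, report) if return_report else state


def _spd_project(S: np.ndarray) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    floor = 1e-8 * w.max()
    if w.min() > floor:
        return S, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def adapt_by_covariance(state: MGSMState,
                        pert: CovariancePerturbation) -> MGSMState:
    """Return a copy of ``state`` with the target covariance perturbed.

    Only the declared entries change: the listed center diagonal entries
    (both phases per orientation), the surround diagonal, and the surround
    off-diagonal / center-surround cross blocks.  Priors and every other
    matrix are untouched.
    """
    target = pert.target_component
    comp = state.sigma_cn[target]
    S = comp.Sigma.copy()

    mask_center = np.zeros(24, dtype=bool)
    for ori, fac in pert.center_variance_scale.items():
        t = ORIENTATIONS.index(ori)
        for ph in (0, 1):
            S[2 * t + ph, 2 * t + ph] *= fac
    sur = slice(CENTER_DIM, 24)
    if pert.surround_variance_scale != 1.0:
        idx = np.arange(CENTER_DIM, 24)
        S[idx, idx] *= pert.surround_variance_scale
    if pert.surround_covariance_scale != 1.0:
        fac = pert.surround_covariance_scale
        off = np.ones((16, 16), dtype=bool)
        np.fill_diagonal(off, False)
        S[sur, sur] = np.where(off, S[sur, sur] * fac, S[sur, sur])
        S[:CENTER_DIM, sur] *= fac
        S[sur, :CENTER_DIM] *= fac

    S, repaired = _spd_project(S)
    if repaired:
        log.warning("perturbation of component %s broke positive "
                    "definiteness; eigenvalue floor applied", target)
    new_cn = dict(state.sigma_cn)
    # perturbed matrix keeps its raw trace: fold it into the gain so the
    # stored matrix stays trace-normalised while the effective covariance
    # carries the full perturbation
    new_cn[target] = GSMComponent(S, scale=comp.scale)
    out = MGSMState(
        prior_nonshared=state.prior_nonshared,
        prior_shared=dict(state.prior_shared),
        sigma_c=state.sigma_c,
        sigma_cn=new_cn,
        sigma_n=dict(state.sigma_n),
        metadata=dict(state.metadata),
    )
    out.metadata["covariance_perturbation"] = {
        "target": target,
        "center_variance_scale": dict(pert.center_variance_scale),
        "surround_variance_scale": pert.surround_variance_scale,
        "surround_covariance_scale": pert.surround_covariance_scale,
        "spd_repaired": bool(repaired),
    }
    return out


@dataclass(frozen=True)
class StateDiff:
    prior_delta: np.ndarray                 # after - before, component order
    covariance_delta: dict                  # name -> Frobenius norm of change

    @property
    def max_prior_gain_component(self) -> int:
        return int(np.argmax(self.prior_delta))


def compare_states(before: MGSMState, after: MGSMState) -> StateDiff:
    """Per-component prior deltas and covariance-change norms."""
    if before.sigma_c.d != after.sigma_c.d:
        raise ValueError("states have incompatible dimensions")
    deltas = after.priors - before.priors
    cov = {"nonshared": float(np.linalg.norm(
        after.sigma_c.effective_Sigma - before.sigma_c.effective_Sigma))}
    for t in ORIENTATIONS:
        cov[t] = float(np.linalg.norm(
            after.sigma_cn[t].effective_Sigma
            - before.sigma_cn[t].effective_Sigma))
        cov[f"surround_{int(t)}"] = float(np.linalg.norm(
            after.sigma_n[t].effective_Sigma
            - before.sigma_n[t].effective_Sigma))
    return StateDiff(prior_delta=deltas, covariance_delta=cov)
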