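"""V1-like oriented quadrature filter bank and response extraction.

The classical receptive field (CRF, "center") is modelled by four oriented
quadrature filter pairs (orientations 0/45/90/135 deg, even and odd phase) at
the patch center: 8 center outputs.  The non-classical receptive field
(nCRF, "surround") is 8 filter positions equally spaced on a ring around the
center; at every position the filter pair shares the orientation theta of the
surround block, giving 16 surround outputs per orientation: 72 outputs total.

Kernels are single-scale log-Gabor-like quadrature pairs (Gaussian envelope
times a sinusoidal carrier), zero-mean and unit L2 norm.  Response
extraction is a plain inner product of each kernel, placed at its position,
with the patch, so it is exactly linear in the patch.

Layout of the flat 72-vector (used by every downstream module):

* ``[0:8]``   center: (0 even, 0 odd, 45 even, 45 odd, 90 even, 90 odd,
  135 even, 135 odd)
* ``[8 + 16 t : 24 + 16 t]`` surround block for ORIENTATIONS[t]: positions
  0..7 counter-clockwise from "east", each (even, odd).

Component vectors for the mixture model: the non-shared component sees the
full 8-dim center vector; the co-shared component at theta sees the 24-dim
concatenation of the full center vector (all four orientations, matching the
covariance structure the model visualises) and the surround block at theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import ImagePatch

__all__ = [
    "ORIENTATIONS",
    "PHASES",
    "CENTER_DIM",
    "SURROUND_DIM",
    "TOTAL_DIM",
    "FilterBankParams",
    "FilterBank",
    "ResponseVector",
    "build_filterbank",
    "extract_responses",
    "response_matrix",
    "assemble_component_vectors",
    "component_matrix",
    "surround_matrix",
    "surround_canonical_permutation",
    "center_channel_index",
    "surround_slice",
]

ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
PHASES = ("even", "odd")
CENTER_DIM = 8
SURROUND_DIM = 16
TOTAL_DIM = CENTER_DIM + 4 * SURROUND_DIM  # 72


def center_channel_index(orientation_deg: float, phase: str) -> int:
    """Index of a center channel in the flat response vector."""
    t = ORIENTATIONS.index(float(orientation_deg) % 180.0)
    return 2 * t + PHASES.index(phase)


def surround_slice(orientation_deg: float) -> slice:
    t = ORIENTATIONS.index(float(orientation_deg) % 180.0)
    return slice(CENTER_DIM + SURROUND_DIM * t,
                 CENTER_DIM + SURROUND_DIM * (t + 1))


@dataclass(frozen=True)
class FilterBankParams:
    """Geometry and tuning of the bank.

    Defaults: 13-px kernels at 1/6 cycles per pixel in a 40-px patch, with
    the surround ring one kernel support away so surround kernels abut but
    do not overlap the center footprint (the "small" grating aperture equals
    the center footprint and leaves the surround silent).
    """

    patch_size: int = 40
    kernel_size: int = 13
    envelope_sigma: float = 3.0
    spatial_freq: float = 1.0 / 6.0  # cycles per pixel, the bank's peak
    ring_radius: float = 13.0

    def __post_init__(self):
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.kernel_size > self.patch_size:
            raise ValueError("kernel support exceeds patch size")
        half = self.kernel_size // 2
        c = (self.patch_size - 1) / 2.0
        reach = self.ring_radius + half
        if c - reach < 0 or c + reach > self.patch_size - 1:
            raise ValueError(
                "surround ring does not fit inside the patch: "
                f"radius {self.ring_radius} + half-support {half} "
                f"vs patch {self.patch_size}"
            )


def _gabor(kernel_size: int, sigma: float, freq: float,
           orientation_deg: float, phase: str) -> np.ndarray:
    half = kernel_size // 2
    rows, cols = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    theta = np.deg2rad(orientation_deg)
    s = rows * np.cos(theta) + cols * np.sin(theta)
    env = np.exp(-(rows**2 + cols**2) / (2.0 * sigma**2))
    carrier = np.cos if phase == "even" else np.sin
    k = env * carrier(2.0 * np.pi * freq * s)
    k -= k.mean()  # band-pass: remove the DC leak of the even kernel
    return k / np.linalg.norm(k)


class FilterBank:
    """Kernels plus placement geometry; build with :func:`build_filterbank`."""

    def __init__(self, params: FilterBankParams):
        self.params = params
        n = params.patch_size
        half = params.kernel_size // 2
        self.center_position = ((n - 1) // 2, (n - 1) // 2)
        self.kernels = {
            (ori, ph): _gabor(params.kernel_size, params.envelope_sigma,
                              params.spatial_freq, ori, ph)
            for ori in ORIENTATIONS for ph in PHASES
        }
        # 8 surround positions, 45-degree steps counter-clockwise from east
        cy, cx = self.center_position
        self.surround_positions = []
        for k in range(8):
            ang = np.deg2rad(45.0 * k)
            dr = int(round(-params.ring_radius * np.sin(ang)))
            dc = int(round(params.ring_radius * np.cos(ang)))
            self.surround_positions.append((cy + dr, cx + dc))
        # dense (72, patch_size^2) analysis matrix: row = kernel at position
        M = np.zeros((TOTAL_DIM, n * n))
        for ori_i, ori in enumerate(ORIENTATIONS):
            for ph_i, ph in enumerate(PHASES):
                M[2 * ori_i + ph_i] = self._placed(
                    self.kernels[(ori, ph)], self.center_position).ravel()
        for t, ori in enumerate(ORIENTATIONS):
            base = CENTER_DIM + SURROUND_DIM * t
            for p, pos in enumerate(self.surround_positions):
                for ph_i, ph in enumerate(PHASES):
                    M[base + 2 * p + ph_i] = self._placed(
                        self.kernels[(ori, ph)], pos).ravel()
        self._analysis = M

    def _placed(self, kernel: np.ndarray, pos: tuple[int, int]) -> np.ndarray:
        n = self.params.patch_size
        half = self.params.kernel_size // 2
        canvas = np.zeros((n, n))
        r, c = pos
        canvas[r - half:r + half + 1, c - half:c + half + 1] = kernel
        return canvas

    @property
    def analysis_matrix(self) -> np.ndarray:
        """(72, npix) matrix whose product with a flattened patch gives the
        flat response vector."""
        return self._analysis

    @property
    def small_aperture_diameter(self) -> float:
        """Diameter of the center-filter footprint (the 'small' grating)."""
        return float(self.params.kernel_size)

    def kernel_grid(self) -> np.ndarray:
        """All kernels tiled into one image, for visual inspection."""
        ks = self.params.kernel_size
        grid = np.zeros((2 * ks + 1, 4 * ks + 3))
        for i, ori in enumerate(ORIENTATIONS):
            for j, ph in enumerate(PHASES):
                grid[j * (ks + 1):j * (ks + 1) + ks,
                     i * (ks + 1):i * (ks + 1) + ks] = self.kernels[(ori, ph)]
        return grid


@dataclass(frozen=True)
class ResponseVector:
    """Center and surround responses of one patch."""

    flat: np.ndarray  # shape (72,)

    def __post_init__(self):
        v = np.asarray(self.flat, dtype=float)
        if v.shape != (TOTAL_DIM,):
            raise ValueError(f"expected shape ({TOTAL_DIM},), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite responses")
        object.__setattr__(self, "flat", v)

    @property
    def c(self) -> np.ndarray:
        return self.flat[:CENTER_DIM]

    def n(self, orientation_deg: float) -> np.ndarray:
        return self.flat[surround_slice(orientation_deg)]


def build_filterbank(params: FilterBankParams | None = None) -> FilterBank:
    return FilterBank(params or FilterBankParams())


def _pixels(patch) -> np.ndarray:
    return patch.pixels if isinstance(patch, ImagePatch) else np.asarray(patch, float)


def extract_responses(patch, bank: FilterBank) -> ResponseVector:
    px = _pixels(patch)
    n = bank.params.patch_size
    if px.shape != (n, n):
        raise ValueError(f"patch shape {px.shape} does not match bank "
                         f"geometry ({n}, {n})")
    return ResponseVector(bank.analysis_matrix @ px.ravel())


def response_matrix(patches, bank: FilterBank) -> np.ndarray:
    """Batch extraction: (n_patches, 72) array."""
    P = np.stack([_pixels(p).ravel() for p in patches])
    return P @ bank.analysis_matrix.T


def assemble_component_vectors(r) -> dict:
    """Component data vectors: ``"nonshared"`` -> 8-dim center vector,
    theta -> 24-dim [center, surround_at_theta]."""
    flat = r.flat if isinstance(r, ResponseVector) else np.asarray(r, float)
    out = {"nonshared": flat[:CENTER_DIM]}
    for ori in ORIENTATIONS:
        out[ori] = np.concatenate([flat[:CENTER_DIM], flat[surround_slice(ori)]])
    return out


def component_matrix(X: np.ndarray, component) -> np.ndarray:
    """Batch version of :func:`assemble_component_vectors` for one component.

    ``component`` is ``"nonshared"`` or an orientation in ORIENTATIONS.
    """
    X = np.atleast_2d(X)
    if component == "nonshared":
        return X[:, :CENTER_DIM]
    return np.concatenate(
        [X[:, :CENTER_DIM], X[:, surround_slice(component)]], axis=1)


def surround_matrix(X: np.ndarray, orientation_deg) -> np.ndarray:
    """Batch extraction of one 16-dim surround block, (n, 16)."""
    return np.atleast_2d(X)[:, surround_slice(orientation_deg)]


def surround_canonical_permutation(orientation_deg) -> np.ndarray:
    """Index permutation mapping a surround block into the canonical frame.

    Rotating a patch by ``-orientation_deg`` carries the surround block at
    that orientation onto the block at 0 deg while shifting the ring
    position index by ``orientation_deg / 45`` (positions are spaced 45 deg
    counter-clockwise).  ``block[:, perm]`` is the block expressed in the
    canonical (orientation-0) frame; a canonical 16x16 covariance ``S`` is
    carried back to the block's own frame by
    ``out[np.ix_(perm, perm)] = S``.
    """
    t = ORIENTATIONS.index(float(orientation_deg) % 180.0)
    perm = np.empty(SURROUND_DIM, dtype=int)
    for p in range(8):
        src = (p + t) % 8
        perm[2 * p] = 2 * src
        perm[2 * p + 1] = 2 * src + 1
    return perm
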