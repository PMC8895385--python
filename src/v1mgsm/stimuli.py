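"""Stimulus and training-ensemble generation.

Three input sources, so the whole model is testable without downloads:

* sinusoidal gratings (small aperture = classical-receptive-field footprint,
  or full patch), the stimuli of orientation-adaptation experiments;
* a "natural surrogate" texture generator: spatially correlated 1/f noise
  with a per-patch multiplicative mixer, emulating the orientation-isotropic,
  heavy-tailed, center-surround-dependent statistics of natural image patches;
* optional external grayscale images (PNG/TIFF/PGM) via Pillow.

Orientation convention (used everywhere in the package): 0 deg = horizontal
grating stripes, angles increase counter-clockwise, taken modulo 180 deg.
All patches are zero-mean luminance ("mid-gray" maps to 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GratingSpec",
    "ImagePatch",
    "TextureParams",
    "MixedDatasetSpec",
    "make_grating",
    "make_texture_patch",
    "texture_patches",
    "sample_mixed_dataset",
    "load_image_patches",
    "write_manifest",
]

DEFAULT_PATCH_SIZE = 40


@dataclass(frozen=True)
class ImagePatch:
    """A square zero-mean luminance array plus its provenance tag."""

    pixels: np.ndarray
    provenance: str = "external"  # grating | texture | external
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"patch must be square 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("patch contains non-finite values")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class GratingSpec:
    """Parameters of a sinusoidal grating patch.

    ``aperture_diameter_px`` is either a positive number (circular aperture,
    zero outside) or the string ``"full"``.  Luminance amplitude is
    ``contrast / 2`` (Michelson contrast about a mid-gray of 0).
    """

    orientation_deg: float
    contrast: float = 1.0
    phase_rad: float = 0.0
    spatial_freq: float = 1.0 / 6.0  # cycles per pixel
    aperture_diameter_px: float | str = "full"
    patch_size_px: int = DEFAULT_PATCH_SIZE

    def __post_init__(self):
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.spatial_freq <= 0:
            raise ValueError("spatial_freq must be positive")
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if self.aperture_diameter_px != "full":
            diam = float(self.aperture_diameter_px)
            if diam <= 0:
                raise ValueError("aperture diameter must be positive")
            if diam > self.patch_size_px:
                raise ValueError(
                    f"aperture ({diam}px) larger than patch "
                    f"({self.patch_size_px}px)"
                )


def make_grating(spec: GratingSpec) -> ImagePatch:
    """Render a grating patch; a pure, deterministic function of the spec."""
    n = spec.patch_size_px
    theta = np.deg2rad(spec.orientation_deg % 180.0)
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    rows -= c
    cols -= c
    # wave axis perpendicular to the stripes: s = row cos(theta) + col sin(theta)
    s = rows * np.cos(theta) + cols * np.sin(theta)
    px = 0.5 * spec.contrast * np.cos(2.0 * np.pi * spec.spatial_freq * s
                                      + spec.phase_rad)
    if spec.aperture_diameter_px != "full":
        r = float(spec.aperture_diameter_px) / 2.0
        px = np.where(rows**2 + cols**2 <= r * r, px, 0.0)
    return ImagePatch(px, provenance="grating", meta={"spec": asdict(spec)})


@dataclass(frozen=True)
class TextureParams:
    """Natural-surrogate texture: mixer-modulated correlated noise.

    Each patch is the sum of two Gaussian random fields with amplitude
    spectra ~ f^-slope (1/f amplitude, i.e. 1/f^2 power, for the default
    slope of 1), each scaled by its own per-patch log-normal mixer:

    * an *oriented* field whose spectrum is tilted (amplitude
      ``orientation_diversity``) toward a per-patch axis drawn uniformly
      in [0, 180) — the local contour/edge structure of a natural patch;
    * an *isotropic* background field.

    The mixers give heavy-tailed filter-response marginals and a common
    magnitude to center and surround within a patch (the dependency the
    co-shared components capture); the oriented field makes that
    center-surround coupling strongest at the patch's own axis, which is
    what lets each co-shared mixture component own the patches dominated
    by its orientation.  The ensemble stays orientation-isotropic because
    the axis is uniform.  ``oriented_fraction`` sets the share of rms
    contrast carried by the oriented field (0 = single isotropic field
    with one global mixer).

    ``anisotropy`` in [0, 1) additionally tilts *every* patch toward
    ``anisotropy_orientation_deg`` (0 = no ensemble bias).
    """

    size: int = DEFAULT_PATCH_SIZE
    spectral_slope: float = 1.0
    rms_contrast: float = 0.2
    mixer_sigma: float = 0.5
    orientation_diversity: float = 0.6
    oriented_fraction: float = 1.0
    anisotropy: float = 0.0
    anisotropy_orientation_deg: float = 0.0

    def __post_init__(self):
        if self.size <= 1:
            raise ValueError("size must exceed 1")
        if not 0.0 <= self.anisotropy < 1.0:
            raise ValueError("anisotropy must be in [0, 1)")
        if not 0.0 <= self.orientation_diversity < 1.0:
            raise ValueError("orientation_diversity must be in [0, 1)")
        if not 0.0 <= self.oriented_fraction <= 1.0:
            raise ValueError("oriented_fraction must be in [0, 1]")
        if self.rms_contrast <= 0 or self.mixer_sigma < 0:
            raise ValueError("rms_contrast must be > 0, mixer_sigma >= 0")


def _spectral_gain(params: TextureParams,
                   tilt_axis_rad: float | None = None) -> np.ndarray:
    n = params.size
    fr = np.fft.fftfreq(n)[:, None]
    fc = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fr, fc)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-params.spectral_slope), 0.0)
    # wave-vector angle maps to stimulus orientation via the same
    # convention as make_grating
    phi = np.arctan2(fc, fr)
    if params.anisotropy > 0:
        theta0 = np.deg2rad(params.anisotropy_orientation_deg)
        amp = amp * (1.0 + params.anisotropy * np.cos(2.0 * (phi - theta0)))
    if tilt_axis_rad is not None and params.orientation_diversity > 0:
        amp = amp * (1.0 + params.orientation_diversity
                     * np.cos(2.0 * (phi - tilt_axis_rad)))
    return amp


def _unit_field(params: TextureParams, rng: np.random.Generator,
                tilt_axis_rad: float | None) -> np.ndarray:
    """One correlated Gaussian field, normalised to unit rms."""
    white = rng.standard_normal((params.size, params.size))
    spec = np.fft.fft2(white) * _spectral_gain(params, tilt_axis_rad=tilt_axis_rad)
    px = np.real(np.fft.ifft2(spec))
    sd = px.std()
    return px / sd if sd > 0 else px


def make_texture_patch(params: TextureParams, rng: np.random.Generator) -> ImagePatch:
    """Draw one surrogate texture patch (bit-reproducible given the rng state)."""
    w = params.oriented_fraction
    use_oriented = w > 0 and params.orientation_diversity > 0
    axis = float(rng.uniform(0.0, np.pi)) if use_oriented else None
    mixer_o = float(np.exp(rng.normal(0.0, params.mixer_sigma)))
    mixer_b = float(np.exp(rng.normal(0.0, params.mixer_sigma)))
    if use_oriented:
        px = params.rms_contrast * (
            np.sqrt(w) * mixer_o * _unit_field(params, rng, axis)
            + np.sqrt(1.0 - w) * mixer_b * _unit_field(params, rng, None))
    else:
        px = params.rms_contrast * mixer_b * _unit_field(params, rng, None)
    return ImagePatch(px, provenance="texture",
                      meta={"mixer_oriented": mixer_o,
                            "mixer_background": mixer_b,
                            "orientation_axis_rad": axis})


def texture_patches(params: TextureParams, n: int,
                    rng: np.random.Generator) -> list[ImagePatch]:
    return [make_texture_patch(params, rng) for _ in range(n)]


@dataclass(frozen=True)
class MixedDatasetSpec:
    """Adaptation ensemble: surrogate textures plus adaptor-biased gratings.

    Grating orientations follow a wrapped Gaussian centred on the adaptor
    with standard deviation ``orientation_spread_deg``; contrasts are uniform
    on ``contrast_range`` and phases uniform on [0, 2 pi).  The default
    26,000 patches mirrors the size of the adaptation ensemble the model is
    meant to be retrained on; ``grating_fraction`` controls how strongly the
    adaptor dominates the ensemble statistics.

    ``grating_noise_rms`` adds i.i.d. Gaussian pixel noise to the grating
    patches only (textures are stochastic by construction).  Displayed
    stimuli and the neural signals they evoke are never noise-free, and the
    noise floor is also what keeps the ensemble full-rank: ideal sinusoids
    occupy a low-dimensional response manifold on which a maximum-likelihood
    density fit is unbounded.  The default is small relative to the weakest
    grating (contrast 0.2 = rms ~0.07).

    ``grating_aperture_px`` sets the adaptor gratings' aperture ("full" or
    a diameter in pixels).  The standard adaptation recipe uses full-field
    gratings regardless of the test protocol; a center-filter-sized
    aperture is available for aperture-matched protocol variants.
    """

    n_patches: int = 26_000
    grating_fraction: float = 0.3
    adaptor_orientation_deg: float = 90.0
    orientation_spread_deg: float = 5.0
    contrast_range: tuple[float, float] = (0.2, 1.0)
    spatial_freq: float = 1.0 / 6.0
    patch_size_px: int = DEFAULT_PATCH_SIZE
    texture_params: TextureParams = field(default_factory=TextureParams)
    grating_noise_rms: float = 0.01
    grating_aperture_px: int | str = "full"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patches <= 0:
            raise ValueError("n_patches must be positive")
        if not 0.0 <= self.grating_fraction <= 1.0:
            raise ValueError("grating_fraction must be in [0, 1]")
        lo, hi = self.contrast_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("contrast_range must satisfy 0 <= lo <= hi <= 1")
        if self.grating_noise_rms < 0:
            raise ValueError("grating_noise_rms must be non-negative")
        if self.grating_fraction < 1.0 and self.texture_params is None:
            raise ValueError("a texture source is required when "
                             "grating_fraction < 1")
        if self.texture_params is not None and \
                self.texture_params.size != self.patch_size_px:
            raise ValueError("texture size must match patch_size_px")


def sample_mixed_dataset(spec: MixedDatasetSpec) -> list[ImagePatch]:
    """Sample the mixed ensemble; fully reproducible from ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n_grating = int(round(spec.grating_fraction * spec.n_patches))
    patches: list[ImagePatch] = []
    lo, hi = spec.contrast_range
    for _ in range(n_grating):
        # wrapped Gaussian: sample unwrapped, reduce mod 180
        ori = rng.normal(spec.adaptor_orientation_deg,
                         spec.orientation_spread_deg) % 180.0
        g = GratingSpec(
            orientation_deg=ori,
            contrast=rng.uniform(lo, hi),
            phase_rad=rng.uniform(0.0, 2.0 * np.pi),
            spatial_freq=spec.spatial_freq,
            aperture_diameter_px=spec.grating_aperture_px,
            patch_size_px=spec.patch_size_px,
        )
        p = make_grating(g)
        if spec.grating_noise_rms > 0:
            noise = rng.normal(0.0, spec.grating_noise_rms,
                               size=p.pixels.shape)
            p = ImagePatch(pixels=p.pixels + noise - noise.mean(),
                           provenance="grating", meta=dict(p.meta))
        patches.append(p)
    for _ in range(spec.n_patches - n_grating):
        patches.append(make_texture_patch(spec.texture_params, rng))
    order = rng.permutation(len(patches))
    return [patches[i] for i in order]


def load_image_patches(paths: Sequence[str], n_patches: int,
                       patch_size: int = DEFAULT_PATCH_SIZE,
                       seed: int = 0) -> list[ImagePatch]:
    """Randomly crop zero-centred patches from grayscale image files."""
    from PIL import Image

    if not paths:
        raise ValueError("no source images given")
    rng = np.random.default_rng(seed)
    images = []
    for p in paths:
        arr = np.asarray(Image.open(p).convert("L"), dtype=float) / 255.0
        if min(arr.shape) < patch_size:
            raise ValueError(f"image {p} smaller than patch size {patch_size}")
        images.append(arr)
    out = []
    for _ in range(n_patches):
        img = images[rng.integers(len(images))]
        r = rng.integers(img.shape[0] - patch_size + 1)
        c = rng.integers(img.shape[1] - patch_size + 1)
        crop = img[r:r + patch_size, c:c + patch_size]
        out.append(ImagePatch(crop - crop.mean(), provenance="external"))
    return out


def write_manifest(spec: MixedDatasetSpec, path: str) -> None:
    """Write a JSON manifest from which the dataset regenerates exactly."""
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2, default=list)
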