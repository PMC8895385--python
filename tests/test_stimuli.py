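"""Stimulus generators: conventions, determinism, validation."""

import numpy as np
import pytest

from v1mgsm.stimuli import (GratingSpec, MixedDatasetSpec, TextureParams,
                            make_grating, make_texture_patch,
                            sample_mixed_dataset, texture_patches)


def test_zero_degree_grating_has_horizontal_stripes():
    px = make_grating(GratingSpec(orientation_deg=0.0)).pixels
    # luminance constant along each row, varying across rows
    assert np.allclose(px, px[:, :1])
    assert np.ptp(px[:, 0]) > 0.5


def test_ninety_degree_grating_has_vertical_stripes():
    px = make_grating(GratingSpec(orientation_deg=90.0)).pixels
    assert np.allclose(px, px[:1, :])
    assert np.ptp(px[0, :]) > 0.5


def test_grating_amplitude_is_half_contrast():
    px = make_grating(GratingSpec(orientation_deg=30.0, contrast=0.6)).pixels
    assert np.max(np.abs(px)) <= 0.3 + 1e-12
    assert np.max(np.abs(px)) > 0.29


def test_orientation_is_periodic_mod_180():
    a = make_grating(GratingSpec(orientation_deg=30.0)).pixels
    b = make_grating(GratingSpec(orientation_deg=210.0)).pixels
    assert np.allclose(a, b)


def test_aperture_zeroes_outside_and_keeps_inside():
    spec = GratingSpec(orientation_deg=0.0, aperture_diameter_px=13,
                       patch_size_px=40)
    px = make_grating(spec).pixels
    c = (40 - 1) / 2.0
    rows, cols = np.mgrid[0:40, 0:40].astype(float)
    outside = (rows - c) ** 2 + (cols - c) ** 2 > 6.5 ** 2
    assert np.all(px[outside] == 0.0)
    assert np.ptp(px[~outside]) > 0.5


def test_grating_spec_validation():
    with pytest.raises(ValueError):
        GratingSpec(orientation_deg=0.0, contrast=1.5)
    with pytest.raises(ValueError):
        GratingSpec(orientation_deg=0.0, aperture_diameter_px=100,
                    patch_size_px=40)
    with pytest.raises(ValueError):
        GratingSpec(orientation_deg=0.0, spatial_freq=0.0)


def test_texture_patch_is_deterministic_given_rng_state():
    a = make_texture_patch(TextureParams(), np.random.default_rng(5)).pixels
    b = make_texture_patch(TextureParams(), np.random.default_rng(5)).pixels
    assert np.array_equal(a, b)


def test_texture_marginals_are_heavy_tailed():
    # per-patch log-normal mixers must produce kurtosis above Gaussian
    patches = texture_patches(TextureParams(), 300, np.random.default_rng(8))
    vals = np.concatenate([p.pixels.ravel() for p in patches])
    vals = vals / vals.std()
    kurtosis = np.mean(vals ** 4) - 3.0
    assert kurtosis > 0.5


def test_texture_ensemble_is_orientation_isotropic():
    from v1mgsm.filterbank import ORIENTATIONS, build_filterbank, \
        center_channel_index, response_matrix
    bank = build_filterbank()
    patches = texture_patches(TextureParams(), 1500, np.random.default_rng(13))
    X = response_matrix(patches, bank)
    energies = []
    for ori in ORIENTATIONS:
        idx = [center_channel_index(ori, ph) for ph in ("even", "odd")]
        energies.append(np.mean(X[:, idx] ** 2))
    assert max(energies) / min(energies) < 1.5


def test_mixed_dataset_reproducible_and_correctly_composed():
    spec = MixedDatasetSpec(n_patches=200, rng_seed=42)
    a = sample_mixed_dataset(spec)
    b = sample_mixed_dataset(spec)
    assert len(a) == 200
    assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
    n_grating = sum(p.provenance == "grating" for p in a)
    assert n_grating == round(0.3 * 200)
    oris = [p.meta["spec"]["orientation_deg"] for p in a
            if p.provenance == "grating"]
    assert all(0.0 <= o < 180.0 for o in oris)
    # wrapped Gaussian around the adaptor: nearly all within 3 sigma
    dev = np.minimum(np.abs(np.array(oris) - 90.0),
                     180.0 - np.abs(np.array(oris) - 90.0))
    assert np.mean(dev < 15.0) > 0.95


def test_grating_fraction_zero_yields_pure_textures():
    spec = MixedDatasetSpec(n_patches=50, grating_fraction=0.0, rng_seed=1)
    assert all(p.provenance == "texture" for p in sample_mixed_dataset(spec))


def test_grating_noise_is_zero_mean_and_small():
    spec = MixedDatasetSpec(n_patches=60, rng_seed=3)
    noisy = [p for p in sample_mixed_dataset(spec) if p.provenance == "grating"]
    clean = make_grating(GratingSpec(**noisy[0].meta["spec"]))
    resid = noisy[0].pixels - clean.pixels
    assert abs(resid.mean()) < 1e-12
    assert 0.0 < resid.std() < 0.05


def test_mixed_spec_validation():
    with pytest.raises(ValueError):
        MixedDatasetSpec(n_patches=0)
    with pytest.raises(ValueError):
        MixedDatasetSpec(grating_fraction=1.2)
    with pytest.raises(ValueError):
        MixedDatasetSpec(contrast_range=(0.9, 0.1))
    with pytest.raises(ValueError):
        MixedDatasetSpec(texture_params=TextureParams(size=32),
                         patch_size_px=40)
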