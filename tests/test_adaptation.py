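"""Adaptation strategies: prior substitution and covariance perturbation."""

import numpy as np
import pytest

from v1mgsm.adaptation import (PERTURBATION_PRESETS, CovariancePerturbation,
                               adapt_by_covariance, adapt_by_prior,
                               compare_states)
from v1mgsm.filterbank import CENTER_DIM, ORIENTATIONS
from v1mgsm.stimuli import MixedDatasetSpec


def test_presets_follow_declared_directions():
    presets = PERTURBATION_PRESETS(target=45.0)
    up = presets["enhance_center_normalization"]
    assert up.target_component == 45.0
    assert set(up.center_variance_scale) == {0.0, 90.0, 135.0}
    assert all(f == 2.0 for f in up.center_variance_scale.values())
    assert up.surround_variance_scale == 1.0
    down = presets["weaken_surround_normalization"]
    assert down.center_variance_scale == {}
    assert down.surround_variance_scale == 0.5
    assert down.surround_covariance_scale == 0.5
    both = presets["combined"]
    assert both.surround_variance_scale == 0.5
    assert all(f == 2.0 for f in both.center_variance_scale.values())
    double = presets["combined_double"]
    assert all(f == 4.0 for f in double.center_variance_scale.values())


@pytest.mark.parametrize("name", sorted(PERTURBATION_PRESETS()))
def test_perturbation_touches_only_the_target(small_state, name):
    pert = PERTURBATION_PRESETS(target=45.0)[name]
    out = adapt_by_covariance(small_state, pert)
    assert np.array_equal(out.priors, small_state.priors)
    assert np.array_equal(out.sigma_c.effective_Sigma,
                          small_state.sigma_c.effective_Sigma)
    for t in ORIENTATIONS:
        if t == 45.0:
            continue
        assert np.array_equal(out.sigma_cn[t].effective_Sigma,
                              small_state.sigma_cn[t].effective_Sigma)
    assert not out.metadata["covariance_perturbation"]["spd_repaired"]


def test_perturbed_entries_scale_as_declared(small_state):
    pert = PERTURBATION_PRESETS(target=45.0)["combined"]
    before = small_state.sigma_cn[45.0].effective_Sigma
    after = adapt_by_covariance(small_state, pert).sigma_cn[45.0] \
        .effective_Sigma
    sur = slice(CENTER_DIM, 24)
    # adaptor's own center variances untouched
    t45 = 2 * ORIENTATIONS.index(45.0)
    for ph in (0, 1):
        assert np.isclose(after[t45 + ph, t45 + ph],
                          before[t45 + ph, t45 + ph])
    # non-adapted center variances doubled
    for ori in (0.0, 90.0, 135.0):
        t = 2 * ORIENTATIONS.index(ori)
        for ph in (0, 1):
            assert np.isclose(after[t + ph, t + ph],
                              2.0 * before[t + ph, t + ph])
    # surround variances and all surround/cross covariances halved
    assert np.allclose(np.diag(after[sur, sur]),
                       0.5 * np.diag(before[sur, sur]))
    assert np.allclose(after[:CENTER_DIM, sur], 0.5 * before[:CENTER_DIM, sur])
    off = ~np.eye(16, dtype=bool)
    assert np.allclose(after[sur, sur][off], 0.5 * before[sur, sur][off])


def test_literal_preset_directions_preserve_positive_definiteness(small_state):
    for name, pert in PERTURBATION_PRESETS(target=90.0).items():
        out = adapt_by_covariance(small_state, pert)
        eigs = np.linalg.eigvalsh(out.sigma_cn[90.0].effective_Sigma)
        assert eigs.min() > 0, name
        assert not out.metadata["covariance_perturbation"]["spd_repaired"]


def test_perturbation_validation():
    with pytest.raises(ValueError):
        CovariancePerturbation(target_component=30.0)
    with pytest.raises(ValueError):
        CovariancePerturbation(target_component=0.0,
                               center_variance_scale={10.0: 2.0})
    with pytest.raises(ValueError):
        CovariancePerturbation(target_component=0.0,
                               surround_variance_scale=-1.0)


def test_prior_substitution_keeps_baseline_covariances(bank, small_state):
    spec = MixedDatasetSpec(n_patches=300, rng_seed=7)
    from v1mgsm.estimator import EMConfig
    cfg = EMConfig(n_iter_max=15)
    frozen = adapt_by_prior(None, spec, bank, cfg, freeze_covariance=True,
                            baseline_state=small_state)
    full = adapt_by_prior(None, spec, bank, cfg)
    # frozen state: retrained priors, baseline covariances bit-identical
    assert np.array_equal(frozen.priors, full.priors)
    assert np.array_equal(frozen.sigma_c.effective_Sigma,
                          small_state.sigma_c.effective_Sigma)
    for t in ORIENTATIONS:
        assert np.array_equal(frozen.sigma_cn[t].effective_Sigma,
                              small_state.sigma_cn[t].effective_Sigma)
    # fully retrained covariances do differ from the baseline
    assert not np.allclose(full.sigma_cn[90.0].effective_Sigma,
                           small_state.sigma_cn[90.0].effective_Sigma)


def test_freeze_requires_a_baseline(bank):
    with pytest.raises(ValueError):
        adapt_by_prior(None, MixedDatasetSpec(n_patches=300), bank,
                       freeze_covariance=True)


def test_compare_states_reports_prior_and_covariance_deltas(small_state):
    pert = PERTURBATION_PRESETS(target=90.0)["combined"]
    out = adapt_by_covariance(small_state, pert)
    diff = compare_states(small_state, out)
    assert np.allclose(diff.prior_delta, 0.0)
    assert diff.covariance_delta[90.0] > 0.0
    assert diff.covariance_delta[0.0] == 0.0
    assert diff.covariance_delta["nonshared"] == 0.0
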