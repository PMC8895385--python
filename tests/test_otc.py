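"""Tuning-curve measurement and its metrics."""

import numpy as np
import pytest

from v1mgsm.otc import (PARADIGMS, OTCProtocol, OTCResult, ParadigmConfig,
                        _interp_peak, measure_otc, otc_metrics, run_paradigm)


def synthetic_result(before, after, grid=None):
    grid = np.asarray(grid if grid is not None
                      else range(-90, 91, 15), dtype=float)
    return OTCResult(grid_deg=grid, response_before=np.asarray(before, float),
                     response_after=np.asarray(after, float),
                     winner_trace=np.zeros(len(grid), dtype=int),
                     protocol=OTCProtocol())


def gaussian_curve(grid, mu, amp=1.0, width=30.0):
    g = np.asarray(grid, dtype=float)
    return amp * np.exp(-0.5 * ((g - mu) / width) ** 2)


def test_interp_peak_recovers_quadratic_vertex():
    grid = np.arange(-90.0, 91.0, 15.0)
    y = -((grid - 7.0) ** 2)
    assert np.isclose(_interp_peak(grid, y), 7.0)


def test_interp_peak_at_grid_edge_stays_on_grid():
    grid = np.arange(-90.0, 91.0, 15.0)
    y = np.linspace(0.0, 1.0, len(grid))
    assert _interp_peak(grid, y) == 90.0


def test_shift_sign_is_positive_toward_the_adaptor():
    grid = np.arange(-90.0, 91.0, 15.0)
    before = gaussian_curve(grid, 0.0)
    toward = gaussian_curve(grid, -10.0)   # moved toward adaptor at -45
    away = gaussian_curve(grid, +10.0)
    m = otc_metrics(synthetic_result(before, toward), -45.0)
    assert m.shift_deg > 0
    m = otc_metrics(synthetic_result(before, away), -45.0)
    assert m.shift_deg < 0


def test_ratio_metrics():
    grid = np.arange(-90.0, 91.0, 15.0)
    before = gaussian_curve(grid, 0.0, amp=1.0)
    after = gaussian_curve(grid, 0.0, amp=0.5)
    m = otc_metrics(synthetic_result(before, after), 0.0)
    assert np.isclose(m.peak_ratio, 0.5)
    assert np.isclose(m.response_ratio_at_adaptor, 0.5)
    assert np.isclose(m.mean_response_ratio, 0.5)
    assert np.isclose(m.shift_deg, 0.0)


def test_flat_curves_are_flagged_not_crashed():
    grid = np.arange(-90.0, 91.0, 15.0)
    m = otc_metrics(synthetic_result(np.ones(len(grid)),
                                     gaussian_curve(grid, 0.0)), 0.0)
    assert m.flat_before and not m.flat_after
    assert np.isnan(m.shift_deg)


def test_protocol_validation():
    with pytest.raises(ValueError):
        OTCProtocol(aperture="medium")
    with pytest.raises(ValueError):
        OTCProtocol(n_phases_averaged=0)
    with pytest.raises(ValueError):
        OTCProtocol(noise_rms=-0.1)


def test_measurement_is_deterministic(bank, small_state):
    protocol = OTCProtocol(n_phases_averaged=2,
                           orientation_grid_deg=(-90, -45, 0, 45, 90))
    a = measure_otc(small_state, small_state, bank, protocol,
                    adaptor_deg_relative=0.0)
    b = measure_otc(small_state, small_state, bank, protocol,
                    adaptor_deg_relative=0.0)
    assert np.array_equal(a.response_before, b.response_before)
    assert np.array_equal(a.response_after, b.response_after)
    assert np.array_equal(a.winner_trace, b.winner_trace)


def test_identical_states_identical_readouts_give_unit_ratios(bank,
                                                              small_state):
    protocol = OTCProtocol(n_phases_averaged=2, readout_after="mixture",
                           orientation_grid_deg=(-45, 0, 45))
    res = measure_otc(small_state, small_state, bank, protocol,
                      adaptor_deg_relative=0.0)
    assert np.allclose(res.response_after, res.response_before)


def test_responses_are_nonnegative_and_tuned(bank, small_state):
    protocol = OTCProtocol(n_phases_averaged=4)
    res = measure_otc(small_state, small_state, bank, protocol,
                      adaptor_deg_relative=0.0)
    assert np.all(res.response_before >= 0.0)
    # peak at the preferred orientation region, flanks low
    i0 = list(res.grid_deg).index(0.0)
    assert res.response_before[i0] > 5.0 * res.response_before[0]
    assert res.response_before[i0] > 5.0 * res.response_before[-1]


def test_paradigm_table_is_complete():
    assert len(PARADIGMS) == 10
    for rel, aperture, strategy in PARADIGMS.values():
        assert rel in (0.0, -45.0, -90.0)
        assert aperture in ("small", "large")
    strategies = {s for _, _, s in PARADIGMS.values()}
    assert "prior" in strategies and "combined" in strategies


def test_unknown_paradigm_is_rejected():
    with pytest.raises(ValueError):
        run_paradigm("no_such_paradigm")


def test_fast_config_scales_down():
    cfg = ParadigmConfig().fast()
    assert cfg.n_train_patches == 2_500
    assert cfg.n_mixed_patches == 2_600
    assert ParadigmConfig().n_train_patches == 25_000
    assert ParadigmConfig().n_mixed_patches == 26_000
    assert ParadigmConfig().grating_fraction == 0.3
    assert ParadigmConfig().orientation_spread_deg == 5.0
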