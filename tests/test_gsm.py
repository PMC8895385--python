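"""GSM closed forms against the quadrature oracle and their edge cases."""

import numpy as np
import pytest

from v1mgsm.gsm import (CovarianceError, GSMComponent, _log_kve, gsm_loglik,
                        gsm_expected_inv_v, gsm_expected_inv_v2,
                        gsm_posterior_mean_g, oracle_posterior_norm,
                        quadrature_oracle)


def random_component(d, rng, condition=10.0):
    """Well-conditioned random SPD covariance of dimension d."""
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    eigs = np.exp(rng.uniform(0.0, np.log(condition), size=d))
    return GSMComponent(Q @ np.diag(eigs) @ Q.T)


def random_input(d, rng):
    """Direction uniform, magnitude log-uniform over six decades."""
    x = rng.standard_normal(d)
    x /= np.linalg.norm(x)
    return x * 10.0 ** rng.uniform(-3, 3)


@pytest.mark.parametrize("d", [1, 2, 4, 8, 24])
def test_closed_forms_match_quadrature_oracle(d):
    rng = np.random.default_rng(100 + d)
    for _ in range(20):
        comp = random_component(d, rng)
        x = random_input(d, rng)
        ll = gsm_loglik(x, comp)
        assert np.isclose(ll, quadrature_oracle("logmarginal", x, comp),
                          rtol=1e-6, atol=0.0)
        assert np.isclose(gsm_expected_inv_v(x, comp),
                          quadrature_oracle("inv_v", x, comp), rtol=1e-6)
        assert np.isclose(gsm_expected_inv_v2(x, comp),
                          quadrature_oracle("inv_v2", x, comp), rtol=1e-6)


def test_posterior_weight_normalises_to_one():
    rng = np.random.default_rng(7)
    for d in (1, 4, 24):
        comp = random_component(d, rng)
        x = random_input(d, rng)
        assert np.isclose(oracle_posterior_norm(x, comp), 1.0, rtol=1e-7)


def test_zero_input_marginal_density_is_half_in_1d():
    comp = GSMComponent(np.array([[1.0]]))
    assert abs(np.exp(gsm_loglik(np.array([0.0]), comp)) - 0.5) < 1e-9


def test_posterior_mean_vanishes_at_zero_input():
    comp = random_component(4, np.random.default_rng(3))
    g = gsm_posterior_mean_g(np.zeros(4), comp)
    assert np.all(g == 0.0)


def test_posterior_mean_is_componentwise_shrinkage():
    # E[g|x] = x * E[1/v|x]: same direction as x, positive gain
    rng = np.random.default_rng(11)
    comp = random_component(6, rng)
    x = random_input(6, rng)
    g = gsm_posterior_mean_g(x, comp)
    gain = gsm_expected_inv_v(x, comp)
    assert gain > 0
    assert np.allclose(g, x * gain)


def test_loglik_finite_over_extreme_magnitudes():
    comp = random_component(8, np.random.default_rng(5))
    for mag in (0.0, 1e-12, 1e-3, 1.0, 1e3, 1e7, 1e12):
        x = np.full(8, mag / np.sqrt(8.0))
        assert np.isfinite(gsm_loglik(x, comp))
        assert np.isfinite(gsm_expected_inv_v2(x, comp))


def test_log_kve_asymptotic_branch_matches_scipy_at_the_switch():
    # scipy's kve is still accurate slightly above the switch point (it
    # only overflows much later), so both branches can be compared at the
    # same argument there
    from scipy.special import kve
    from v1mgsm.gsm import _KVE_ASYMPTOTIC_LAM
    lam = _KVE_ASYMPTOTIC_LAM * 1.000001  # asymptotic branch
    for nu in (0.0, 0.5, 1.0, 5.5, 11.0):
        assert np.isclose(_log_kve(nu, lam), np.log(kve(nu, lam)),
                          rtol=1e-13)


def test_trace_normalisation_folds_into_scale():
    rng = np.random.default_rng(2)
    S = random_component(5, rng).Sigma * 3.7
    comp = GSMComponent(S)
    assert np.isclose(np.trace(comp.Sigma), 5.0)
    assert np.allclose(comp.effective_Sigma, S)


def test_batched_and_single_calls_agree():
    rng = np.random.default_rng(9)
    comp = random_component(4, rng)
    X = np.stack([random_input(4, rng) for _ in range(6)])
    batch = gsm_loglik(X, comp)
    assert np.allclose(batch, [gsm_loglik(x, comp) for x in X])
    batch_g = gsm_posterior_mean_g(X, comp, i=2)
    assert np.allclose(batch_g, [gsm_posterior_mean_g(x, comp, i=2) for x in X])


def test_invalid_covariances_are_rejected():
    with pytest.raises(CovarianceError):
        GSMComponent(np.array([[1.0, 2.0], [2.0, 1.0]]))  # indefinite
    with pytest.raises(CovarianceError):
        GSMComponent(np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(CovarianceError):
        GSMComponent(np.eye(3), scale=-1.0)


def test_mahalanobis_matches_direct_computation():
    rng = np.random.default_rng(21)
    comp = random_component(5, rng)
    x = random_input(5, rng)
    lam = comp.mahalanobis(x)
    direct = np.sqrt(x @ np.linalg.solve(comp.effective_Sigma, x))
    assert np.isclose(lam, direct, rtol=1e-10)
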