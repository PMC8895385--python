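"""EM fitting of the five-component mixture of Gaussian scale mixtures.

:class:`MGSM` is a scikit-learn-style estimator.  ``X`` is the
(n_patches, 72) matrix of flat filter-response vectors (see
:mod:`v1mgsm.filterbank` for the layout); ``fit`` runs
expectation-maximisation:

* E-step: posterior responsibility of each component for each patch, from
  the mixture priors and each component's full 72-dim likelihood (its
  co-shared or center-only GSM factor times an independent GSM factor for
  every surround block it does not co-share; see :mod:`v1mgsm.state`);
* M-step: priors become mean responsibilities, solved under the
  ``min_prior`` floor by exact waterfilling so that every step provably
  does not decrease the data log-likelihood; each covariance becomes the
  responsibility- and E[1/v^2|x]-weighted second moment, the
  maximum-likelihood update for a Gaussian scale mixture.

The fit is two-stage.  The independent-surround covariances Sigma_N_theta
are pre-fit once as a single rotation-equivariant GSM (all four surround
blocks pooled in a canonical frame; see ``_fit_surround_factor``) and held
fixed during the mixture EM, which then learns the priors, Sigma_C and
the Sigma_CN_theta.  Joint maximum
likelihood over the Sigma_N_theta is unstable: their natural update
weights each patch by (1 - q_theta), so the component that wins a stimulus
class removes exactly that class from its own independent-surround factor,
a positive feedback that lets one co-shared component absorb the entire
ensemble.  With the factors fixed, the mixture EM is exact coordinate-wise
EM and the log-likelihood trace is non-decreasing.

The mixer/covariance scale degeneracy is handled by storing every
covariance trace-normalised (trace = d) together with a scalar gain, a
reparameterisation that leaves the likelihood untouched, so the
log-likelihood trace is exactly non-decreasing up to floating-point noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .filterbank import (ORIENTATIONS, FilterBank, component_matrix,
                         response_matrix, surround_canonical_permutation,
                         surround_matrix)
from .gsm import GSMComponent, gsm_expected_inv_v2
from .state import COMPONENTS, MGSMState, component_logliks

__all__ = ["EMConfig", "FitReport", "MGSM", "fit_mgsm", "loglik_dataset"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the EM loop (defaults are the package's standard fit)."""

    n_iter_max: int = 200
    loglik_tol: float = 1e-6
    init_seed: int = 0
    trace_normalize: bool = True
    min_prior: float = 1e-4
    ridge: float = 1e-4

    def __post_init__(self):
        if self.n_iter_max < 1:
            raise ValueError("n_iter_max must be >= 1")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")
        if not 0 <= self.min_prior < 0.2:
            raise ValueError("min_prior must be in [0, 0.2)")


@dataclass
class FitReport:
    loglik_trace: np.ndarray
    n_iter_used: int
    converged: bool
    final_priors: np.ndarray


def _floored_priors(resp_mean: np.ndarray, floor: float) -> np.ndarray:
    """Maximise sum r_k log p_k on the simplex subject to p_k >= floor.

    KKT waterfilling: components whose unconstrained share falls below the
    floor are pinned there; the rest share the remaining mass in proportion
    to their responsibilities.
    """
    r = np.asarray(resp_mean, dtype=float)
    r = r / r.sum()
    if floor <= 0:
        return r
    pinned = np.zeros(len(r), dtype=bool)
    for _ in range(len(r)):
        free_mass = 1.0 - floor * pinned.sum()
        p = np.where(pinned, floor, 0.0)
        r_free = np.where(pinned, 0.0, r)
        p = p + r_free / r_free.sum() * free_mass
        newly = (~pinned) & (p < floor)
        if not newly.any():
            return p
        pinned |= newly
    return np.full(len(r), 1.0 / len(r))


class MGSM(BaseEstimator):
    """Mixture of Gaussian scale mixtures for center-surround responses.

    Parameters
    ----------
    n_iter_max, loglik_tol, min_prior, ridge, init_seed
        See :class:`EMConfig`.  ``ridge`` regularises the data second
        moment used for initialisation (relative to its mean diagonal).
        Initialisation is deterministic (uniform priors, data second
        moments); ``init_seed`` is recorded in the state metadata.

    Attributes (after fit)
    ----------------------
    state_ : MGSMState
    priors_ : (5,) array in component order (non-shared, 0, 45, 90, 135)
    loglik_trace_ : per-iteration total data log-likelihood (non-decreasing)
    n_iter_, converged_
    """

    def __init__(self, n_iter_max: int = 200, loglik_tol: float = 1e-6,
                 min_prior: float = 1e-4, ridge: float = 1e-4,
                 init_seed: int = 0):
        self.n_iter_max = n_iter_max
        self.loglik_tol = loglik_tol
        self.min_prior = min_prior
        self.ridge = ridge
        self.init_seed = init_seed

    # -- helpers ----------------------------------------------------------
    def _config(self) -> EMConfig:
        return EMConfig(n_iter_max=self.n_iter_max, loglik_tol=self.loglik_tol,
                        init_seed=self.init_seed, min_prior=self.min_prior,
                        ridge=self.ridge)

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 72:
            raise ValueError(f"X must be (n, 72) response vectors, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    @staticmethod
    def _init_component(Xk: np.ndarray, ridge: float) -> GSMComponent:
        S = Xk.T @ Xk / len(Xk)
        S = S + ridge * np.mean(np.diag(S)) * np.eye(S.shape[0])
        return GSMComponent(S)

    @staticmethod
    def _fit_single_gsm(Xk: np.ndarray, ridge: float,
                        n_iter: int = 100, tol: float = 1e-8) -> GSMComponent:
        """ML fit of one GSM to all rows of ``Xk`` (fixed-point iteration).

        Each step sets Sigma to the E[1/v^2|x]-weighted second moment, the
        single-component EM update, so the marginal likelihood is
        non-decreasing; iterated to a relative fixed point.
        """
        comp = MGSM._init_component(Xk, ridge)
        for _ in range(n_iter):
            w = gsm_expected_inv_v2(Xk, comp)
            S = (Xk * w[:, None]).T @ Xk / len(Xk)
            S = 0.5 * (S + S.T)
            new = GSMComponent(S)
            delta = np.linalg.norm(new.effective_Sigma - comp.effective_Sigma)
            comp = new
            if delta <= tol * np.linalg.norm(comp.effective_Sigma):
                break
        return comp

    @staticmethod
    def _fit_surround_factor(Xn: dict, ridge: float) -> dict:
        """Rotation-equivariant independent-surround factor.

        The four surround blocks are mapped into a common canonical frame
        (ring positions re-indexed by the block's orientation), pooled, and
        fit as a single GSM; the result is carried back to every block's
        own frame.  The surround geometry is rotation-symmetric, so for an
        orientation-isotropic ensemble the four marginals are the same
        matrix up to this re-indexing, and the constraint is exact.  It is
        essential for an anisotropic ensemble: fitting each block's
        marginal separately lets an over-represented orientation distort
        *one* factor, which biases the competition between the co-shared
        components; the pooled fit spreads any anisotropy equally over the
        four factors, where it cancels in the component posteriors.
        """
        perms = {t: surround_canonical_permutation(t) for t in ORIENTATIONS}
        pooled = np.vstack([Xn[t][:, perms[t]] for t in ORIENTATIONS])
        canon = MGSM._fit_single_gsm(pooled, ridge)
        ncomps = {}
        for t in ORIENTATIONS:
            S = np.empty_like(canon.effective_Sigma)
            S[np.ix_(perms[t], perms[t])] = canon.effective_Sigma
            ncomps[t] = GSMComponent(S)
        return ncomps

    @staticmethod
    def _weighted_component(Xk: np.ndarray, q: np.ndarray,
                            comp: GSMComponent, label: str) -> GSMComponent:
        """One M-step covariance: q- and E[1/v^2|x]-weighted second moment.

        A component whose total responsibility underflows to ~zero has no
        data to estimate from; its covariance is left unchanged (the update
        would be 0/0), which leaves the EM objective untouched because the
        component's weight in it is ~zero.
        """
        qsum = q.sum()
        if not qsum > 1e-9 * len(q):
            log.warning("component %s has vanishing responsibility; "
                        "covariance kept", label)
            return comp
        wk = q * gsm_expected_inv_v2(Xk, comp)
        S = (Xk * wk[:, None]).T @ Xk / qsum
        S = 0.5 * (S + S.T)
        try:
            return GSMComponent(S)
        except Exception:
            # rank-deficient responsibility-weighted moment: ridge it
            log.warning("degenerate covariance update for component %s; "
                        "regularization applied", label)
            S = S + 1e-8 * np.mean(np.diag(S)) * np.eye(S.shape[0])
            return GSMComponent(S)

    # -- scikit-learn API --------------------------------------------------
    def fit(self, X, y=None, init_state: MGSMState | None = None):
        X = self._validate_X(X)
        if len(X) < 100:
            raise ValueError("need at least 100 patches to fit")
        cfg = self._config()

        Xc = {name: component_matrix(X, name) for name in COMPONENTS}
        Xn = {t: surround_matrix(X, t) for t in ORIENTATIONS}
        if init_state is None:
            priors = np.full(5, 0.2)
            comps = {name: self._init_component(Xc[name], cfg.ridge)
                     for name in COMPONENTS}
            # stage 1: independent-surround factor, fixed during the EM
            ncomps = self._fit_surround_factor(Xn, cfg.ridge)
        else:
            priors = init_state.priors.copy()
            comps = {name: init_state.component(name) for name in COMPONENTS}
            ncomps = {t: init_state.sigma_n[t] for t in ORIENTATIONS}

        trace = []
        converged = False
        for it in range(cfg.n_iter_max):
            # E-step (log domain)
            state = self._assemble(priors, comps, ncomps)
            with np.errstate(divide="ignore"):
                logpost = component_logliks(X, state) + np.log(priors)
            m = logpost.max(axis=1, keepdims=True)
            w = np.exp(logpost - m)
            tot = w.sum(axis=1, keepdims=True)
            ll = float((m[:, 0] + np.log(tot[:, 0])).sum())
            Q = w / tot
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= \
                    cfg.loglik_tol * (abs(trace[-2]) + 1.0):
                converged = True
                break

            # M-step
            priors = _floored_priors(Q.mean(axis=0), cfg.min_prior)
            comps = {name: self._weighted_component(Xc[name], Q[:, k],
                                                    comps[name], name)
                     for k, name in enumerate(COMPONENTS)}

        self.state_ = self._assemble(priors, comps, ncomps, seal=True)
        self.priors_ = priors
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    def _assemble(self, priors, comps, ncomps, seal: bool = False) -> MGSMState:
        meta = {}
        if seal:
            from dataclasses import asdict
            meta = {"em_config": asdict(self._config())}
        return MGSMState(
            prior_nonshared=float(priors[0]),
            prior_shared={t: float(priors[1 + i])
                          for i, t in enumerate(ORIENTATIONS)},
            sigma_c=comps["nonshared"],
            sigma_cn={t: comps[t] for t in ORIENTATIONS},
            sigma_n={t: ncomps[t] for t in ORIENTATIONS},
            metadata=meta,
        )

    def predict_proba(self, X) -> np.ndarray:
        from .state import component_posteriors
        self._check_fitted()
        return component_posteriors(self._validate_X(X), self.state_)

    def predict(self, X) -> np.ndarray:
        """Index of the maximum-posterior component per row."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-patch log-likelihood."""
        self._check_fitted()
        X = self._validate_X(X)
        return float(self._total_loglik(X) / len(X))

    def respond(self, X, channel, readout: str = "mixture") -> np.ndarray:
        """Model response of a center channel; readout 'mixture' or 'wta'."""
        from .state import mixture_response, wta_response
        self._check_fitted()
        X = self._validate_X(X)
        if readout == "mixture":
            return mixture_response(X, self.state_, channel)
        if readout == "wta":
            return wta_response(X, self.state_, channel)
        raise ValueError(f"unknown readout {readout!r}")

    def _total_loglik(self, X) -> float:
        with np.errstate(divide="ignore"):
            logpost = component_logliks(X, self.state_) + \
                np.log(self.state_.priors)
        m = logpost.max(axis=1)
        return float((m + np.log(np.exp(logpost - m[:, None]).sum(axis=1))).sum())

    def _check_fitted(self):
        if not hasattr(self, "state_"):
            raise AttributeError("estimator is not fitted; call fit first")


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_mgsm(patches, bank: FilterBank, cfg: EMConfig | None = None,
             init_state: MGSMState | None = None):
    """Fit the mixture to an ensemble of image patches.

    Filtering is done once up front; EM operates on response vectors, so a
    precomputed (n, 72) array may be passed in place of patches.
    """
    cfg = cfg or EMConfig()
    X = patches if isinstance(patches, np.ndarray) \
        else response_matrix(patches, bank)
    est = MGSM(n_iter_max=cfg.n_iter_max, loglik_tol=cfg.loglik_tol,
               min_prior=cfg.min_prior, ridge=cfg.ridge,
               init_seed=cfg.init_seed).fit(X, init_state=init_state)
    report = FitReport(loglik_trace=est.loglik_trace_, n_iter_used=est.n_iter_,
                       converged=est.converged_, final_priors=est.priors_)
    return est.state_, report


def loglik_dataset(patches, bank: FilterBank, state: MGSMState) -> float:
    """Total mixture log-likelihood of an ensemble under a given state."""
    X = patches if isinstance(patches, np.ndarray) \
        else response_matrix(patches, bank)
    with np.errstate(divide="ignore"):
        logpost = component_logliks(X, state) + np.log(state.priors)
    m = logpost.max(axis=1)
    return float((m + np.log(np.exp(logpost - m[:, None]).sum(axis=1))).sum())
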