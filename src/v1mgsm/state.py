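"""The five-component mixture: state container, posteriors and readouts.

An :class:`MGSMState` is the model "state": five mixture priors (one
non-shared component in which center and surround have independent mixers,
and four co-shared components, one per orientation, in which center and the
surround block at that orientation share a mixer) plus the covariances of
the Gaussian factors: 8x8 center-only ``sigma_c``, 24x24 center+surround
``sigma_cn[theta]``, and 16x16 independent-surround ``sigma_n[theta]``.
The state entirely determines the model's response to a stimulus;
adaptation acts by changing it.

Two likelihoods live here, each with its own job:

* **Generative likelihood** (:func:`component_logliks`): every component
  models the *full* 72-dim response vector; the blocks it does not
  co-share are independent GSM factors with their own mixers:

  * non-shared:  GSM(c; sigma_c) * prod_theta GSM(n_theta; sigma_n[theta])
  * co-shared theta:  GSM([c, n_theta]; sigma_cn[theta])
    * prod_{theta' != theta} GSM(n_theta'; sigma_n[theta'])

  This is a proper joint density, the one EM fits and
  :func:`v1mgsm.estimator.loglik_dataset` scores.  It is what makes
  retraining on a grating-enriched ensemble concentrate the gratings in
  the matching co-shared component: only the *difference* between
  co-sharing and independence is scored, so a component whose surround
  happens to be silent gains no density bonus during fitting.

* **Readout posterior** (:func:`component_posteriors`): each component is
  scored on its own component vector only,
  ``posterior_k ∝ prior_k * GSM(x_k; Sigma_k)`` with the 8-dim center
  vector for the non-shared component and the 24-dim center+surround
  vector for each co-shared component.  This is the source model's Bayes
  rule: the five hypotheses are compared on the evidence each one
  explains.  All downstream responses (mixture and WTA readouts, hence
  every tuning curve) use this posterior.

Readouts for a center channel (orientation, phase):

* mixture: the posterior-probability-weighted sum of the five components'
  divisive-normalised responses (the "before adaptation" response);
* winner-take-all (WTA): the response of the single component with the
  largest posterior; the selection vector is one-hot, ties broken toward the
  lowest component index (non-shared first).

Posteriors are computed in the log domain with log-sum-exp, so inputs from
zero up to very large norms stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .filterbank import (ORIENTATIONS, component_matrix, center_channel_index,
                         surround_matrix)
from .gsm import GSMComponent, gsm_loglik, gsm_posterior_mean_g

__all__ = [
    "COMPONENTS",
    "MGSMState",
    "component_logliks",
    "readout_logliks",
    "component_posteriors",
    "normalized_component_responses",
    "mixture_response",
    "wta_response",
]

#: Component order used everywhere: non-shared first, then orientations.
COMPONENTS = ("nonshared",) + ORIENTATIONS


@dataclass
class MGSMState:
    """Mixture priors and component covariances.

    ``sigma_c`` is the 8-dim center-only factor; ``sigma_cn[theta]`` the
    24-dim center+surround factor at orientation theta; ``sigma_n[theta]``
    the 16-dim independent-surround factor used by every component that
    does not co-share that surround block.  Priors must be non-negative
    and sum to one.
    """

    prior_nonshared: float
    prior_shared: Mapping[float, float]
    sigma_c: GSMComponent
    sigma_cn: Mapping[float, GSMComponent]
    sigma_n: Mapping[float, GSMComponent]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        pri = self.priors
        if np.any(pri < 0):
            raise ValueError("priors must be non-negative")
        if not np.isclose(pri.sum(), 1.0, atol=1e-10):
            raise ValueError(f"priors must sum to 1, got {pri.sum()!r}")
        if self.sigma_c.d != 8:
            raise ValueError("center covariance must be 8x8")
        for th in ORIENTATIONS:
            if self.sigma_cn[th].d != 24:
                raise ValueError("center+surround covariances must be 24x24")
            if self.sigma_n[th].d != 16:
                raise ValueError("independent-surround covariances must be "
                                 "16x16")

    @property
    def priors(self) -> np.ndarray:
        """Priors in COMPONENTS order."""
        return np.array([self.prior_nonshared]
                        + [self.prior_shared[t] for t in ORIENTATIONS])

    def component(self, name) -> GSMComponent:
        return self.sigma_c if name == "nonshared" else self.sigma_cn[name]

    def replace_priors(self, priors: np.ndarray) -> "MGSMState":
        return MGSMState(
            prior_nonshared=float(priors[0]),
            prior_shared={t: float(priors[1 + i])
                          for i, t in enumerate(ORIENTATIONS)},
            sigma_c=self.sigma_c,
            sigma_cn=dict(self.sigma_cn),
            sigma_n=dict(self.sigma_n),
            metadata=dict(self.metadata),
        )


def _flat(r):
    from .filterbank import ResponseVector
    flat = r.flat if isinstance(r, ResponseVector) else r
    X = np.asarray(flat, dtype=float)
    return np.atleast_2d(X), X.ndim == 1


def component_logliks(r, state: MGSMState) -> np.ndarray:
    """(n, 5) full generative log-likelihoods log p(C, N | component).

    Each component scores all 72 responses: its co-shared (or center-only)
    GSM factor plus an independent GSM factor for every surround block it
    does not co-share.  This is the likelihood EM fits and
    ``loglik_dataset`` scores; the readout posterior uses
    :func:`readout_logliks` instead.
    """
    X, single = _flat(r)
    ll_c = gsm_loglik(component_matrix(X, "nonshared"), state.sigma_c)
    ll_n = {t: gsm_loglik(surround_matrix(X, t), state.sigma_n[t])
            for t in ORIENTATIONS}
    all_n = np.sum([ll_n[t] for t in ORIENTATIONS], axis=0)
    cols = [ll_c + all_n]
    for t in ORIENTATIONS:
        ll_cn = gsm_loglik(component_matrix(X, t), state.sigma_cn[t])
        cols.append(ll_cn + all_n - ll_n[t])
    L = np.column_stack(cols)
    return L[0] if single else L


def readout_logliks(r, state: MGSMState) -> np.ndarray:
    """(n, 5) per-component log-likelihoods of each component's own vector.

    ``log GSM(c; sigma_c)`` for the non-shared component and
    ``log GSM([c, n_theta]; sigma_cn[theta])`` for each co-shared one —
    the likelihood entering the source model's Bayes posterior.
    """
    X, single = _flat(r)
    cols = [gsm_loglik(component_matrix(X, name), state.component(name))
            for name in COMPONENTS]
    L = np.column_stack(cols)
    return L[0] if single else L


def component_posteriors(r, state: MGSMState) -> np.ndarray:
    """Readout Bayes posteriors over the five components, (n, 5) or (5,).

    ``posterior_k ∝ prior_k * GSM(x_k; Sigma_k)`` with each component
    scored on its own component vector (see module docstring).
    """
    X, single = _flat(r)
    pri = state.priors
    if np.all(pri == 0):
        raise ValueError("all priors are zero")
    with np.errstate(divide="ignore"):
        logpost = readout_logliks(X, state) + np.log(pri)
    m = logpost.max(axis=1, keepdims=True)
    w = np.exp(logpost - m)
    post = w / w.sum(axis=1, keepdims=True)
    return post[0] if single else post


def normalized_component_responses(r, state: MGSMState, channel) -> np.ndarray:
    """Divisive-normalised response of each component at a center channel.

    ``channel`` is (orientation_deg, phase) or a flat center index.  The
    non-shared response is the posterior-mean Gaussian coefficient of the
    channel under the center-only model; each co-shared response is the same
    coefficient under the joint center+surround model (the center block
    occupies the first 8 coordinates of the 24-dim vector, so the channel
    index is shared).
    """
    idx = channel if isinstance(channel, (int, np.integer)) \
        else center_channel_index(*channel)
    X, single = _flat(r)
    cols = [gsm_posterior_mean_g(component_matrix(X, name),
                                 state.component(name), i=idx)
            for name in COMPONENTS]
    R = np.column_stack(cols)
    return R[0] if single else R


def mixture_response(r, state: MGSMState, channel) -> float | np.ndarray:
    """Posterior-weighted sum of the five component responses."""
    X, single = _flat(r)
    post = component_posteriors(X, state)
    resp = normalized_component_responses(X, state, channel)
    out = np.einsum("nk,nk->n", post, resp)
    return float(out[0]) if single else out


def wta_response(r, state: MGSMState, channel, return_winner: bool = False):
    """Winner-take-all readout: the argmax-posterior component's response.

    np.argmax takes the first maximum, so ties deterministically go to the
    lowest component index (non-shared first).
    """
    X, single = _flat(r)
    post = component_posteriors(X, state)
    resp = normalized_component_responses(X, state, channel)
    win = np.argmax(post, axis=1)
    out = resp[np.arange(len(win)), win]
    if single:
        out, win = float(out[0]), int(win[0])
    if return_winner:
        return out, win
    return out
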