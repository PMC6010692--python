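"""Model-fit indices: deviance summaries, DIC, and -2LCPO.

The deviance is D = -2 log L.  The DIC reported here uses the
variance-based effective parameter count p_D = var(D)/2 computed from
the retained deviance draws, so DIC = Dbar + p_D; the classic
plug-in variant p_D = Dbar - D(posterior mean) is also reported for
reference.

The conditional predictive ordinate of response cell (n, i) is
estimated by the harmonic mean of the per-draw cell likelihoods,

    CPO_ni = [ (1/M) * sum_m 1 / L_ni^(m) ]^(-1),

accumulated in log space with a streaming log-sum-exp, and summarized
as -2 * sum(log CPO) at the item and test level.  Smaller DIC and
-2LCPO indicate better fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
from scipy.special import expit

from .mcmc import PosteriorDraws, eap_estimates
from .model_core import (
    EPS,
    QMatrix,
    ResponseMatrix,
    latent_response_matrix,
)

__all__ = [
    "DicResult",
    "FitIndexReport",
    "dic",
    "cpo_matrix",
    "lcpo_summaries",
    "probability_replayer",
    "compute_fit_indices",
]


class DicResult(NamedTuple):
    d_bar: float
    p_d: float
    dic: float


def dic(deviance_draws) -> DicResult:
    """Dbar, p_D = var(D)/2 (sample variance, denominator M - 1), and
    DIC = Dbar + p_D."""
    d = np.asarray(deviance_draws, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("DIC needs at least two deviance draws")
    d_bar = float(d.mean())
    p_d = float(d.var(ddof=1) / 2.0)
    return DicResult(d_bar=d_bar, p_d=p_d, dic=d_bar + p_d)


def cpo_matrix(
    responses: ResponseMatrix,
    probability_draws: Iterable[np.ndarray],
) -> np.ndarray:
    """Harmonic-mean CPO estimate per response cell.

    ``probability_draws`` yields one N x I correct-response probability
    matrix per retained draw (see :func:`probability_replayer`).
    Missing cells get CPO = 1 so they drop out of the log summaries.
    """
    y = responses.entries
    mask = responses.mask
    run_max = None  # streaming log-sum-exp of log(1/L) terms
    run_sum = None
    m_draws = 0
    for p in probability_draws:
        if p.shape != y.shape:
            raise ValueError("probability draw shape does not match the responses")
        pc = np.clip(p, EPS, 1.0 - EPS)
        log_l = np.where(y == 1.0, np.log(pc), np.log1p(-pc))
        term = -log_l  # log(1/L)
        if run_max is None:
            run_max = term.copy()
            run_sum = np.ones_like(term)
        else:
            new_max = np.maximum(run_max, term)
            run_sum = run_sum * np.exp(run_max - new_max) + np.exp(term - new_max)
            run_max = new_max
        m_draws += 1
    if m_draws == 0:
        raise ValueError("no probability draws supplied")
    log_cpo = np.log(m_draws) - (run_max + np.log(run_sum))
    cpo = np.exp(log_cpo)
    if not np.isfinite(cpo).all():
        raise ValueError("non-finite CPO values; check the probability draws")
    return np.where(mask, cpo, 1.0)


def lcpo_summaries(cpo: np.ndarray, mask: Optional[np.ndarray] = None):
    """(-2LCPO at test level, item-level vector).

    Item level is -2 * sum_n log CPO_ni over observed cells; the test
    level is the sum over items.
    """
    c = np.asarray(cpo, dtype=float)
    if (c <= 0).any() or (c > 1.0 + 1e-12).any():
        raise ValueError("CPO values must lie in (0, 1]")
    logc = np.log(c)
    if mask is not None:
        logc = logc * mask
    items = -2.0 * logc.sum(axis=0)
    return float(items.sum()), items


def probability_replayer(draws: PosteriorDraws, q: QMatrix) -> Iterator[np.ndarray]:
    """Replay the retained draws as N x I probability matrices.

    Reconstructs the model's cellwise Bernoulli probabilities from the
    stored parameter draws (delta for PINC, theta/lambda/beta for
    HO-PINC, alpha for the deterministic variants), pooled across
    chains in chain-major order.
    """
    s_all = draws.pooled("slip")
    g_all = draws.pooled("guess")
    qe = q.entries
    if draws.model_tag == "pinc":
        person = draws.pooled("delta")
    elif draws.model_tag == "ho-pinc":
        th = draws.pooled("theta")
        lam = draws.pooled("lambda")
        be = draws.pooled("beta")
        person = None
    else:
        person = draws.pooled("alpha")
    for m in range(s_all.shape[0]):
        if draws.model_tag == "ho-pinc":
            delta = expit(lam[m][None, :] * th[m][:, None].astype(np.float64) - be[m][None, :])
        else:
            delta = person[m].astype(np.float64)
        w = latent_response_matrix(delta, qe)
        yield g_all[m][None, :] + (1.0 - s_all[m] - g_all[m])[None, :] * w


@dataclass(frozen=True)
class FitIndexReport:
    """Deviance-based and predictive fit indices for one fitted model."""

    model_tag: str
    minus2ll_at_posterior_mean: float
    posterior_mean_deviance: float
    p_d: float
    dic: float
    p_d_plugin: float
    dic_plugin: float
    minus2lcpo_test: float
    minus2lcpo_items: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "minus2ll_at_posterior_mean": self.minus2ll_at_posterior_mean,
            "posterior_mean_deviance": self.posterior_mean_deviance,
            "p_d": self.p_d,
            "dic": self.dic,
            "p_d_plugin": self.p_d_plugin,
            "dic_plugin": self.dic_plugin,
            "minus2lcpo_test": self.minus2lcpo_test,
            "minus2lcpo_items": self.minus2lcpo_items.tolist(),
        }


def _deviance_at_posterior_mean(
    responses: ResponseMatrix, q: QMatrix, draws: PosteriorDraws
) -> float:
    from .model_core import bernoulli_loglik  # local to avoid clutter above

    eap = eap_estimates(draws)
    s = eap["slip"].mean
    g = eap["guess"].mean
    if draws.model_tag == "pinc":
        delta = eap["delta"].mean
    elif draws.model_tag == "ho-pinc":
        th = eap["theta"].mean
        lam = eap["lambda"].mean
        be = eap["beta"].mean
        delta = expit(lam[None, :] * th[:, None] - be[None, :])
    else:
        # deterministic models: plug in the modal profile
        delta = (eap["alpha"].mean > 0.5).astype(float)
    w = latent_response_matrix(delta, q.entries)
    p = g[None, :] + (1.0 - s - g)[None, :] * w
    mask = None if responses.is_complete else responses.mask.astype(float)
    return -2.0 * float(bernoulli_loglik(responses.entries, p, mask).sum())


def compute_fit_indices(
    responses: ResponseMatrix, q: QMatrix, draws: PosteriorDraws
) -> FitIndexReport:
    """Full fit-index report from one posterior sample."""
    responses.check_paired(q)
    d_bar, p_d, dic_v = dic(draws.pooled("deviance"))
    d_hat = _deviance_at_posterior_mean(responses, q, draws)
    p_d_plugin = d_bar - d_hat
    cpo = cpo_matrix(responses, probability_replayer(draws, q))
    test_level, items = lcpo_summaries(cpo, mask=responses.mask)
    return FitIndexReport(
        model_tag=draws.model_tag,
        minus2ll_at_posterior_mean=d_hat,
        posterior_mean_deviance=d_bar,
        p_d=p_d,
        dic=dic_v,
        p_d_plugin=p_d_plugin,
        dic_plugin=d_hat + 2.0 * p_d_plugin,
        minus2lcpo_test=test_level,
        minus2lcpo_items=items,
    )
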