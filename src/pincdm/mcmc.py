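"""Metropolis-within-Gibbs estimation for the DINA/PINC model family.

One sweep updates every parameter block once:

* PINC: each mastery-probability column ``delta[:, k]`` by random-walk
  Metropolis on the logit scale (vectorized over persons, accepted per
  person), then the slip and guess vectors by logit-scale random walks
  (accepted per item, proposals violating ``g < 1 - s`` rejected,
  which is equivalent to the jointly truncated prior).
* HO-PINC: the trait vector ``theta`` by per-person random walks, each
  slope ``lambda_k`` (proposals at or below zero rejected, matching
  the positive-truncated normal prior) and intercept ``beta_k`` by
  scalar random walks, then the item block.
* DINA / HO-DINA: each ``alpha[:, k]`` drawn exactly from its
  two-point full conditional (a Gibbs step); the higher-order
  structural parameters see only the Bernoulli likelihood of alpha.

Proposal scales are adapted by Robbins-Monro toward a 0.30-0.45
acceptance band during burn-in only and frozen afterwards, so retained
draws come from a fixed-kernel chain.  The deviance -2 log L is
recorded at every retained iteration.

Priors follow the standard non-informative choices for these models:
delta ~ Beta(1, 1); s ~ Beta(1, 1) and g ~ Beta(1, 1) restricted to
g < 1 - s; theta ~ N(0, 1) (fixed, for identification);
lambda ~ N(0, 4) truncated positive; beta ~ N(0, 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import (
    EPS,
    MODEL_TAGS,
    QMatrix,
    ResponseMatrix,
    bernoulli_loglik,
)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "ConvergenceReport",
    "fit_model",
    "eap_estimates",
    "psrf",
    "convergence_report",
]

_TARGET_ACCEPT = 0.375  # middle of the 0.30-0.45 band


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log(expit(x)), stable for large negative x."""
    return -np.logaddexp(0.0, -x)


def _logit(p: np.ndarray) -> np.ndarray:
    pc = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(pc) - np.log1p(-pc)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    ``lambda_sd`` / ``beta_sd`` are the standard deviations of the
    normal priors on the higher-order slopes and intercepts (the
    default 2.0 corresponds to variance 4).  ``alpha_base_rate`` is
    the independent Bernoulli prior on mastery for the plain DINA
    model.  The theta prior is fixed at N(0, 1) for identification.
    """

    delta_shapes: Tuple[float, float] = (1.0, 1.0)
    slip_shapes: Tuple[float, float] = (1.0, 1.0)
    guess_shapes: Tuple[float, float] = (1.0, 1.0)
    lambda_sd: float = 2.0
    beta_sd: float = 2.0
    alpha_base_rate: float = 0.5

    def __post_init__(self):
        for name in ("delta_shapes", "slip_shapes", "guess_shapes"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_sd <= 0 or self.beta_sd <= 0:
            raise ValueError("prior standard deviations must be positive")
        if not 0.0 < self.alpha_base_rate < 1.0:
            raise ValueError("alpha_base_rate must lie strictly in (0, 1)")


@dataclass(frozen=True)
class McmcConfig:
    """Chain configuration; the default mirrors the standard protocol
    of 2 chains x 10,000 iterations with the first 5,000 as burn-in."""

    n_chains: int = 2
    n_iter: int = 10_000
    n_burn: int = 5_000
    n_thin: int = 1
    seed: Union[int, np.random.SeedSequence] = 0
    adapt: bool = True
    target_accept: float = _TARGET_ACCEPT

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("require 0 <= n_burn < n_iter")
        if self.n_thin < 1:
            raise ValueError("n_thin must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain."""
        return (self.n_iter - self.n_burn + self.n_thin - 1) // self.n_thin


@dataclass(frozen=True)
class PosteriorSummary:
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class PosteriorDraws:
    """Retained draws, shaped (n_chains, n_draws, *param_shape) per
    block, plus the per-draw deviance under the key ``"deviance"``."""

    model_tag: str
    draws: Dict[str, np.ndarray]
    acceptance: Dict[str, float]
    config: McmcConfig
    priors: PriorSpec

    @property
    def n_chains(self) -> int:
        return self.draws["deviance"].shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return self.draws["deviance"].shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (n_chains * n_draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def monitored_names(self) -> Tuple[str, ...]:
        """Parameter blocks monitored for convergence (binary alpha
        draws are excluded; the deviance is included)."""
        return tuple(n for n in self.draws if n != "alpha")


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


class _AcceptanceTracker:
    def __init__(self):
        self._sums: Dict[str, float] = {}
        self._counts: Dict[str, int] = {}

    def add(self, name: str, accepted_fraction: float) -> None:
        self._sums[name] = self._sums.get(name, 0.0) + accepted_fraction
        self._counts[name] = self._counts.get(name, 0) + 1

    def rates(self) -> Dict[str, float]:
        return {k: self._sums[k] / self._counts[k] for k in self._sums}


class _BaseSampler:
    """Shared state and the slip/guess update.

    Subclasses maintain ``self.w`` (the N x I latent-response/gate
    matrix), and the caches ``p``, ``cell_ll``, ``person_ll``,
    ``item_ll`` derived from it.
    """

    def __init__(self, y, mask, q_entries, priors: PriorSpec, rng: np.random.Generator,
                 target_accept: float):
        self.y = y
        self.mask = mask  # float 0/1 matrix or None (complete data)
        self.q = np.asarray(q_entries, dtype=float)
        self.qT = self.q.T.copy()
        self.N, self.I = y.shape
        self.K = self.q.shape[1]
        self.priors = priors
        self.rng = rng
        self.target = target_accept
        self.track = _AcceptanceTracker()

    # -- cache plumbing ------------------------------------------------

    def _cll(self, p):
        return bernoulli_loglik(self.y, p, self.mask)

    def _refresh_from_w(self):
        self.p = self.g[None, :] + (1.0 - self.s - self.g)[None, :] * self.w
        self.cell_ll = self._cll(self.p)
        self.person_ll = self.cell_ll.sum(axis=1)
        self.item_ll = self.cell_ll.sum(axis=0)

    def deviance(self) -> float:
        return -2.0 * float(self.person_ll.sum())

    def _init_items(self):
        a_s, b_s = self.priors.slip_shapes
        a_g, b_g = self.priors.guess_shapes
        self.s = self.rng.beta(a_s, b_s, self.I)
        g = self.rng.beta(a_g, b_g, self.I)
        for _ in range(1000):
            bad = g >= 1.0 - self.s
            if not bad.any():
                break
            g[bad] = self.rng.beta(a_g, b_g, int(bad.sum()))
        else:
            g = np.minimum(g, (1.0 - self.s) * 0.5)
        self.g = g
        self.log_scale_s = np.full(self.I, np.log(0.3))
        self.log_scale_g = np.full(self.I, np.log(0.3))

    # -- item updates --------------------------------------------------

    def _update_items(self, gamma: float, adapting: bool) -> None:
        rng = self.rng
        for which in ("slip", "guess"):
            if which == "slip":
                cur, a, b, ls = self.s, *self.priors.slip_shapes, self.log_scale_s
            else:
                cur, a, b, ls = self.g, *self.priors.guess_shapes, self.log_scale_g
            prop = expit(_logit(cur) + np.exp(ls) * rng.standard_normal(self.I))
            prop = np.clip(prop, 1e-12, 1.0 - 1e-12)
            if which == "slip":
                valid = prop < 1.0 - self.g
                s_new, g_new = prop, self.g
            else:
                valid = prop < 1.0 - self.s
                s_new, g_new = self.s, prop
            p_prop = g_new[None, :] + (1.0 - s_new - g_new)[None, :] * self.w
            cll_prop = self._cll(p_prop)
            ill_prop = cll_prop.sum(axis=0)
            # Beta prior with the logit-scale Jacobian absorbed:
            # a*log(x) + b*log(1-x)
            lp_prop = a * np.log(prop) + b * np.log1p(-prop)
            lp_cur = a * np.log(cur) + b * np.log1p(-cur)
            log_acc = (ill_prop - self.item_ll) + (lp_prop - lp_cur)
            acc = valid & (np.log(rng.random(self.I)) < log_acc)
            cols = np.flatnonzero(acc)
            if cols.size:
                if which == "slip":
                    self.s[cols] = prop[cols]
                else:
                    self.g[cols] = prop[cols]
                self.p[:, cols] = p_prop[:, cols]
                self.cell_ll[:, cols] = cll_prop[:, cols]
                self.item_ll[cols] = ill_prop[cols]
            if adapting:
                ls += gamma * (acc.astype(float) - self.target)
            else:
                self.track.add(which, float(acc.mean()))
        self.person_ll = self.cell_ll.sum(axis=1)


class _PincSampler(_BaseSampler):
    monitored = ("delta", "slip", "guess")

    def init_state(self):
        a, b = self.priors.delta_shapes
        delta = np.clip(self.rng.beta(a, b, (self.N, self.K)), 1e-6, 1.0 - 1e-6)
        self.x = _logit(delta)
        self.delta = delta
        self.log_delta = _log_sigmoid(self.x)
        # per-attribute item lists: updating delta[:, k] only perturbs
        # the likelihood of items requiring attribute k
        self.cols_k = [np.flatnonzero(self.q[:, k] == 1) for k in range(self.K)]
        self.log_w = self.log_delta @ self.qT
        self.w = np.exp(self.log_w)
        self._init_items()
        self._refresh_from_w()
        self.log_scale_delta = np.zeros((self.N, self.K))
        self._sweep_count = 0

    def sweep(self, gamma: float, adapting: bool):
        rng = self.rng
        a, b = self.priors.delta_shapes
        self._sweep_count += 1
        if self._sweep_count % 500 == 0:  # clear accumulated rounding
            self.log_w = self.log_delta @ self.qT
            self.w = np.exp(self.log_w)
        for k in range(self.K):
            cols = self.cols_k[k]
            x_prop = self.x[:, k] + np.exp(self.log_scale_delta[:, k]) * rng.standard_normal(self.N)
            log_d = _log_sigmoid(x_prop)
            log_1md = _log_sigmoid(-x_prop)
            # q_ik = 1 on these items, so the gate just rescales by delta'/delta
            log_w_prop = self.log_w[:, cols] + (log_d - self.log_delta[:, k])[:, None]
            w_prop = np.exp(log_w_prop)
            coef = (1.0 - self.s - self.g)[cols]
            p_prop = self.g[cols][None, :] + coef[None, :] * w_prop
            mcols = None if self.mask is None else self.mask[:, cols]
            cll_prop = bernoulli_loglik(self.y[:, cols], p_prop, mcols)
            d_ll = cll_prop.sum(axis=1) - self.cell_ll[:, cols].sum(axis=1)
            # Beta(a, b) prior on delta with the logit Jacobian absorbed
            lp_prop = a * log_d + b * log_1md
            lp_cur = a * _log_sigmoid(self.x[:, k]) + b * _log_sigmoid(-self.x[:, k])
            acc = np.log(rng.random(self.N)) < (d_ll + lp_prop - lp_cur)
            rows = np.flatnonzero(acc)
            if rows.size:
                self.x[rows, k] = x_prop[rows]
                self.delta[rows, k] = expit(x_prop[rows])
                self.log_delta[rows, k] = log_d[rows]
                ix = np.ix_(rows, cols)
                self.log_w[ix] = log_w_prop[rows]
                self.w[ix] = w_prop[rows]
                self.p[ix] = p_prop[rows]
                self.cell_ll[ix] = cll_prop[rows]
                self.person_ll[rows] += d_ll[rows]
            if adapting:
                self.log_scale_delta[:, k] += gamma * (acc.astype(float) - self.target)
            else:
                self.track.add("delta", float(acc.mean()))
        self.item_ll = self.cell_ll.sum(axis=0)
        self._update_items(gamma, adapting)

    def snapshot(self):
        return {
            "delta": self.delta.astype(np.float32),
            "slip": self.s.copy(),
            "guess": self.g.copy(),
        }


class _HoPincSampler(_BaseSampler):
    monitored = ("theta", "lambda", "beta", "slip", "guess")

    def init_state(self):
        rng = self.rng
        self.theta = rng.standard_normal(self.N)
        # positive-truncated normal via the reflection identity
        self.lam = np.maximum(np.abs(rng.normal(0.0, self.priors.lambda_sd, self.K)), 1e-3)
        self.beta = rng.normal(0.0, self.priors.beta_sd, self.K)
        m = self.lam[None, :] * self.theta[:, None] - self.beta[None, :]
        self.log_delta = _log_sigmoid(m)
        self.cols_k = [np.flatnonzero(self.q[:, k] == 1) for k in range(self.K)]
        self.log_w = self.log_delta @ self.qT
        self.w = np.exp(self.log_w)
        self._init_items()
        self._refresh_from_w()
        self.log_scale_theta = np.full(self.N, np.log(0.5))
        self.log_scale_lam = np.full(self.K, np.log(0.2))
        self.log_scale_beta = np.full(self.K, np.log(0.2))
        self._sweep_count = 0

    def sweep(self, gamma: float, adapting: bool):
        rng = self.rng
        self._sweep_count += 1
        if self._sweep_count % 500 == 0:  # clear accumulated rounding
            self.log_w = self.log_delta @ self.qT
            self.w = np.exp(self.log_w)
        # ---- theta (per person; every item is affected) -------------
        th_prop = self.theta + np.exp(self.log_scale_theta) * rng.standard_normal(self.N)
        m_prop = self.lam[None, :] * th_prop[:, None] - self.beta[None, :]
        log_delta_prop = _log_sigmoid(m_prop)
        log_w_prop = log_delta_prop @ self.qT
        w_prop = np.exp(log_w_prop)
        p_prop = self.g[None, :] + (1.0 - self.s - self.g)[None, :] * w_prop
        cll_prop = self._cll(p_prop)
        pll_prop = cll_prop.sum(axis=1)
        lp = -0.5 * (th_prop**2 - self.theta**2)  # N(0, 1) prior
        acc = np.log(rng.random(self.N)) < (pll_prop - self.person_ll + lp)
        rows = np.flatnonzero(acc)
        if rows.size:
            self.theta[rows] = th_prop[rows]
            self.log_delta[rows] = log_delta_prop[rows]
            self.log_w[rows] = log_w_prop[rows]
            self.w[rows] = w_prop[rows]
            self.p[rows] = p_prop[rows]
            self.cell_ll[rows] = cll_prop[rows]
            self.person_ll[rows] = pll_prop[rows]
        if adapting:
            self.log_scale_theta += gamma * (acc.astype(float) - self.target)
        else:
            self.track.add("theta", float(acc.mean()))

        # ---- lambda_k, beta_k (scalar random walks) -----------------
        # only items requiring attribute k enter each acceptance ratio
        lam_var = self.priors.lambda_sd**2
        beta_var = self.priors.beta_sd**2
        for k in range(self.K):
            cols = self.cols_k[k]
            coef = (1.0 - self.s - self.g)[cols]
            gc = self.g[cols]
            mcols = None if self.mask is None else self.mask[:, cols]
            for par in ("lambda", "beta"):
                if par == "lambda":
                    step = np.exp(self.log_scale_lam[k])
                    prop = self.lam[k] + step * rng.standard_normal()
                    if prop <= 0.0:  # positive truncation
                        accepted = False
                    else:
                        m_col = prop * self.theta - self.beta[k]
                        lp_d = -(prop**2 - self.lam[k] ** 2) / (2.0 * lam_var)
                        accepted = None
                else:
                    step = np.exp(self.log_scale_beta[k])
                    prop = self.beta[k] + step * rng.standard_normal()
                    m_col = self.lam[k] * self.theta - prop
                    lp_d = -(prop**2 - self.beta[k] ** 2) / (2.0 * beta_var)
                    accepted = None
                if accepted is None:
                    log_d = _log_sigmoid(m_col)
                    log_w_prop = self.log_w[:, cols] + (log_d - self.log_delta[:, k])[:, None]
                    w_prop = np.exp(log_w_prop)
                    p_prop = gc[None, :] + coef[None, :] * w_prop
                    cll_prop = bernoulli_loglik(self.y[:, cols], p_prop, mcols)
                    d_pll = cll_prop.sum(axis=1) - self.cell_ll[:, cols].sum(axis=1)
                    d_ll = float(d_pll.sum())
                    accepted = np.log(rng.random()) < (d_ll + lp_d)
                    if accepted:
                        if par == "lambda":
                            self.lam[k] = prop
                        else:
                            self.beta[k] = prop
                        self.log_delta[:, k] = log_d
                        self.log_w[:, cols] = log_w_prop
                        self.w[:, cols] = w_prop
                        self.p[:, cols] = p_prop
                        self.cell_ll[:, cols] = cll_prop
                        self.person_ll += d_pll
                if adapting:
                    if par == "lambda":
                        self.log_scale_lam[k] += gamma * (float(accepted) - self.target)
                    else:
                        self.log_scale_beta[k] += gamma * (float(accepted) - self.target)
                else:
                    self.track.add(par, float(accepted))

        self.item_ll = self.cell_ll.sum(axis=0)
        self._update_items(gamma, adapting)

    def snapshot(self):
        return {
            "theta": self.theta.astype(np.float32),
            "lambda": self.lam.copy(),
            "beta": self.beta.copy(),
            "slip": self.s.copy(),
            "guess": self.g.copy(),
        }


class _DinaSampler(_BaseSampler):
    monitored = ("slip", "guess")
    higher_order = False

    def init_state(self):
        rng = self.rng
        if self.higher_order:
            self.theta = rng.standard_normal(self.N)
            self.lam = np.maximum(np.abs(rng.normal(0.0, self.priors.lambda_sd, self.K)), 1e-3)
            self.beta = rng.normal(0.0, self.priors.beta_sd, self.K)
            prob = expit(self.lam[None, :] * self.theta[:, None] - self.beta[None, :])
            self.log_scale_theta = np.full(self.N, np.log(0.5))
            self.log_scale_lam = np.full(self.K, np.log(0.2))
            self.log_scale_beta = np.full(self.K, np.log(0.2))
        else:
            prob = np.full((self.N, self.K), self.priors.alpha_base_rate)
        self.alpha = (rng.random((self.N, self.K)) < prob).astype(float)
        self.deficit = (1.0 - self.alpha) @ self.qT  # required-but-missing counts
        self.w = (self.deficit == 0).astype(float)
        self._init_items()
        self._refresh_from_w()

    def _prior_logit(self, k: int) -> np.ndarray:
        if self.higher_order:
            return self.lam[k] * self.theta - self.beta[k]
        r = self.priors.alpha_base_rate
        return np.full(self.N, np.log(r) - np.log1p(-r))

    def sweep(self, gamma: float, adapting: bool):
        rng = self.rng
        # ---- alpha: exact two-point full conditionals ---------------
        for k in range(self.K):
            qk = self.q[:, k]
            cols = np.flatnonzero(qk == 1)
            miss = (1.0 - self.alpha[:, k])[:, None] * qk[None, :]
            d1 = self.deficit - miss          # deficits if alpha_nk = 1
            d0 = d1 + qk[None, :]             # deficits if alpha_nk = 0
            w1 = (d1[:, cols] == 0).astype(float)
            # eta is 0 for every item requiring k when alpha_nk = 0
            p1 = self.g[cols][None, :] + (1.0 - self.s - self.g)[cols][None, :] * w1
            p0 = np.broadcast_to(self.g[cols], (self.N, cols.size))
            ycols = self.y[:, cols]
            mcols = None if self.mask is None else self.mask[:, cols]
            ll1 = bernoulli_loglik(ycols, p1, mcols).sum(axis=1)
            ll0 = bernoulli_loglik(ycols, p0, mcols).sum(axis=1)
            post_logit = self._prior_logit(k) + ll1 - ll0
            new = (rng.random(self.N) < expit(post_logit)).astype(float)
            self.alpha[:, k] = new
            self.deficit = np.where(new[:, None] == 1.0, d1, d0)
        self.w = (self.deficit == 0).astype(float)
        self._refresh_from_w()

        # ---- higher-order structure (sees only Bernoulli(alpha)) ----
        if self.higher_order:
            self._update_structure(gamma, adapting)

        self._update_items(gamma, adapting)

    def _bern_ll_theta(self, theta):
        m = self.lam[None, :] * theta[:, None] - self.beta[None, :]
        return (self.alpha * _log_sigmoid(m) + (1.0 - self.alpha) * _log_sigmoid(-m)).sum(axis=1)

    def _update_structure(self, gamma: float, adapting: bool):
        rng = self.rng
        th_prop = self.theta + np.exp(self.log_scale_theta) * rng.standard_normal(self.N)
        ll_prop = self._bern_ll_theta(th_prop)
        ll_cur = self._bern_ll_theta(self.theta)
        lp = -0.5 * (th_prop**2 - self.theta**2)
        acc = np.log(rng.random(self.N)) < (ll_prop - ll_cur + lp)
        self.theta = np.where(acc, th_prop, self.theta)
        if adapting:
            self.log_scale_theta += gamma * (acc.astype(float) - self.target)
        else:
            self.track.add("theta", float(acc.mean()))

        lam_var = self.priors.lambda_sd**2
        beta_var = self.priors.beta_sd**2
        for k in range(self.K):
            ak = self.alpha[:, k]
            for par in ("lambda", "beta"):
                if par == "lambda":
                    prop = self.lam[k] + np.exp(self.log_scale_lam[k]) * rng.standard_normal()
                    if prop <= 0.0:
                        accepted = False
                    else:
                        m_new = prop * self.theta - self.beta[k]
                        m_old = self.lam[k] * self.theta - self.beta[k]
                        lp_d = -(prop**2 - self.lam[k] ** 2) / (2.0 * lam_var)
                        accepted = None
                else:
                    prop = self.beta[k] + np.exp(self.log_scale_beta[k]) * rng.standard_normal()
                    m_new = self.lam[k] * self.theta - prop
                    m_old = self.lam[k] * self.theta - self.beta[k]
                    lp_d = -(prop**2 - self.beta[k] ** 2) / (2.0 * beta_var)
                    accepted = None
                if accepted is None:
                    ll_new = (ak * _log_sigmoid(m_new) + (1.0 - ak) * _log_sigmoid(-m_new)).sum()
                    ll_old = (ak * _log_sigmoid(m_old) + (1.0 - ak) * _log_sigmoid(-m_old)).sum()
                    accepted = np.log(rng.random()) < (ll_new - ll_old + lp_d)
                    if accepted:
                        if par == "lambda":
                            self.lam[k] = prop
                        else:
                            self.beta[k] = prop
                if adapting:
                    if par == "lambda":
                        self.log_scale_lam[k] += gamma * (float(accepted) - self.target)
                    else:
                        self.log_scale_beta[k] += gamma * (float(accepted) - self.target)
                else:
                    self.track.add(par, float(accepted))

    def snapshot(self):
        out = {
            "alpha": self.alpha.astype(np.int8),
            "slip": self.s.copy(),
            "guess": self.g.copy(),
        }
        if self.higher_order:
            out["theta"] = self.theta.astype(np.float32)
            out["lambda"] = self.lam.copy()
            out["beta"] = self.beta.copy()
        return out


class _HoDinaSampler(_DinaSampler):
    monitored = ("theta", "lambda", "beta", "slip", "guess")
    higher_order = True


_SAMPLERS = {
    "pinc": _PincSampler,
    "ho-pinc": _HoPincSampler,
    "dina": _DinaSampler,
    "ho-dina": _HoDinaSampler,
}

_STORE_DTYPES = {"alpha": np.int8, "delta": np.float32, "theta": np.float32}


def fit_model(
    responses: ResponseMatrix,
    q: QMatrix,
    model_tag: str,
    priors: Optional[PriorSpec] = None,
    config: Optional[McmcConfig] = None,
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent Metropolis-within-Gibbs
    chains from prior-drawn starting points and collect retained draws.

    Refitting with the same configuration and seed reproduces the
    draws exactly.
    """
    tag = str(model_tag).lower()
    if tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    responses.check_paired(q)

    y = responses.entries
    mask = None if responses.is_complete else responses.mask.astype(float)
    obs = responses.mask
    col_means = np.where(obs.sum(0) > 0, (y * obs).sum(0) / np.maximum(obs.sum(0), 1), np.nan)
    degenerate = np.flatnonzero((col_means == 0.0) | (col_means == 1.0))
    if degenerate.size:
        warnings.warn(
            f"items {list(degenerate + 1)} have constant observed responses; "
            "their slip/guess parameters are weakly identified",
            UserWarning,
            stacklevel=2,
        )

    seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_chains)

    M = config.n_retained
    chain_draws = []
    chain_dev = np.empty((config.n_chains, M))
    acc_rates: Dict[str, float] = {}
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        sampler = _SAMPLERS[tag](y, mask, q.entries, priors, rng, config.target_accept)
        sampler.init_state()
        store = None
        idx = 0
        for t in range(config.n_iter):
            adapting = config.adapt and t < config.n_burn
            gamma = (t + 1.0) ** -0.6 if adapting else 0.0
            sampler.sweep(gamma, adapting)
            if t >= config.n_burn and (t - config.n_burn) % config.n_thin == 0:
                snap = sampler.snapshot()
                if store is None:
                    store = {
                        name: np.empty((M,) + arr.shape, dtype=_STORE_DTYPES.get(name, np.float64))
                        for name, arr in snap.items()
                    }
                for name, arr in snap.items():
                    store[name][idx] = arr
                chain_dev[c, idx] = sampler.deviance()
                idx += 1
        chain_draws.append(store)
        for name, rate in sampler.track.rates().items():
            acc_rates[f"chain{c + 1}:{name}"] = rate

    draws = {
        name: np.stack([cd[name] for cd in chain_draws], axis=0)
        for name in chain_draws[0]
    }
    draws["deviance"] = chain_dev
    return PosteriorDraws(
        model_tag=tag, draws=draws, acceptance=acc_rates, config=config, priors=priors
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def eap_estimates(draws: PosteriorDraws) -> Dict[str, PosteriorSummary]:
    """Posterior means and standard deviations pooled across chains.

    For the deterministic models the ``alpha`` mean is also exposed as
    ``"mastery_probability"`` (the per-cell draw frequency of
    alpha = 1).  For HO-PINC a derived ``"delta"`` summary is computed
    by pushing every retained (theta, lambda, beta) draw through the
    logistic link.
    """
    if draws.n_draws < 1:
        raise ValueError("no retained draws")
    out: Dict[str, PosteriorSummary] = {}
    for name in draws.draws:
        pool = draws.pooled(name).astype(np.float64)
        out[name] = PosteriorSummary(mean=pool.mean(axis=0), sd=pool.std(axis=0, ddof=1)
                                     if pool.shape[0] > 1 else np.zeros(pool.shape[1:]))
    if "alpha" in draws.draws:
        out["mastery_probability"] = out["alpha"]
    if draws.model_tag == "ho-pinc":
        th = draws.pooled("theta").astype(np.float64)
        lam = draws.pooled("lambda")
        be = draws.pooled("beta")
        M = th.shape[0]
        s1 = np.zeros((th.shape[1], lam.shape[1]))
        s2 = np.zeros_like(s1)
        chunk = 500
        for lo in range(0, M, chunk):
            hi = min(lo + chunk, M)
            d = expit(lam[lo:hi, None, :] * th[lo:hi, :, None] - be[lo:hi, None, :])
            s1 += d.sum(axis=0)
            s2 += (d * d).sum(axis=0)
        mean = s1 / M
        var = np.maximum(s2 / M - mean**2, 0.0) * (M / max(M - 1, 1))
        out["delta"] = PosteriorSummary(mean=mean, sd=np.sqrt(var))
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def psrf(draws_per_chain) -> float:
    """Univariate Brooks-Gelman potential scale reduction factor.

    ``draws_per_chain`` is an (n_chains, n_draws) array of retained
    draws for one scalar parameter.  A zero within-chain variance
    (constant parameter) returns 1.0 with a warning.
    """
    arr = np.asarray(draws_per_chain, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("PSRF needs at least two chains of equal length")
    if arr.shape[1] < 2:
        raise ValueError("PSRF needs at least two draws per chain")
    return float(_psrf_array(arr))


def _psrf_array(arr: np.ndarray) -> np.ndarray:
    """Vectorized PSRF over trailing parameter axes of (C, M, ...)."""
    arr = arr.astype(np.float64, copy=False)
    C, M = arr.shape[0], arr.shape[1]
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = arr.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (M - 1) / M * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    zero = W == 0
    if np.any(zero):
        warnings.warn(
            "zero within-chain variance for some parameters; PSRF set to 1.0",
            UserWarning,
            stacklevel=2,
        )
        r = np.where(zero, 1.0, r)
    return r


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    threshold: float

    @property
    def max_psrf(self) -> float:
        return float(self.table["psrf"].max())

    @property
    def median_psrf(self) -> float:
        return float(self.table["psrf"].median())

    @property
    def all_converged(self) -> bool:
        return bool((self.table["psrf"] < self.threshold).all())

    def failing(self) -> pd.DataFrame:
        return self.table[self.table["psrf"] >= self.threshold]


def _scalar_labels(name: str, shape: Tuple[int, ...]):
    if not shape:
        return [name]
    idx = np.indices(shape).reshape(len(shape), -1).T + 1  # 1-indexed in reports
    return [name + "[" + ",".join(map(str, row)) + "]" for row in idx]


def convergence_report(draws: PosteriorDraws, threshold: float = 1.2) -> ConvergenceReport:
    """PSRF for every monitored scalar (all person/structural/item
    parameters plus the deviance), with a pass/fail flag at
    ``threshold``."""
    if draws.n_chains < 2:
        raise ValueError("convergence assessment requires at least two chains")
    names, values = [], []
    for name in draws.monitored_names():
        arr = draws.draws[name]
        r = _psrf_array(arr.reshape(arr.shape[0], arr.shape[1], -1))
        names.extend(_scalar_labels(name, arr.shape[2:]))
        values.append(np.atleast_1d(r))
    values = np.concatenate(values)
    table = pd.DataFrame({"parameter": names, "psrf": values})
    table["converged"] = table["psrf"] < threshold
    return ConvergenceReport(table=table, threshold=threshold)
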