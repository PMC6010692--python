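"""Parameter-recovery simulation studies.

A study condition crosses sample size (500 / 1000), test length
(15 / 30 items, structured Q-matrix) and item quality (high: s = g =
0.1; low: s = g = 0.2) for one generating model, runs several
replications, gates each fitted replication on chain convergence
(non-convergent datasets are replaced with freshly simulated ones,
never re-run longer), and scores recovery.

Scoring conventions
-------------------
The generating person parameters are drawn once per condition and held
fixed across replications; each replication redraws only the response
noise.  Two summaries are reported per attribute:

* RMSE -- root mean square error between the true values and the EAP
  estimates, computed over persons within each replication and
  averaged across replications (a pooled variant is also provided;
  the two agree closely for fixed truth).
* Cor -- the Pearson correlation between the true values and the
  estimates *averaged across replications*.  Averaging suppresses the
  per-replication estimation noise, so this measures how well the
  systematic part of the estimator tracks the truth; the average of
  the per-replication correlations is also reported, and is
  substantially lower because single-replication EAP estimates of a
  weakly-informed parameter are noisy.

For the higher-order models the trait theta is scored the same way.
Item slip/guess parameters are scored as per-item RMSE across
replications.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import McmcConfig, PosteriorDraws, PriorSpec, convergence_report, eap_estimates, fit_model
from .simulator import (
    GeneratingConfig,
    build_default_qmatrix,
    simulate_delta_higher_order,
    simulate_delta_independent,
    simulate_responses,
)

__all__ = [
    "rmse",
    "cor",
    "StudyCondition",
    "RecoveryReport",
    "run_condition",
    "run_grid",
    "desk_mcmc",
    "full_mcmc",
    "design_conditions",
]


def rmse(true_values, estimates) -> float:
    """Root mean square error between paired vectors."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if t.shape != e.shape or t.size == 0:
        raise ValueError("inputs must be non-empty vectors of equal length")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def cor(true_values, estimates) -> float:
    """Pearson correlation; returns NaN (with a warning) if either
    input has zero variance."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if t.shape != e.shape or t.size < 2:
        raise ValueError("inputs must be vectors of equal length >= 2")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        warnings.warn("zero-variance input; correlation undefined", UserWarning, stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(t, e)[0])


def desk_mcmc() -> McmcConfig:
    """Reduced-scale chain settings: 2 chains x 3,000 iterations with
    1,500 burn-in."""
    return McmcConfig(n_chains=2, n_iter=3000, n_burn=1500)


def full_mcmc() -> McmcConfig:
    """Full-scale chain settings: 2 chains x 10,000 iterations with
    5,000 burn-in."""
    return McmcConfig(n_chains=2, n_iter=10_000, n_burn=5_000)


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the recovery design."""

    model_tag: str
    n_persons: int = 500
    n_items: int = 15
    item_quality: str = "high"
    replications: int = 20
    mcmc: McmcConfig = field(default_factory=desk_mcmc)
    priors: PriorSpec = field(default_factory=PriorSpec)
    base_seed: int = 0
    psrf_threshold: float = 1.5
    max_attempts: int = 10
    fixed_truth: bool = True
    n_attributes: int = 5

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    def label(self) -> str:
        return (f"{self.model_tag} IQ={self.item_quality} N={self.n_persons} "
                f"I={self.n_items}")

    def generating_config(self, seed) -> GeneratingConfig:
        return GeneratingConfig(
            model_tag=self.model_tag,
            n_persons=self.n_persons,
            n_items=self.n_items,
            n_attributes=self.n_attributes,
            item_quality=self.item_quality,
            seed=seed,
        )


@dataclass
class RecoveryReport:
    """Aggregated recovery results for one study condition."""

    condition: StudyCondition
    delta_rmse: np.ndarray           # per attribute, replication-averaged
    delta_rmse_pooled: np.ndarray
    delta_cor: np.ndarray            # true vs replication-averaged estimate
    delta_cor_per_rep: np.ndarray    # mean of per-replication correlations
    slip_rmse: np.ndarray            # per item, across replications
    guess_rmse: np.ndarray
    theta_rmse: Optional[float] = None
    theta_rmse_pooled: Optional[float] = None
    theta_cor: Optional[float] = None
    theta_cor_per_rep: Optional[float] = None
    n_replications: int = 0
    n_replaced: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per condition x index x parameter)."""
        c = self.condition
        rows = []

        def add(index, parameter, value):
            rows.append({
                "model": c.model_tag, "IQ": c.item_quality, "N": c.n_persons,
                "I": c.n_items, "index": index, "parameter": parameter,
                "value": value,
            })

        for k in range(self.delta_rmse.shape[0]):
            name = f"delta{k + 1}"
            add("RMSE", name, self.delta_rmse[k])
            add("RMSE_pooled", name, self.delta_rmse_pooled[k])
            add("Cor", name, self.delta_cor[k])
            add("Cor_per_rep", name, self.delta_cor_per_rep[k])
        if self.theta_rmse is not None:
            add("RMSE", "theta", self.theta_rmse)
            add("RMSE_pooled", "theta", self.theta_rmse_pooled)
            add("Cor", "theta", self.theta_cor)
            add("Cor_per_rep", "theta", self.theta_cor_per_rep)
        for i in range(self.slip_rmse.shape[0]):
            add("RMSE", f"slip{i + 1}", self.slip_rmse[i])
            add("RMSE", f"guess{i + 1}", self.guess_rmse[i])
        add("meta", "replications_used", float(self.n_replications))
        add("meta", "datasets_replaced", float(self.n_replaced))
        return pd.DataFrame(rows)


def _condition_seed(cond: StudyCondition, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=cond.base_seed, spawn_key=tuple(key))


def _draw_truth(cond: StudyCondition):
    """Generating person parameters for a condition (spawn key 0)."""
    seed = _condition_seed(cond, 0)
    cfg = cond.generating_config(seed)
    tag = cfg.model_tag
    if tag == "pinc":
        a, b = cfg.beta_shape
        delta = simulate_delta_independent(cfg.n_persons, cfg.n_attributes, a, b, seed)
        return {"delta": delta, "theta": None, "alpha": None}
    if tag in ("ho-pinc", "ho-dina"):
        lam, be = cfg.higher_order_values()
        theta, delta = simulate_delta_higher_order(cfg.n_persons, lam, be, seed)
        return {"delta": delta, "theta": theta, "alpha": None}
    # dina: a fixed binary profile
    rng = np.random.default_rng(seed)
    alpha = (rng.random((cfg.n_persons, cfg.n_attributes)) < cfg.base_rate).astype(np.int8)
    from .model_core import AttributeProfileMatrix

    return {"delta": None, "theta": None, "alpha": AttributeProfileMatrix(alpha)}


def _person_estimates(draws: PosteriorDraws):
    """(delta-like estimate matrix, theta estimate or None)."""
    eap = eap_estimates(draws)
    if draws.model_tag in ("pinc", "ho-pinc"):
        est = eap["delta"].mean
    else:
        est = eap["mastery_probability"].mean
    theta_est = eap["theta"].mean if "theta" in draws.draws else None
    return est, theta_est, eap["slip"].mean, eap["guess"].mean


def _load_checkpoint(path: Optional[Path]) -> Dict[int, dict]:
    done: Dict[int, dict] = {}
    if path is None or not Path(path).exists():
        return done
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            done[int(rec["replication"])] = rec
    return done


def run_condition(
    cond: StudyCondition,
    checkpoint: Optional[Path] = None,
    progress: bool = False,
) -> RecoveryReport:
    """Simulate, fit and score every replication of one condition.

    Each replication derives its data and chain seeds deterministically
    from (base_seed, replication, attempt), so any replication can be
    reproduced in isolation.  A replication whose maximum PSRF reaches
    ``psrf_threshold`` is discarded and its dataset replaced by a
    freshly simulated one (up to ``max_attempts`` times).  If
    ``checkpoint`` is given, finished replications are appended there
    as JSON lines and skipped on re-runs.
    """
    truth = _draw_truth(cond)
    true_delta = truth["delta"].delta if truth["delta"] is not None else None
    true_theta = truth["theta"]
    true_alpha = truth["alpha"].alpha if truth["alpha"] is not None else None
    items_true = cond.generating_config(0).item_parameters()

    done = _load_checkpoint(checkpoint)
    est_list, theta_list, slip_list, guess_list = [], [], [], []
    n_replaced = 0
    for r in range(cond.replications):
        if r in done:
            rec = done[r]
            est_list.append(np.asarray(rec["person_estimate"]))
            if rec.get("theta_estimate") is not None:
                theta_list.append(np.asarray(rec["theta_estimate"]))
            slip_list.append(np.asarray(rec["slip_estimate"]))
            guess_list.append(np.asarray(rec["guess_estimate"]))
            n_replaced += int(rec.get("attempts_used", 1)) - 1
            continue
        for attempt in range(cond.max_attempts):
            data_seed = _condition_seed(cond, 1, r, attempt)
            chain_seed = _condition_seed(cond, 2, r, attempt)
            kwargs = {}
            if cond.fixed_truth:
                if cond.model_tag == "pinc":
                    kwargs["delta"] = truth["delta"]
                elif cond.model_tag in ("ho-pinc", "ho-dina"):
                    kwargs["theta"] = true_theta
                else:
                    kwargs["alpha"] = truth["alpha"]
            sim = simulate_responses(cond.generating_config(data_seed), **kwargs)
            draws = fit_model(
                sim.responses, sim.q, cond.model_tag, priors=cond.priors,
                config=replace(cond.mcmc, seed=chain_seed),
            )
            report = convergence_report(draws, threshold=cond.psrf_threshold)
            if report.all_converged:
                break
            n_replaced += 1
            if progress:
                print(f"  [{cond.label()}] rep {r + 1}: max PSRF "
                      f"{report.max_psrf:.3f} >= {cond.psrf_threshold}; replacing dataset")
        else:
            raise RuntimeError(
                f"replication {r + 1} of condition '{cond.label()}' failed to "
                f"converge in {cond.max_attempts} attempts "
                f"(last max PSRF {report.max_psrf:.3f})"
            )
        est, theta_est, slip_est, guess_est = _person_estimates(draws)
        if not cond.fixed_truth:
            # score against this replication's own truth; correlation of
            # averaged estimates is not defined across different persons
            if cond.model_tag == "pinc" or cond.model_tag == "ho-pinc":
                this_true = sim.delta.delta
            else:
                this_true = sim.alpha.alpha
            est = np.stack([this_true, est])  # packed (true, est) pair
            if theta_est is not None:
                theta_est = np.stack([sim.theta, theta_est])
        est_list.append(est)
        if theta_est is not None:
            theta_list.append(theta_est)
        slip_list.append(slip_est)
        guess_list.append(guess_est)
        if checkpoint is not None:
            rec = {
                "replication": r,
                "attempts_used": attempt + 1,
                "person_estimate": np.asarray(est).tolist(),
                "theta_estimate": None if theta_est is None else np.asarray(theta_est).tolist(),
                "slip_estimate": slip_est.tolist(),
                "guess_estimate": guess_est.tolist(),
            }
            with open(checkpoint, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        if progress:
            print(f"  [{cond.label()}] replication {r + 1}/{cond.replications} done")

    return _score(cond, true_delta, true_theta, true_alpha, items_true,
                  est_list, theta_list, slip_list, guess_list, n_replaced)


def _score(cond, true_delta, true_theta, true_alpha, items_true,
           est_list, theta_list, slip_list, guess_list, n_replaced) -> RecoveryReport:
    K = cond.n_attributes
    if cond.fixed_truth:
        target = true_delta if true_delta is not None else true_alpha.astype(float)
        ests = np.stack(est_list)                      # (R, N, K)
        per_rep_rmse = np.sqrt(((ests - target[None]) ** 2).mean(axis=1))  # (R, K)
        d_rmse = per_rep_rmse.mean(axis=0)
        d_rmse_pooled = np.sqrt((per_rep_rmse**2).mean(axis=0))
        mean_est = ests.mean(axis=0)
        d_cor = np.array([cor(target[:, k], mean_est[:, k]) for k in range(K)])
        d_cor_rep = np.array([
            np.mean([cor(target[:, k], ests[r, :, k]) for r in range(ests.shape[0])])
            for k in range(K)
        ])
        th_rmse = th_rmse_pooled = th_cor = th_cor_rep = None
        if theta_list:
            th = np.stack(theta_list)                  # (R, N)
            rep_rmse = np.sqrt(((th - true_theta[None]) ** 2).mean(axis=1))
            th_rmse = float(rep_rmse.mean())
            th_rmse_pooled = float(np.sqrt((rep_rmse**2).mean()))
            th_cor = cor(true_theta, th.mean(axis=0))
            th_cor_rep = float(np.mean([cor(true_theta, th[r]) for r in range(th.shape[0])]))
    else:
        pairs = est_list                               # list of (2, N, K) packs
        per_rep_rmse = np.stack([
            np.sqrt(((p[1] - p[0]) ** 2).mean(axis=0)) for p in pairs
        ])
        d_rmse = per_rep_rmse.mean(axis=0)
        d_rmse_pooled = np.sqrt((per_rep_rmse**2).mean(axis=0))
        d_cor_rep = np.array([
            np.mean([cor(p[0][:, k], p[1][:, k]) for p in pairs]) for k in range(K)
        ])
        d_cor = d_cor_rep.copy()
        th_rmse = th_rmse_pooled = th_cor = th_cor_rep = None
        if theta_list:
            rep_rmse = np.array([np.sqrt(((p[1] - p[0]) ** 2).mean()) for p in theta_list])
            th_rmse = float(rep_rmse.mean())
            th_rmse_pooled = float(np.sqrt((rep_rmse**2).mean()))
            th_cor_rep = float(np.mean([cor(p[0], p[1]) for p in theta_list]))
            th_cor = th_cor_rep

    slips = np.stack(slip_list)
    guesses = np.stack(guess_list)
    s_rmse = np.sqrt(((slips - items_true.slip[None]) ** 2).mean(axis=0))
    g_rmse = np.sqrt(((guesses - items_true.guess[None]) ** 2).mean(axis=0))
    return RecoveryReport(
        condition=cond,
        delta_rmse=d_rmse,
        delta_rmse_pooled=d_rmse_pooled,
        delta_cor=d_cor,
        delta_cor_per_rep=d_cor_rep,
        slip_rmse=s_rmse,
        guess_rmse=g_rmse,
        theta_rmse=th_rmse,
        theta_rmse_pooled=th_rmse_pooled,
        theta_cor=th_cor,
        theta_cor_per_rep=th_cor_rep,
        n_replications=cond.replications,
        n_replaced=n_replaced,
    )


def design_conditions(
    model_tag: str,
    replications: int = 20,
    mcmc: Optional[McmcConfig] = None,
    base_seed: int = 0,
    psrf_threshold: float = 1.5,
) -> List[StudyCondition]:
    """The full 2 x 2 x 2 recovery grid (N x I x item quality) for one
    model, with per-condition derived seeds."""
    mcmc = mcmc or desk_mcmc()
    conds = []
    idx = 0
    for iq in ("high", "low"):
        for n in (500, 1000):
            for i in (15, 30):
                conds.append(StudyCondition(
                    model_tag=model_tag, n_persons=n, n_items=i, item_quality=iq,
                    replications=replications, mcmc=mcmc,
                    base_seed=base_seed * 1000 + idx, psrf_threshold=psrf_threshold,
                ))
                idx += 1
    return conds


def run_grid(
    conditions: Sequence[StudyCondition],
    checkpoint_dir: Optional[Path] = None,
    progress: bool = False,
) -> Tuple[pd.DataFrame, Dict[str, RecoveryReport]]:
    """Run several conditions; per-condition failures are collected and
    reported, not fatal to the rest of the grid."""
    if not conditions:
        raise ValueError("empty condition list")
    frames, reports, failures = [], {}, {}
    for j, cond in enumerate(conditions):
        ckpt = None
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir) / f"condition_{j:02d}.jsonl"
        try:
            rep = run_condition(cond, checkpoint=ckpt, progress=progress)
        except Exception as exc:  # noqa: BLE001 - sibling conditions continue
            failures[cond.label()] = str(exc)
            continue
        reports[cond.label()] = rep
        frames.append(rep.to_frame())
    if failures and not reports:
        raise RuntimeError(f"every condition failed: {failures}")
    if failures:
        warnings.warn(f"conditions failed: {failures}", UserWarning, stacklevel=2)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, reports
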