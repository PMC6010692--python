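"""Sampler behavior: diagnostics, summaries, constraints, determinism."""

import numpy as np
import pytest

from pincdm.mcmc import (
    McmcConfig,
    PosteriorDraws,
    PriorSpec,
    convergence_report,
    eap_estimates,
    fit_model,
    psrf,
)
from pincdm.model_core import ResponseMatrix
from pincdm.simulator import GeneratingConfig, build_default_qmatrix, random_qmatrix, simulate_responses

TINY = McmcConfig(n_chains=2, n_iter=400, n_burn=200, seed=0)


def _tiny_fit(model_tag, n=40, seed=0, config=TINY):
    sim = simulate_responses(GeneratingConfig(model_tag, n, 15, seed=seed))
    return sim, fit_model(sim.responses, sim.q, model_tag, config=config)


# ------------------------------------------------------------- PSRF

def test_psrf_identical_chains_at_lower_bound():
    rng = np.random.default_rng(0)
    x = rng.normal(size=1000)
    r = psrf(np.stack([x, x]))
    # B = 0 collapses the estimator to sqrt((n-1)/n)
    assert r == pytest.approx(np.sqrt(999 / 1000), abs=1e-12)
    assert r <= 1.0005


def test_psrf_matches_independent_formula():
    """Vectorized estimator equals an explicitly coded Brooks-Gelman
    computation."""
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(3, 200))
    M = 200
    W = np.mean([c.var(ddof=1) for c in chains])
    means = chains.mean(axis=1)
    B_over_n = np.var(means, ddof=1)
    expected = np.sqrt(((M - 1) / M * W + B_over_n) / W)
    assert psrf(chains) == pytest.approx(expected, abs=1e-12)


def test_psrf_well_mixed_versus_separated():
    rng = np.random.default_rng(2)
    same = rng.normal(size=(2, 5000))
    assert psrf(same) < 1.05
    apart = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert psrf(apart) > 1.2


def test_psrf_constant_chain_warns():
    with pytest.warns(UserWarning, match="zero within-chain variance"):
        assert psrf(np.zeros((2, 100))) == 1.0


def test_psrf_input_validation():
    with pytest.raises(ValueError):
        psrf(np.zeros((1, 100)))
    with pytest.raises(ValueError):
        psrf(np.zeros((2, 1)))


# ------------------------------------------------------ EAP summaries

def _draws_from(arrs, model_tag="pinc"):
    draws = {k: np.asarray(v) for k, v in arrs.items()}
    n_chains, n_draws = next(iter(draws.values())).shape[:2]
    if "deviance" not in draws:
        draws["deviance"] = np.zeros((n_chains, n_draws))
    return PosteriorDraws(model_tag=model_tag, draws=draws, acceptance={},
                          config=McmcConfig(n_chains=n_chains, n_iter=2 * n_draws,
                                            n_burn=n_draws), priors=PriorSpec())


def test_eap_constant_draws():
    d = _draws_from({"slip": np.full((2, 10, 3), 0.25)})
    eap = eap_estimates(d)
    assert np.allclose(eap["slip"].mean, 0.25)
    assert np.allclose(eap["slip"].sd, 0.0)


def test_eap_alpha_frequency():
    alpha = np.array([[[[1]], [[1]], [[0]], [[1]]]], dtype=np.int8)  # (1,4,1,1)
    d = _draws_from({"alpha": alpha}, model_tag="dina")
    eap = eap_estimates(d)
    assert eap["mastery_probability"].mean[0, 0] == pytest.approx(0.75)


def test_eap_pooled_equals_weighted_chain_means():
    rng = np.random.default_rng(3)
    arr = rng.random((2, 50, 4))
    d = _draws_from({"guess": arr})
    eap = eap_estimates(d)
    assert np.allclose(eap["guess"].mean, arr.mean(axis=(0, 1)))


# ----------------------------------------------------- chain behavior

def test_fit_same_seed_reproduces_draws():
    _, a = _tiny_fit("pinc", seed=1)
    _, b = _tiny_fit("pinc", seed=1)
    for name in a.draws:
        assert np.array_equal(a.draws[name], b.draws[name])


def test_constraints_hold_in_every_retained_draw():
    for tag in ("pinc", "ho-pinc", "dina", "ho-dina"):
        _, d = _tiny_fit(tag, seed=2)
        s = d.pooled("slip")
        g = d.pooled("guess")
        assert (g < 1.0 - s).all()
        if "lambda" in d.draws:
            assert (d.pooled("lambda") > 0).all()
        if "delta" in d.draws:
            dd = d.pooled("delta")
            assert ((dd > 0) & (dd < 1)).all()


def test_prior_only_posterior_matches_beta_prior():
    """With every response masked the delta posterior is the Beta(1, 1)
    prior: mean 1/2, variance 1/12."""
    q = random_qmatrix(6, 2, {1: 1.0}, seed=0)
    y = ResponseMatrix(np.full((40, 6), np.nan))
    cfg = McmcConfig(n_chains=2, n_iter=1500, n_burn=500, seed=4)
    d = fit_model(y, q, "pinc", config=cfg)
    pool = d.pooled("delta").astype(float)
    assert abs(pool.mean() - 0.5) < 0.05
    assert abs(pool.var() - 1.0 / 12.0) < 0.02


def test_person_exchangeability_statistical():
    """Permuting person rows permutes the delta estimates (up to
    Monte-Carlo error; proposal noise is drawn positionally, so the
    chains are not bit-identical)."""
    sim = simulate_responses(GeneratingConfig("pinc", 30, 15, seed=5))
    cfg = McmcConfig(n_chains=2, n_iter=1500, n_burn=500, seed=6)
    d1 = fit_model(sim.responses, sim.q, "pinc", config=cfg)
    perm = np.random.default_rng(7).permutation(30)
    d2 = fit_model(ResponseMatrix(sim.responses.entries[perm]), sim.q, "pinc", config=cfg)
    e1 = eap_estimates(d1)["delta"].mean
    e2 = eap_estimates(d2)["delta"].mean
    assert np.abs(e1[perm] - e2).mean() < 0.04


def test_degenerate_column_warns_not_fails():
    sim = simulate_responses(GeneratingConfig("pinc", 25, 15, seed=8))
    y = sim.responses.entries.copy()
    y[:, 3] = 1.0
    with pytest.warns(UserWarning, match="constant observed responses"):
        fit_model(ResponseMatrix(y), sim.q, "pinc", config=TINY)


def test_config_validation_and_retained_count():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=100, n_burn=100)
    cfg = McmcConfig(n_chains=3, n_iter=1000, n_burn=400, n_thin=3)
    assert cfg.n_retained == 200
    _, d = _tiny_fit("pinc", config=McmcConfig(n_chains=2, n_iter=300, n_burn=100,
                                               n_thin=2, seed=9))
    assert d.n_draws == 100 and d.n_chains == 2


# -------------------------------------------------- convergence report

def test_convergence_report_monitors_all_scalars():
    _, d = _tiny_fit("pinc", n=20, seed=10)
    rep = convergence_report(d, threshold=1.2)
    n_delta = 20 * 5
    assert len(rep.table) == n_delta + 15 + 15 + 1  # delta + slip + guess + deviance
    assert set(rep.table.columns) == {"parameter", "psrf", "converged"}
    assert "deviance" in set(rep.table["parameter"])


def test_convergence_report_needs_two_chains():
    sim = simulate_responses(GeneratingConfig("pinc", 15, 15, seed=11))
    d = fit_model(sim.responses, sim.q, "pinc",
                  config=McmcConfig(n_chains=1, n_iter=200, n_burn=100, seed=0))
    with pytest.raises(ValueError, match="two chains"):
        convergence_report(d)


def test_ho_dina_monitors_structural_parameters():
    _, d = _tiny_fit("ho-dina", n=25, seed=12)
    names = d.monitored_names()
    assert "theta" in names and "lambda" in names and "alpha" not in names
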