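"""Response functions: condensation rules, probability maps, likelihood."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pincdm.model_core import (
    AttributeProfileMatrix,
    HigherOrderParameters,
    ItemParameterSet,
    MasteryProbabilityMatrix,
    QMatrix,
    ResponseMatrix,
    conjunctive_condensation,
    higher_order_mastery_probability,
    latent_response_matrix,
    log_likelihood,
    model_probability_matrix,
    probabilistic_latent_response,
    response_probability_dina,
    response_probability_pinc,
)
from pincdm.simulator import build_default_qmatrix


# --------------------------------------------------------------- gates

@pytest.mark.parametrize(
    "x, q, expected",
    [
        ((1, 1, 0), (1, 1, 0), 1),   # all required attributes mastered
        ((1, 0, 1), (1, 1, 0), 0),   # one required attribute missing
        ((0, 0, 0), (0, 0, 0), 1),   # empty product convention 0**0 = 1
    ],
)
def test_conjunctive_condensation_examples(x, q, expected):
    assert conjunctive_condensation(x, q) == expected


def test_condensation_length_mismatch():
    with pytest.raises(ValueError):
        conjunctive_condensation((1, 1), (1, 1, 0))


@given(st.lists(st.integers(0, 1), min_size=1, max_size=8), st.data())
def test_condensation_ignores_unrequired_attributes(q, data):
    """Flipping attributes the item does not require never changes eta."""
    q = np.array(q)
    x = np.array(data.draw(st.lists(st.integers(0, 1), min_size=len(q), max_size=len(q))))
    base = conjunctive_condensation(x, q)
    x2 = x.copy()
    x2[q == 0] = 1 - x2[q == 0]
    assert conjunctive_condensation(x2, q) == base


@pytest.mark.parametrize(
    "d, q, expected",
    [
        ((1.0, 1.0, 1.0), (1, 1, 1), 1.0),
        ((0.5, 0.5, 0.9), (1, 1, 0), 0.25),   # third attribute not required
        ((0.3, 0.3), (0, 0), 1.0),            # empty product
    ],
)
def test_probabilistic_latent_response_examples(d, q, expected):
    assert probabilistic_latent_response(d, q) == pytest.approx(expected)


def test_probabilistic_latent_response_domain_error():
    with pytest.raises(ValueError):
        probabilistic_latent_response((1.2, 0.5), (1, 1))


@given(st.data())
def test_latent_response_monotone_in_required_delta(data):
    """rho is non-decreasing in each required delta and constant in the rest."""
    K = data.draw(st.integers(1, 5))
    q = np.array(data.draw(st.lists(st.integers(0, 1), min_size=K, max_size=K)))
    d = np.random.default_rng(data.draw(st.integers(0, 10_000))).random(K)
    base = probabilistic_latent_response(d, q)
    k = data.draw(st.integers(0, K - 1))
    d2 = d.copy()
    d2[k] = min(1.0, d[k] + 0.3)
    bumped = probabilistic_latent_response(d2, q)
    if q[k] == 1:
        assert bumped >= base - 1e-12
    else:
        assert bumped == pytest.approx(base)


# ------------------------------------------------- response functions

@pytest.mark.parametrize(
    "d, q, s, g, expected",
    [
        ((1.0, 1.0), (1, 1), 0.1, 0.1, 0.9),     # rho=1 gives 1-s
        ((0.5, 0.5), (1, 1), 0.1, 0.1, 0.3),     # 0.1 + 0.8*0.25
        ((0.0, 1.0), (1, 1), 0.2, 0.2, 0.2),     # rho=0 gives g
    ],
)
def test_response_probability_pinc_examples(d, q, s, g, expected):
    assert response_probability_pinc(d, q, s, g) == pytest.approx(expected)


def test_response_probability_monotonicity_violation():
    with pytest.raises(ValueError):
        response_probability_pinc((0.5,), (1,), 0.6, 0.5)


@pytest.mark.parametrize(
    "a, q, s, g, expected",
    [
        ((1, 1), (1, 1), 0.1, 0.2, 0.9),
        ((1, 0), (1, 1), 0.1, 0.2, 0.2),
    ],
)
def test_response_probability_dina_examples(a, q, s, g, expected):
    assert response_probability_dina(a, q, s, g) == pytest.approx(expected)


@given(st.lists(st.integers(0, 1), min_size=1, max_size=6), st.data())
def test_pinc_reduces_to_dina_at_binary_delta(alpha, data):
    q = np.array(data.draw(
        st.lists(st.integers(0, 1), min_size=len(alpha), max_size=len(alpha))))
    a = np.array(alpha)
    p_dina = response_probability_dina(a, q, 0.15, 0.1)
    p_pinc = response_probability_pinc(a.astype(float), q, 0.15, 0.1)
    assert p_pinc == p_dina


# ------------------------------------------------ higher-order link

def test_higher_order_link_values():
    assert higher_order_mastery_probability(0.0, 1.5, 0.0) == pytest.approx(0.5)
    # logistic(1), frozen from the closed form exp(1)/(1+exp(1))
    assert higher_order_mastery_probability(0.0, 1.5, -1.0) == pytest.approx(
        0.7310585786300049, abs=1e-12)
    assert higher_order_mastery_probability(1e3, 1.5, 0.0) == pytest.approx(1.0)
    assert higher_order_mastery_probability(-1e3, 1.5, 0.0) == pytest.approx(0.0)


def test_higher_order_link_rejects_nonpositive_slope():
    with pytest.raises(ValueError):
        higher_order_mastery_probability(0.0, -0.5, 0.0)


def test_higher_order_link_increasing_in_theta(rng):
    th = np.sort(rng.normal(size=50))
    d = higher_order_mastery_probability(th, 1.5, 0.3)
    assert (np.diff(d) >= 0).all()


# ---------------------------------------------------- log-likelihood

def test_log_likelihood_forced_arithmetic():
    y = np.array([[1.0, 0.0]])
    p = np.array([[0.5, 0.5]])
    assert log_likelihood(y, p) == pytest.approx(2 * np.log(0.5))


def test_log_likelihood_matches_brute_force(rng):
    """Vectorized likelihood equals an independent cell-by-cell loop."""
    for _ in range(5):
        y = (rng.random((5, 5)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (5, 5))
        expected = 0.0
        for n in range(5):
            for i in range(5):
                expected += (np.log(p[n, i]) if y[n, i] == 1
                             else np.log(1 - p[n, i]))
        assert log_likelihood(y, p) == pytest.approx(expected, abs=1e-12)


def test_log_likelihood_missing_cells_contribute_zero(rng):
    y = (rng.random((4, 3)) < 0.5).astype(float)
    p = rng.uniform(0.2, 0.8, (4, 3))
    full = log_likelihood(y, p)
    y_missing = y.copy()
    y_missing[0, 0] = np.nan
    reduced = log_likelihood(ResponseMatrix(y_missing), p)
    cell = np.log(p[0, 0]) if y[0, 0] == 1 else np.log(1 - p[0, 0])
    assert reduced == pytest.approx(full - cell, abs=1e-12)


def test_log_likelihood_shape_mismatch():
    with pytest.raises(ValueError):
        log_likelihood(np.ones((2, 2)), np.full((2, 3), 0.5))


# ------------------------------------------- model probability matrix

@pytest.fixture(scope="module")
def q15():
    return build_default_qmatrix(15)


def _items(I, s=0.1, g=0.1):
    return ItemParameterSet(slip=np.full(I, s), guess=np.full(I, g))


def test_pinc_all_mastered_hits_ceiling(q15):
    delta = MasteryProbabilityMatrix(np.ones((4, 5)))
    p = model_probability_matrix("pinc", delta, _items(15, s=0.15, g=0.1), q15)
    assert np.allclose(p, 0.85)


def test_ho_pinc_theta_zero_frozen_deltas(q15):
    """At theta=0, lambda=1.5, beta=(-1,-.5,0,.5,1) the implied mastery
    probabilities are the logistic values (0.731, 0.622, 0.5, 0.378, 0.269)."""
    ho = HigherOrderParameters(theta=np.zeros(2), slope=np.full(5, 1.5),
                               intercept=np.array([-1, -0.5, 0, 0.5, 1.0]))
    d = ho.mastery_probabilities().delta
    assert np.allclose(d[0], [0.73105858, 0.62245933, 0.5, 0.37754067, 0.26894142])
    p = model_probability_matrix("ho-pinc", ho, _items(15), q15)
    # single-attribute item 1 requires only attribute 1
    assert p[0, 0] == pytest.approx(0.1 + 0.8 * 0.73105858)


def test_dina_equals_pinc_at_binary_profiles(q15, rng):
    alpha = (rng.random((20, 5)) < 0.5).astype(int)
    items = _items(15, s=0.12, g=0.08)
    p_dina = model_probability_matrix("dina", AttributeProfileMatrix(alpha), items, q15)
    p_pinc = model_probability_matrix(
        "pinc", MasteryProbabilityMatrix(alpha.astype(float)), items, q15)
    assert np.array_equal(p_dina, p_pinc)


def test_probability_range_invariant(q15, rng):
    """Every model probability lies in [g_i, 1 - s_i]."""
    s = rng.uniform(0.05, 0.3, 15)
    g = rng.uniform(0.05, 0.3, 15)
    g = np.minimum(g, 1 - s - 0.05)
    items = ItemParameterSet(slip=s, guess=g)
    delta = MasteryProbabilityMatrix(rng.random((30, 5)))
    p = model_probability_matrix("pinc", delta, items, q15)
    assert (p >= g[None, :] - 1e-12).all() and (p <= 1 - s[None, :] + 1e-12).all()


def test_ho_pinc_collapses_to_ho_dina_at_steep_slope(q15):
    """With lambda=50 the logistic link is near-deterministic, so HO-PINC
    probabilities approach HO-DINA's conditional on alpha = 1{theta > beta/lambda}."""
    rng = np.random.default_rng(3)
    theta = rng.normal(size=200)
    beta = np.array([-1, -0.5, 0, 0.5, 1.0])
    # keep persons whose trait is not within the narrow transition band
    # around any threshold beta_k / lambda
    theta = theta[np.abs(theta[:, None] - beta[None, :] / 50.0).min(axis=1) > 0.3][:40]
    ho = HigherOrderParameters(theta=theta, slope=np.full(5, 50.0), intercept=beta)
    alpha = (50.0 * theta[:, None] - beta[None, :] > 0).astype(int)
    items = _items(15)
    p_ho = model_probability_matrix("ho-pinc", ho, items, q15)
    p_dina = model_probability_matrix("ho-dina", AttributeProfileMatrix(alpha), items, q15)
    assert np.allclose(p_ho, p_dina, atol=1e-4)


def test_model_dispatch_rejects_wrong_pairings(q15):
    delta = MasteryProbabilityMatrix(np.full((3, 5), 0.5))
    with pytest.raises(TypeError):
        model_probability_matrix("dina", delta, _items(15), q15)
    with pytest.raises(TypeError):
        model_probability_matrix("ho-pinc", delta, _items(15), q15)
    with pytest.raises(ValueError):
        model_probability_matrix("nonsense", delta, _items(15), q15)


# ------------------------------------------------------- containers

def test_qmatrix_rejects_empty_item_row():
    with pytest.raises(ValueError, match="measure no attribute"):
        QMatrix(np.array([[1, 0], [0, 0]]))


def test_qmatrix_warns_on_unmeasured_attribute():
    with pytest.warns(UserWarning, match="measured by no item"):
        QMatrix(np.array([[1, 0], [1, 0]]))


def test_qmatrix_rejects_nonbinary():
    with pytest.raises(ValueError):
        QMatrix(np.array([[1, 2]]))


def test_response_matrix_masks_nan():
    y = np.array([[1.0, np.nan], [0.0, 1.0]])
    r = ResponseMatrix(y)
    assert r.mask.sum() == 3 and not r.is_complete
    with pytest.raises(ValueError):
        ResponseMatrix(np.array([[0.5]]))


def test_item_parameter_constraint_is_strict():
    with pytest.raises(ValueError, match="monotonicity"):
        ItemParameterSet(slip=np.array([0.5]), guess=np.array([0.5]))
    ItemParameterSet(slip=np.array([0.5]), guess=np.array([0.49]))  # ok


def test_latent_response_matrix_handles_zero_delta(q15):
    d = np.zeros((2, 5))
    w = latent_response_matrix(d, q15.entries)
    assert np.allclose(w, 0.0)
    d_one = np.ones((2, 5))
    assert np.allclose(latent_response_matrix(d_one, q15.entries), 1.0)
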