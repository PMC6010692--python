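"""Response functions and shared containers for conjunctive cognitive
diagnosis models.

Four model variants share one signal-detection item response function,

    P(Y_ni = 1) = g_i + (1 - s_i - g_i) * w_ni,

where ``w_ni`` is the latent (ideal) response of person ``n`` to item
``i`` and ``s_i`` / ``g_i`` are the item's slip and guessing
probabilities (with the monotonicity restriction ``g_i < 1 - s_i``):

* DINA / HO-DINA: ``w = eta = prod_k alpha_nk ** q_ik`` -- a binary
  conjunctive ("and") gate over the attributes the Q-matrix requires
  for the item, driven by a binary mastery profile ``alpha``.
* PINC / HO-PINC: ``w = rho = prod_k delta_nk ** q_ik`` -- the same
  gate applied to per-person mastery *probabilities* ``delta`` in
  [0, 1], so attribute mastery is probabilistic rather than
  deterministic.

The higher-order (HO-) variants derive the person parameters from a
single latent trait ``theta`` through a logistic link,

    delta_nk = logistic(lambda_k * theta_n - beta_k),

with positive attribute slopes ``lambda_k`` and intercepts ``beta_k``.
PINC reduces exactly to DINA when every ``delta`` is 0 or 1; the HO
variants coincide in the limit of an infinitely steep link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "EPS",
    "MODEL_TAGS",
    "QMatrix",
    "ResponseMatrix",
    "ItemParameterSet",
    "MasteryProbabilityMatrix",
    "AttributeProfileMatrix",
    "HigherOrderParameters",
    "conjunctive_condensation",
    "probabilistic_latent_response",
    "latent_response_matrix",
    "response_probability_pinc",
    "response_probability_dina",
    "higher_order_mastery_probability",
    "bernoulli_loglik",
    "log_likelihood",
    "model_probability_matrix",
]

#: floor/ceiling applied to probabilities before any logarithm
EPS = 1e-10

#: floor for delta inside the log-space condensation product
_TINY = 1e-300

MODEL_TAGS = ("dina", "ho-dina", "pinc", "ho-pinc")


def _default_ids(prefix: str, n: int) -> tuple:
    return tuple(f"{prefix}{j + 1}" for j in range(n))


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-attribute design matrix.

    ``entries[i, k] == 1`` means item ``i`` requires attribute ``k``.
    Items that measure no attribute are rejected; attributes measured
    by no item only trigger a warning, because the corresponding person
    parameters are simply unidentified (their posterior returns the
    prior).
    """

    entries: np.ndarray
    item_ids: Optional[Sequence[str]] = None
    attribute_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        e = np.asarray(self.entries)
        if e.ndim != 2:
            raise ValueError("Q-matrix must be 2-D (items x attributes)")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("Q-matrix entries must all be 0 or 1")
        e = e.astype(np.int8)
        empty_rows = np.flatnonzero(e.sum(axis=1) == 0)
        if empty_rows.size:
            raise ValueError(
                f"items {list(empty_rows + 1)} measure no attribute; every "
                "item row of the Q-matrix needs at least one 1"
            )
        empty_cols = np.flatnonzero(e.sum(axis=0) == 0)
        if empty_cols.size:
            warnings.warn(
                f"attributes {list(empty_cols + 1)} are measured by no item; "
                "their mastery parameters are unidentified and the posterior "
                "will return the prior",
                UserWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "entries", e)
        item_ids = self.item_ids or _default_ids("I", e.shape[0])
        attr_ids = self.attribute_ids or _default_ids("A", e.shape[1])
        if len(item_ids) != e.shape[0] or len(attr_ids) != e.shape[1]:
            raise ValueError("id labels do not match Q-matrix shape")
        object.__setattr__(self, "item_ids", tuple(item_ids))
        object.__setattr__(self, "attribute_ids", tuple(attr_ids))

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @property
    def required_counts(self) -> np.ndarray:
        """Number of attributes each item requires (row sums)."""
        return self.entries.sum(axis=1)


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary person-by-item response matrix with an optional missing mask.

    ``entries`` may contain NaN for missing cells; internally the data
    are stored as a dense 0/1 float matrix plus a boolean ``mask``
    (True = observed).  Missing cells contribute nothing to any
    likelihood.
    """

    entries: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2:
            raise ValueError("response matrix must be 2-D (persons x items)")
        nan_mask = np.isnan(e)
        if self.mask is None:
            mask = ~nan_mask
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != e.shape:
                raise ValueError("mask shape must match response shape")
            mask = mask & ~nan_mask
        vals = e[mask]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("observed responses must all be 0 or 1")
        y = np.where(mask, np.nan_to_num(e), 0.0)
        object.__setattr__(self, "entries", y)
        object.__setattr__(self, "mask", mask)

    @property
    def n_persons(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def check_paired(self, q: QMatrix) -> None:
        if self.n_items != q.n_items:
            raise ValueError(
                f"response matrix has {self.n_items} items but the "
                f"Q-matrix has {q.n_items}"
            )


@dataclass(frozen=True)
class ItemParameterSet:
    """Per-item slip ``s_i`` and guess ``g_i`` with ``g_i < 1 - s_i``."""

    slip: np.ndarray
    guess: np.ndarray

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.slip, dtype=float))
        g = np.atleast_1d(np.asarray(self.guess, dtype=float))
        if s.shape != g.shape or s.ndim != 1:
            raise ValueError("slip and guess must be 1-D vectors of equal length")
        if (s < 0).any() or (g < 0).any():
            raise ValueError("slip and guess must be non-negative")
        if (g >= 1.0 - s).any():
            bad = np.flatnonzero(g >= 1.0 - s)
            raise ValueError(
                f"monotonicity violated (g >= 1 - s) for items {list(bad + 1)}"
            )
        object.__setattr__(self, "slip", s)
        object.__setattr__(self, "guess", g)

    @property
    def n_items(self) -> int:
        return self.slip.shape[0]


@dataclass(frozen=True)
class MasteryProbabilityMatrix:
    """Person-by-attribute mastery probabilities ``delta`` in [0, 1]."""

    delta: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 2:
            raise ValueError("delta must be 2-D (persons x attributes)")
        if (d < 0).any() or (d > 1).any() or np.isnan(d).any():
            raise ValueError("delta entries must lie in [0, 1]")
        object.__setattr__(self, "delta", d)

    @property
    def n_persons(self) -> int:
        return self.delta.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.delta.shape[1]


@dataclass(frozen=True)
class AttributeProfileMatrix:
    """Binary person-by-attribute mastery profiles ``alpha``."""

    alpha: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha)
        if a.ndim != 2:
            raise ValueError("alpha must be 2-D (persons x attributes)")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("alpha entries must all be 0 or 1")
        object.__setattr__(self, "alpha", a.astype(np.int8))

    @property
    def n_persons(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.alpha.shape[1]


@dataclass(frozen=True)
class HigherOrderParameters:
    """Higher-order trait ``theta`` plus per-attribute slopes/intercepts.

    ``theta`` lives on the standard-normal scale; ``slope`` must be
    strictly positive (matching the truncated prior used in
    estimation).
    """

    theta: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray

    def __post_init__(self):
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        lam = np.atleast_1d(np.asarray(self.slope, dtype=float))
        be = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        if lam.shape != be.shape:
            raise ValueError("slope and intercept must have equal length")
        if (lam <= 0).any():
            raise ValueError("attribute slopes must be strictly positive")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "slope", lam)
        object.__setattr__(self, "intercept", be)

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.slope.shape[0]

    def mastery_probabilities(self) -> MasteryProbabilityMatrix:
        """Map (theta, lambda, beta) to the implied delta matrix."""
        d = higher_order_mastery_probability(
            self.theta[:, None], self.slope[None, :], self.intercept[None, :]
        )
        return MasteryProbabilityMatrix(d)


# ---------------------------------------------------------------------------
# elementary response functions
# ---------------------------------------------------------------------------


def conjunctive_condensation(profile_row, q_row) -> int:
    """Binary AND gate: prod_k x_k ** q_k with the 0**0 = 1 convention.

    Returns 1 iff every attribute the item requires is mastered;
    attributes the item does not require never matter.
    """
    x = np.asarray(profile_row)
    q = np.asarray(q_row)
    if x.shape != q.shape:
        raise ValueError("profile and Q-matrix rows have different lengths")
    return int(np.all(x[q == 1] == 1))


def probabilistic_latent_response(delta_row, q_row) -> float:
    """Probabilistic gate rho = prod_k delta_k ** q_k (0**0 = 1)."""
    d = np.asarray(delta_row, dtype=float)
    q = np.asarray(q_row)
    if d.shape != q.shape:
        raise ValueError("delta and Q-matrix rows have different lengths")
    if (d < 0).any() or (d > 1).any():
        raise ValueError("delta entries must lie in [0, 1]")
    return float(np.prod(np.where(q == 1, d, 1.0)))


def latent_response_matrix(delta: np.ndarray, q_entries: np.ndarray) -> np.ndarray:
    """Vectorized rho (or eta) matrix: N x I gate values.

    Computed as exp(log(delta) @ Q') so the cost is one BLAS matmul;
    deltas are floored at a denormal-safe constant, which only matters
    for cells whose exact gate value is 0 anyway.
    """
    d = np.asarray(delta, dtype=float)
    logd = np.log(np.maximum(d, _TINY))
    return np.exp(logd @ np.asarray(q_entries, dtype=float).T)


def _check_item_pair(s: float, g: float) -> None:
    if s < 0 or g < 0 or g >= 1.0 - s:
        raise ValueError(f"item parameters violate g < 1 - s (s={s}, g={g})")


def response_probability_pinc(delta_row, q_row, s: float, g: float) -> float:
    """PINC correct-response probability g + (1 - s - g) * rho."""
    _check_item_pair(s, g)
    rho = probabilistic_latent_response(delta_row, q_row)
    return g + (1.0 - s - g) * rho


def response_probability_dina(alpha_row, q_row, s: float, g: float) -> float:
    """DINA correct-response probability g + (1 - s - g) * eta."""
    _check_item_pair(s, g)
    eta = conjunctive_condensation(alpha_row, q_row)
    return g + (1.0 - s - g) * eta


def higher_order_mastery_probability(theta, slope, intercept):
    """Logistic link delta = exp(lam*th - b) / (1 + exp(lam*th - b)).

    Vectorized and numerically stable for large |lam*theta - beta|.
    """
    lam = np.asarray(slope, dtype=float)
    if (lam <= 0).any():
        raise ValueError("attribute slope must be strictly positive")
    out = expit(lam * np.asarray(theta, dtype=float) - np.asarray(intercept, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def bernoulli_loglik(y: np.ndarray, p: np.ndarray, mask=None) -> np.ndarray:
    """Cellwise Bernoulli log-likelihood with probabilities clamped to
    (EPS, 1 - EPS); masked (missing) cells contribute exactly 0."""
    pc = np.clip(p, EPS, 1.0 - EPS)
    out = y * np.log(pc) + (1.0 - y) * np.log1p(-pc)
    if mask is not None:
        out = out * mask
    return out


def log_likelihood(responses: Union[ResponseMatrix, np.ndarray], probabilities) -> float:
    """Total Bernoulli log-likelihood over all observed cells."""
    if isinstance(responses, ResponseMatrix):
        y, mask = responses.entries, responses.mask
    else:
        y = np.asarray(responses, dtype=float)
        mask = ~np.isnan(y)
        y = np.where(mask, np.nan_to_num(y), 0.0)
        mask = None if mask.all() else mask
    p = np.asarray(probabilities, dtype=float)
    if p.shape != y.shape:
        raise ValueError(
            f"probability matrix shape {p.shape} does not match "
            f"response shape {y.shape}"
        )
    return float(bernoulli_loglik(y, p, mask).sum())


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

PersonParams = Union[MasteryProbabilityMatrix, AttributeProfileMatrix, HigherOrderParameters]


def model_probability_matrix(
    model_tag: str,
    person_params: PersonParams,
    item_params: ItemParameterSet,
    q: QMatrix,
) -> np.ndarray:
    """N x I matrix of correct-response probabilities for any variant.

    Accepted pairings:

    * ``pinc``    -- :class:`MasteryProbabilityMatrix`
    * ``dina``    -- :class:`AttributeProfileMatrix`
    * ``ho-pinc`` -- :class:`HigherOrderParameters` (mapped to delta
      through the logistic link, then gated)
    * ``ho-dina`` -- :class:`AttributeProfileMatrix` for the response
      probabilities conditional on a realized profile, or
      :class:`HigherOrderParameters` for the probabilities marginal
      over alpha (which coincide with the HO-PINC expression).

    Every entry lies in [g_i, 1 - s_i] for its column.
    """
    tag = str(model_tag).lower()
    if tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")
    if item_params.n_items != q.n_items:
        raise ValueError("item parameter vectors do not match the Q-matrix item count")

    if tag == "pinc":
        if not isinstance(person_params, MasteryProbabilityMatrix):
            raise TypeError("PINC requires a MasteryProbabilityMatrix")
        delta = person_params.delta
    elif tag == "ho-pinc":
        if not isinstance(person_params, HigherOrderParameters):
            raise TypeError("HO-PINC requires HigherOrderParameters")
        delta = person_params.mastery_probabilities().delta
    elif tag == "dina":
        if not isinstance(person_params, AttributeProfileMatrix):
            raise TypeError("DINA requires an AttributeProfileMatrix")
        delta = person_params.alpha.astype(float)
    else:  # ho-dina
        if isinstance(person_params, AttributeProfileMatrix):
            delta = person_params.alpha.astype(float)
        elif isinstance(person_params, HigherOrderParameters):
            delta = person_params.mastery_probabilities().delta
        else:
            raise TypeError(
                "HO-DINA requires an AttributeProfileMatrix (conditional) or "
                "HigherOrderParameters (marginal over alpha)"
            )
    if delta.shape[1] != q.n_attributes:
        raise ValueError("person parameters do not match the Q-matrix attribute count")
    w = latent_response_matrix(delta, q.entries)
    s, g = item_params.slip, item_params.guess
    return g[None, :] + (1.0 - s - g)[None, :] * w
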