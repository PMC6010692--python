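"""Synthetic data generation for the DINA/PINC model family.

The generators emulate the standard parameter-recovery design for these
models: K = 5 attributes, a structured Q-matrix whose first five items
are single-attribute "pure" items, the next five load adjacent
attribute pairs and the last five load three or more attributes (the
30-item form repeats the 15-item block); independent mastery
probabilities delta ~ Beta(1, 1) for PINC; theta ~ N(0, 1) with slopes
lambda_k = 1.5 and intercepts beta = (-1, -0.5, 0, 0.5, 1) for the
higher-order variants; and item quality levels high (s = g = 0.1) or
low (s = g = 0.2).

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np

from .model_core import (
    AttributeProfileMatrix,
    HigherOrderParameters,
    ItemParameterSet,
    MasteryProbabilityMatrix,
    MODEL_TAGS,
    QMatrix,
    ResponseMatrix,
    higher_order_mastery_probability,
    model_probability_matrix,
)

__all__ = [
    "ITEM_QUALITY_LEVELS",
    "DEFAULT_HO_SLOPE",
    "default_ho_intercepts",
    "GeneratingConfig",
    "SimulatedData",
    "build_default_qmatrix",
    "random_qmatrix",
    "simulate_delta_independent",
    "simulate_delta_higher_order",
    "simulate_responses",
]

#: slip = guess value for the two standard item-quality levels
ITEM_QUALITY_LEVELS = {"high": 0.1, "low": 0.2}

#: common attribute slope for higher-order generation
DEFAULT_HO_SLOPE = 1.5

# required-attribute sets of the structured 15-item block (1-indexed)
_BASE15 = (
    {1}, {2}, {3}, {4}, {5},
    {1, 2}, {2, 3}, {3, 4}, {4, 5}, {5, 1},
    {1, 2, 3}, {2, 3, 4}, {3, 4, 5}, {1, 2, 3, 4}, {1, 2, 3, 4, 5},
)


def default_ho_intercepts(n_attributes: int) -> np.ndarray:
    """Evenly spaced intercepts from -1 to 1 (the 5-attribute default
    is (-1, -0.5, 0, 0.5, 1))."""
    if n_attributes == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n_attributes)


SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneratingConfig:
    """Everything needed to simulate one response dataset.

    ``item_quality`` is ``"high"`` (s = g = 0.1), ``"low"``
    (s = g = 0.2), or an explicit ``(slip, guess)`` pair of vectors or
    scalars.  ``beta_shape`` parameterizes the Beta distribution of the
    independent mastery probabilities (PINC); ``ho_slope`` /
    ``ho_intercept`` are the higher-order generating values (HO
    variants).  ``base_rate`` is the marginal mastery probability used
    to draw alpha for the plain DINA model.
    """

    model_tag: str
    n_persons: int
    n_items: int
    n_attributes: int = 5
    item_quality: Union[str, Tuple] = "high"
    beta_shape: Tuple[float, float] = (1.0, 1.0)
    ho_slope: Optional[np.ndarray] = None
    ho_intercept: Optional[np.ndarray] = None
    base_rate: float = 0.5
    seed: SeedLike = 0

    def __post_init__(self):
        if str(self.model_tag).lower() not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}")
        object.__setattr__(self, "model_tag", str(self.model_tag).lower())
        if self.n_persons <= 0 or self.n_items <= 0 or self.n_attributes <= 0:
            raise ValueError("N, I and K must all be positive")
        a, b = self.beta_shape
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        # validate the item-quality setting early
        self.item_parameters()

    def item_parameters(self) -> ItemParameterSet:
        iq = self.item_quality
        if isinstance(iq, str):
            try:
                v = ITEM_QUALITY_LEVELS[iq.lower()]
            except KeyError:
                raise ValueError(
                    f"item quality must be one of {sorted(ITEM_QUALITY_LEVELS)} "
                    "or an explicit (slip, guess) pair"
                ) from None
            s = np.full(self.n_items, v)
            g = np.full(self.n_items, v)
        else:
            s, g = iq
            s = np.broadcast_to(np.asarray(s, dtype=float), (self.n_items,)).copy()
            g = np.broadcast_to(np.asarray(g, dtype=float), (self.n_items,)).copy()
        return ItemParameterSet(slip=s, guess=g)

    def higher_order_values(self) -> Tuple[np.ndarray, np.ndarray]:
        lam = self.ho_slope
        if lam is None:
            lam = np.full(self.n_attributes, DEFAULT_HO_SLOPE)
        lam = np.broadcast_to(np.asarray(lam, dtype=float), (self.n_attributes,)).copy()
        be = self.ho_intercept
        if be is None:
            be = default_ho_intercepts(self.n_attributes)
        be = np.broadcast_to(np.asarray(be, dtype=float), (self.n_attributes,)).copy()
        if (lam <= 0).any():
            raise ValueError("higher-order slopes must be strictly positive")
        return lam, be


@dataclass(frozen=True)
class SimulatedData:
    """A simulated response matrix plus the generating truth."""

    responses: ResponseMatrix
    q: QMatrix
    item_params: ItemParameterSet
    delta: Optional[MasteryProbabilityMatrix] = None
    alpha: Optional[AttributeProfileMatrix] = None
    theta: Optional[np.ndarray] = None
    ho_slope: Optional[np.ndarray] = None
    ho_intercept: Optional[np.ndarray] = None
    model_tag: str = "pinc"

    def truth_dict(self) -> Dict:
        """JSON-serializable bundle of the generating values."""
        out: Dict = {
            "model_tag": self.model_tag,
            "slip": self.item_params.slip.tolist(),
            "guess": self.item_params.guess.tolist(),
        }
        if self.delta is not None:
            out["delta"] = self.delta.delta.tolist()
        if self.alpha is not None:
            out["alpha"] = self.alpha.alpha.tolist()
        if self.theta is not None:
            out["theta"] = self.theta.tolist()
        if self.ho_slope is not None:
            out["ho_slope"] = self.ho_slope.tolist()
            out["ho_intercept"] = self.ho_intercept.tolist()
        return out


def build_default_qmatrix(n_items: int, n_attributes: int = 5) -> QMatrix:
    """The structured 5-attribute Q-matrix used in the recovery design.

    Items 1-5 are pure single-attribute items (an identity block),
    items 6-10 load the adjacent pairs (1,2), (2,3), (3,4), (4,5),
    (5,1), and items 11-15 load (1,2,3), (2,3,4), (3,4,5), (1,2,3,4)
    and all five attributes.  The 30-item form repeats the 15-item
    block, so items 16-30 are identical to items 1-15.
    """
    if n_attributes != 5 or n_items not in (15, 30):
        raise ValueError(
            "the structured design is defined for I in {15, 30} and K = 5; "
            "use random_qmatrix() for other sizes"
        )
    base = np.zeros((15, 5), dtype=np.int8)
    for i, attrs in enumerate(_BASE15):
        for k in attrs:
            base[i, k - 1] = 1
    entries = base if n_items == 15 else np.vstack([base, base])
    return QMatrix(entries)


def random_qmatrix(
    n_items: int,
    n_attributes: int,
    complexity_weights: Optional[Mapping[int, float]] = None,
    seed: SeedLike = None,
    max_tries: int = 1000,
) -> QMatrix:
    """Random Q-matrix with a given distribution over the number of
    required attributes per item; retries until every attribute is
    measured at least once."""
    if complexity_weights is None:
        complexity_weights = {1: 0.5, 2: 0.3, 3: 0.2}
    counts = np.array(sorted(complexity_weights), dtype=int)
    if (counts < 1).any() or (counts > n_attributes).any():
        raise ValueError("required-attribute counts must lie in [1, K]")
    w = np.array([complexity_weights[c] for c in counts], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("complexity weights must be non-negative and not all zero")
    w = w / w.sum()
    if n_items < n_attributes and counts.max() * n_items < n_attributes:
        raise ValueError("cannot cover every attribute with this configuration")
    rng = _rng(seed)
    for _ in range(max_tries):
        entries = np.zeros((n_items, n_attributes), dtype=np.int8)
        row_counts = rng.choice(counts, size=n_items, p=w)
        for i, c in enumerate(row_counts):
            cols = rng.choice(n_attributes, size=int(c), replace=False)
            entries[i, cols] = 1
        if (entries.sum(axis=0) > 0).all():
            return QMatrix(entries)
    raise ValueError(
        "failed to generate a Q-matrix covering every attribute; "
        "check the complexity weights"
    )


def simulate_delta_independent(
    n_persons: int,
    n_attributes: int,
    a_delta: float = 1.0,
    b_delta: float = 1.0,
    seed: SeedLike = None,
) -> MasteryProbabilityMatrix:
    """i.i.d. Beta(a, b) mastery probabilities (uniform for a = b = 1)."""
    if a_delta <= 0 or b_delta <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = _rng(seed)
    return MasteryProbabilityMatrix(rng.beta(a_delta, b_delta, size=(n_persons, n_attributes)))


def simulate_delta_higher_order(
    n_persons: int,
    slope: np.ndarray,
    intercept: np.ndarray,
    seed: SeedLike = None,
) -> Tuple[np.ndarray, MasteryProbabilityMatrix]:
    """Draw theta ~ N(0, 1) and map through the logistic link.

    Returns the trait vector and the implied delta matrix; columns with
    larger intercepts have smaller mean mastery probabilities.
    """
    lam = np.atleast_1d(np.asarray(slope, dtype=float))
    be = np.atleast_1d(np.asarray(intercept, dtype=float))
    if lam.shape != be.shape:
        raise ValueError("slope and intercept vectors must have equal length")
    rng = _rng(seed)
    theta = rng.standard_normal(n_persons)
    delta = higher_order_mastery_probability(theta[:, None], lam[None, :], be[None, :])
    return theta, MasteryProbabilityMatrix(delta)


def simulate_responses(
    config: GeneratingConfig,
    q: Optional[QMatrix] = None,
    alpha: Optional[AttributeProfileMatrix] = None,
    delta: Optional[MasteryProbabilityMatrix] = None,
    theta: Optional[np.ndarray] = None,
) -> SimulatedData:
    """Simulate Y ~ Bernoulli(p) under the configured model.

    PINC draws delta ~ Beta(a, b); HO-PINC draws theta ~ N(0, 1) and
    maps it to delta.  For HO-DINA a binary profile alpha is drawn from
    Bernoulli(delta) before the gate is applied; for plain DINA alpha
    may be supplied directly, otherwise alpha_nk ~ Bernoulli(base_rate).

    Person parameters (``delta`` for PINC, ``theta`` for the HO
    variants, ``alpha`` for DINA) may be passed in explicitly, in which
    case only the response noise (and, for HO-DINA, the profile draw)
    is fresh.  This supports recovery designs that hold the generating
    person parameters fixed while replicating the response process.
    """
    if q is None:
        q = build_default_qmatrix(config.n_items, config.n_attributes)
    if q.n_items != config.n_items or q.n_attributes != config.n_attributes:
        raise ValueError("Q-matrix dimensions do not match the generating config")
    rng = _rng(config.seed)
    items = config.item_parameters()
    tag = config.model_tag

    lam = be = None
    alpha_out = None
    if tag == "pinc":
        if delta is None:
            a, b = config.beta_shape
            delta = simulate_delta_independent(config.n_persons, config.n_attributes, a, b, rng)
        elif delta.delta.shape != (config.n_persons, config.n_attributes):
            raise ValueError("supplied delta does not match the generating config")
        theta = None
        p = model_probability_matrix("pinc", delta, items, q)
    elif tag in ("ho-pinc", "ho-dina"):
        lam, be = config.higher_order_values()
        if theta is None:
            theta, delta = simulate_delta_higher_order(config.n_persons, lam, be, rng)
        else:
            theta = np.asarray(theta, dtype=float)
            if theta.shape != (config.n_persons,):
                raise ValueError("supplied theta does not match the generating config")
            delta = MasteryProbabilityMatrix(
                higher_order_mastery_probability(theta[:, None], lam[None, :], be[None, :])
            )
        if tag == "ho-pinc":
            p = model_probability_matrix("pinc", delta, items, q)
        else:
            alpha_out = AttributeProfileMatrix(
                (rng.random(delta.delta.shape) < delta.delta).astype(np.int8)
            )
            p = model_probability_matrix("dina", alpha_out, items, q)
    else:  # dina
        delta = theta = None
        if alpha is not None:
            if alpha.alpha.shape != (config.n_persons, config.n_attributes):
                raise ValueError("supplied alpha does not match the generating config")
            alpha_out = alpha
        else:
            alpha_out = AttributeProfileMatrix(
                (rng.random((config.n_persons, config.n_attributes)) < config.base_rate
                 ).astype(np.int8)
            )
        p = model_probability_matrix("dina", alpha_out, items, q)

    y = (rng.random(p.shape) < p).astype(float)
    return SimulatedData(
        responses=ResponseMatrix(y),
        q=q,
        item_params=items,
        delta=delta,
        alpha=alpha_out,
        theta=theta,
        ho_slope=lam,
        ho_intercept=be,
        model_tag=tag,
    )
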