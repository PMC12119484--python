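"""Distribution-level health-equity mathematics.

Given a distribution of a nonnegative effect (health outcome, access
probability, life-years) over units — persons or subpopulations, optionally
population-weighted — this module computes the standard inequality toolkit:
the empirical Lorenz curve, the Gini coefficient, the Atkinson index with its
equally-distributed-equivalent (EDE) level, and the Rawlsian leximin ordering.
It also provides the relative (health-adjusted) life-expectancy fraction used
to compare absolute versus relative effectiveness of life-saving treatments.

All formulas are population-weighted so that subpopulation-level outcome
tables can be scored directly; with unit weights they reduce to the familiar
per-person definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError

__all__ = [
    "Distribution",
    "LorenzCurve",
    "lorenz_curve",
    "gini",
    "atkinson",
    "leximin_compare",
    "relative_hale_fraction",
    "n_subpopulations",
]


@dataclass(frozen=True)
class Distribution:
    """Nonnegative effect values with positive population weights."""

    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise DataError("values must be a non-empty 1-d array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise DataError("values must be finite and nonnegative")
        if self.weights is None:
            weights = np.ones_like(values)
        else:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != values.shape:
                raise DataError("weights must match values in shape")
            if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
                raise DataError("weights must be finite and strictly positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    @property
    def mean(self) -> float:
        """Population-weighted mean effect."""
        return float(np.average(self.values, weights=self.weights))


def _as_distribution(dist) -> Distribution:
    if isinstance(dist, Distribution):
        return dist
    return Distribution(np.asarray(dist, dtype=float))


@dataclass(frozen=True)
class LorenzCurve:
    """Piecewise-linear empirical Lorenz curve.

    Vertices run from (0, 0) to (1, 1); ``p`` is the cumulative population
    share and ``L`` the cumulative effect share after sorting units by value
    ascending, so the curve is convex and lies on or below the diagonal
    line of equality.
    """

    p: np.ndarray
    L: np.ndarray

    def gap_area(self) -> float:
        """Trapezoid area between the diagonal and the curve."""
        return 0.5 - float(np.trapezoid(self.L, self.p))


def lorenz_curve(dist) -> LorenzCurve:
    """Empirical Lorenz curve of a weighted distribution.

    Units are sorted by value ascending; cumulative population share against
    cumulative effect share. Perfect equality yields the diagonal.
    """
    dist = _as_distribution(dist)
    total = float(np.sum(dist.values * dist.weights))
    if total <= 0:
        raise DomainError("Lorenz curve undefined: total effect is zero")
    order = np.argsort(dist.values, kind="stable")
    v, w = dist.values[order], dist.weights[order]
    p = np.concatenate([[0.0], np.cumsum(w) / np.sum(w)])
    L = np.concatenate([[0.0], np.cumsum(v * w) / total])
    p[-1] = 1.0
    L[-1] = 1.0
    return LorenzCurve(p=p, L=L)


def gini(dist) -> float:
    """Gini coefficient in [0, 1).

    Computed as the weighted mean absolute difference normalized by twice the
    mean, Σ wᵢwⱼ|xᵢ−xⱼ| / (2 (Σw)² μ), which for the empirical distribution
    equals twice the area between the Lorenz curve and the line of equality.
    0 is perfect equality; (n−1)/n → 1 is one unit holding everything.
    """
    dist = _as_distribution(dist)
    mu = dist.mean
    if mu <= 0:
        raise DomainError("Gini undefined: total effect is zero")
    order = np.argsort(dist.values, kind="stable")
    v, w = dist.values[order], dist.weights[order]
    W = np.sum(w)
    cw = np.cumsum(w)
    # Sorted-form identity for the weighted mean absolute difference:
    # G = Σ v_i w_i (2·cw_i − w_i − W) / (W² μ)   with cw the inclusive cumsum.
    g = float(np.sum(v * w * (2.0 * cw - w - W)) / (W * W * mu))
    return g


def atkinson(dist, epsilon: float = 0.5) -> tuple[float, float]:
    """Atkinson inequality index and equally-distributed equivalent.

    The EDE is the weighted generalized mean of order (1−ε) — the geometric
    mean at ε=1 — i.e. the uniform effect level a society with the given
    inequality aversion ε would accept in exchange for the observed unequal
    distribution. The index is 1 − EDE/μ, the fraction of total effect the
    population could sacrifice while keeping welfare constant. ε=0 is the
    utilitarian limit (index 0); larger ε weighs the worst-off more.

    Returns ``(index, ede)``.
    """
    dist = _as_distribution(dist)
    if epsilon < 0:
        raise DomainError("epsilon must be >= 0")
    mu = dist.mean
    if mu <= 0:
        raise DomainError("Atkinson undefined: mean effect is zero")
    v, w = dist.values, dist.weights
    wn = w / np.sum(w)
    if epsilon >= 1 and np.any(v <= 0):
        raise DomainError(
            "Atkinson with epsilon >= 1 requires strictly positive values"
        )
    if epsilon == 0:
        ede = mu
    elif epsilon == 1:
        ede = float(np.exp(np.sum(wn * np.log(v))))
    else:
        r = 1.0 - epsilon
        ede = float(np.sum(wn * np.power(v, r)) ** (1.0 / r))
    index = 1.0 - ede / mu
    # guard tiny negative round-off for near-equal distributions
    if -1e-12 < index < 0:
        index = 0.0
    return index, ede


def leximin_compare(groups_a, groups_b) -> str:
    """Rawlsian leximin comparison of two group-effect vectors.

    Sort both ascending and compare lexicographically; the first strict
    difference decides. Returns ``"a_better"``, ``"b_better"`` or ``"equal"``.
    """
    a = np.sort(np.asarray(groups_a, dtype=float))
    b = np.sort(np.asarray(groups_b, dtype=float))
    if a.shape != b.shape:
        raise DataError("leximin_compare requires equal group counts")
    for x, y in zip(a, b):
        if x > y:
            return "a_better"
        if x < y:
            return "b_better"
    return "equal"


def relative_hale_fraction(
    age_at_treatment_years: float,
    years_gained: float,
    original_hale_years: float,
) -> float:
    """Fraction of original (health-adjusted) life expectancy attained.

    A patient treated at a given age who gains ``years_gained`` life-years
    reaches (age + gained) / original_hale of the (HA)LE they would have had:
    e.g. a 30-year-old gaining 25 years against an original HALE of 80 attains
    (30+25)/80 = 0.69, while a 55-year-old gaining the same 25 years returns
    to the full original (HA)LE.
    """
    if original_hale_years <= 0:
        raise DomainError("original_hale_years must be > 0")
    if age_at_treatment_years < 0 or years_gained < 0:
        raise DomainError("age and years gained must be >= 0")
    return (age_at_treatment_years + years_gained) / original_hale_years


def n_subpopulations(dimensions: dict[str, int] | list[int]) -> int:
    """Number of joint subpopulations from per-dimension level counts.

    E.g. age(3) × gender(2) × insurance(2) × blood type(4) = 48.
    """
    counts = list(dimensions.values()) if isinstance(dimensions, dict) else list(dimensions)
    if not counts or any(int(c) < 1 for c in counts):
        raise DataError("every equity dimension needs at least one level")
    return int(math.prod(int(c) for c in counts))
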