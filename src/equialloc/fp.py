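"""Family-planning outreach: visit-frequency allocation under a budget.

A mobile team with a fixed annual budget of operating days must choose how
many visits per year to pay each outreach site, from a small set of
admissible frequencies (default every one, three or six months: 12, 4 or 2
visits/year; one visit consumes one team-day). A site's expected yearly
client visits follow its concave response curve, and an equity-weighted
objective up-weights client visits at sites with large shares of young or
low-access clients (default weight 1.5).

Three allocators of decreasing explainability:

* :func:`allocate_equal` — the same frequency for every site;
* :func:`allocate_greedy` — rank sites by average clients per visit at the
  reference frequency and walk the ranking assigning the highest affordable
  category while reserving the minimum category for the remaining sites;
* :func:`allocate_exact` — exact dynamic program over (site, remaining
  budget) maximizing the equity-weighted objective.

:func:`optimality_gap` scores any plan against the exact optimum on both the
effectiveness and the equity-weighted objective, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, FeasibilityError
from .synthetic import Site, response_value

__all__ = [
    "FPBudget",
    "FPObjectiveConfig",
    "VisitPlan",
    "plan_scores",
    "allocate_equal",
    "allocate_greedy",
    "allocate_exact",
    "optimality_gap",
]


@dataclass
class FPBudget:
    """Annual team-day budget and admissible visit frequencies."""

    team_days_per_year: int = 220
    n_teams: int = 1
    categories: tuple[int, ...] = (12, 4, 2)

    def __post_init__(self) -> None:
        if self.team_days_per_year <= 0 or self.n_teams <= 0:
            raise ConfigurationError("budget and n_teams must be > 0")
        cats = tuple(int(c) for c in self.categories)
        if len(cats) != len(set(cats)) or any(c <= 0 for c in cats):
            raise ConfigurationError("categories must be positive and distinct")
        self.categories = tuple(sorted(cats, reverse=True))

    @property
    def total_days(self) -> int:
        return self.team_days_per_year * self.n_teams


@dataclass
class FPObjectiveConfig:
    """Equity weighting of priority-subpopulation client visits."""

    priority_weight: float = 1.5

    def __post_init__(self) -> None:
        if self.priority_weight < 1.0:
            raise ConfigurationError("priority_weight must be >= 1")


@dataclass
class VisitPlan:
    """Visits/year per site (aligned with the site list that produced it)."""

    visits_per_year: tuple[int, ...]

    def total_days(self) -> int:
        return int(sum(self.visits_per_year))


def _site_weight(site: Site, objective: FPObjectiveConfig) -> float:
    # priority shares may overlap; the priority fraction is clipped at 1
    priority = min(1.0, site.young_share + site.low_access_share)
    return 1.0 + (objective.priority_weight - 1.0) * priority


def _check_plan(plan: VisitPlan, sites: list[Site], budget: FPBudget) -> None:
    if len(plan.visits_per_year) != len(sites):
        raise FeasibilityError("plan length does not match the site list")
    allowed = set(budget.categories) | {0}
    bad = [f for f in plan.visits_per_year if f not in allowed]
    if bad:
        raise FeasibilityError(f"frequencies {bad} are not admissible categories")
    if plan.total_days() > budget.total_days:
        raise FeasibilityError(
            f"plan uses {plan.total_days()} team-days, budget is {budget.total_days}"
        )


def plan_scores(
    plan: VisitPlan,
    sites: list[Site],
    objective: FPObjectiveConfig | None = None,
    budget: FPBudget | None = None,
) -> tuple[float, float]:
    """(effectiveness, equity-weighted effectiveness) of a feasible plan.

    Effectiveness is total expected yearly client visits; the weighted score
    multiplies each site's client visits by 1 + (w−1)·priority-fraction.
    """
    objective = objective or FPObjectiveConfig()
    if budget is not None:
        _check_plan(plan, sites, budget)
    elif len(plan.visits_per_year) != len(sites):
        raise FeasibilityError("plan length does not match the site list")
    eff = 0.0
    weighted = 0.0
    for site, f in zip(sites, plan.visits_per_year):
        v = response_value(site.curve, f)
        eff += v
        weighted += v * _site_weight(site, objective)
    return eff, weighted


def allocate_equal(sites: list[Site], budget: FPBudget) -> VisitPlan:
    """Same frequency everywhere: the largest category affordable for all sites."""
    if not sites:
        raise ConfigurationError("need at least one site")
    n = len(sites)
    for c in budget.categories:  # sorted descending
        if n * c <= budget.total_days:
            return VisitPlan(visits_per_year=(c,) * n)
    return VisitPlan(visits_per_year=(0,) * n)


def allocate_greedy(sites: list[Site], budget: FPBudget) -> VisitPlan:
    """Explainable categorization by average clients per visit.

    Sites are ranked by their average number of clients served per visit,
    response_value(f_ref)/f_ref at the reference (middle) category, ties
    broken by site_id. Categories are then assigned *contiguously along the
    ranking* — better-ranked sites never get a lower frequency than
    worse-ranked ones — and the category sizes are the feasible split of the
    ranking that maximizes total client visits within the budget. The result
    is a transparent rule ("the top n₁ sites are visited monthly, the next n₂
    quarterly, …") while remaining close to the exact optimum; a trailing
    zero-frequency block is only used when the budget cannot cover the
    minimum category for every site. Deterministic.
    """
    if not sites:
        raise ConfigurationError("need at least one site")
    cats = budget.categories  # sorted descending
    f_ref = cats[len(cats) // 2]
    n = len(sites)
    order = sorted(
        range(n),
        key=lambda i: (-response_value(sites[i].curve, f_ref) / f_ref, sites[i].site_id),
    )
    # prefix sums of each category's yield along the ranking
    options = list(cats) + [0]
    prefix = np.zeros((len(options), n + 1))
    for oi, f in enumerate(options):
        vals = [response_value(sites[i].curve, f) for i in order]
        prefix[oi, 1:] = np.cumsum(vals)
    total = budget.total_days
    best_val, best_bounds = -1.0, (0,) * len(cats)

    def _search(level: int, start: int, used: int, value: float, bounds: tuple):
        nonlocal best_val, best_bounds
        if level == len(cats):
            if value > best_val:  # sites past the last boundary stay at 0
                best_val, best_bounds = value, bounds
            return
        f = options[level]
        for end in range(start, n + 1):
            cost = used + f * (end - start)
            if cost > total:
                break
            _search(
                level + 1, end, cost,
                value + prefix[level, end] - prefix[level, start],
                bounds + (end,),
            )

    _search(0, 0, 0, 0.0, ())
    visits = [0] * n
    prev = 0
    for oi, bound in enumerate(best_bounds):
        for k in range(prev, bound):
            visits[order[k]] = options[oi]
        prev = bound
    return VisitPlan(visits_per_year=tuple(visits))


def allocate_exact(
    sites: list[Site],
    budget: FPBudget,
    objective: FPObjectiveConfig | None = None,
    max_cells: int = 2_000_000,
) -> VisitPlan:
    """Exact optimum of the equity-weighted objective by dynamic programming.

    State = (site index, team-days used); transitions try every admissible
    frequency (including 0). Ties are broken deterministically toward the
    lowest frequency, then site order. Raises when the DP table would exceed
    ``max_cells`` — use a coarser day resolution.
    """
    if not sites:
        raise ConfigurationError("need at least one site")
    objective = objective or FPObjectiveConfig()
    n = len(sites)
    B = budget.total_days
    if (n + 1) * (B + 1) > max_cells:
        raise ConfigurationError(
            f"DP state space {(n + 1) * (B + 1)} exceeds {max_cells}; "
            "use a coarser day resolution"
        )
    options = [0] + sorted(budget.categories)  # ascending => lowest-frequency ties win
    gains = np.array(
        [
            [response_value(s.curve, f) * _site_weight(s, objective) for f in options]
            for s in sites
        ]
    )
    NEG = -np.inf
    value = np.full((n + 1, B + 1), NEG)
    value[n, :] = 0.0
    choice = np.zeros((n, B + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for oi, f in enumerate(options):
            if f > B:
                continue
            cand = np.full(B + 1, NEG)
            cand[: B + 1 - f] = gains[i, oi] + value[i + 1, f:]
            better = cand > value[i]
            value[i, better] = cand[better]
            choice[i, better] = oi
    visits = []
    b = 0
    for i in range(n):
        f = options[choice[i, b]]
        visits.append(f)
        b += f
    return VisitPlan(visits_per_year=tuple(visits))


def optimality_gap(
    method_plan: VisitPlan,
    exact_plan: VisitPlan,
    sites: list[Site],
    objective: FPObjectiveConfig | None = None,
    budget: FPBudget | None = None,
) -> tuple[float, float]:
    """Relative gaps to the exact plan, in percent, per objective.

    ``100 · (score_exact − score_method) / score_exact`` for effectiveness and
    for the equity-weighted score; the weighted gap is nonnegative whenever
    the exact plan is truly optimal.
    """
    objective = objective or FPObjectiveConfig()
    eff_m, wt_m = plan_scores(method_plan, sites, objective, budget)
    eff_e, wt_e = plan_scores(exact_plan, sites, objective, budget)
    if eff_e <= 0 or wt_e <= 0:
        raise DomainError("optimality gap undefined: exact plan scores zero")
    return (100.0 * (eff_e - eff_m) / eff_e, 100.0 * (wt_e - wt_m) / wt_e)
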