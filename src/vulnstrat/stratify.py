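"""Contiguity-constrained stratification with balanced measures of size.

The sampling frame requires strata that (a) fully cover the study area with
no overlap, (b) are contiguous on the unit adjacency graph, (c) are limited
in number (preferably 12-15, never more than 20), and (d) carry comparable
measures of size: each stratum's expected births/year (MOS) must fall within
mean +/- 10% of the per-stratum mean.  Within those hard rules the partition
should be as homogeneous as possible in the two vulnerability indices
(h_s, a_s).

Finding such a partition is a regionalization problem (NP-hard in general);
`build_strata` formalizes the source study's manual town-combination
iterations as seeded greedy region growing followed by boundary-move local
search with simulated-annealing acceptance, under a penalized objective

    homogeneity_weight * sum_s [var(h_s) + var(a_s)]
  + mos_penalty_weight * sum_s max(0, |MOS_s - mean| / mean - tol)^2

(population variance convention throughout).  Hard rules are re-checked by
the independent `validate_partition`; a returned partition is flagged
feasible only when every hard rule passes.  Units whose own MOS exceeds the
upper bound (a large city) must be pre-split at the child scale; the split
multiplicity is the rounded ratio of the unit's MOS to the target mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .study_model import StudyArea, UnitValidationError, UnknownUnitError

__all__ = [
    "StratConfig",
    "Partition",
    "RuleResult",
    "ComplianceReport",
    "RecruitmentPlan",
    "InfeasibilityError",
    "round_half_up",
    "mos_bounds",
    "split_count",
    "build_strata",
    "validate_partition",
    "homogeneity_report",
    "between_strata_variance_share",
    "recruitment_plan",
    "partition_objective",
]

MAX_STRATA = 20  # hard cap from the sampling rules


class InfeasibilityError(ValueError):
    """The stratification problem cannot be solved as configured."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


@dataclass
class StratConfig:
    """Configuration for the stratum-construction search.

    ``n_strata`` defaults to 15 (the guidance band is 12-15, hard max 20);
    ``mos_tolerance`` is the comparable-size fraction (default 0.10, i.e.
    mean +/- 10%).  ``mos_penalty_weight`` only steers the search while it is
    out of bounds — hard-rule compliance is judged by `validate_partition`.
    """

    n_strata: int = 15
    mos_tolerance: float = 0.10
    homogeneity_weight: float = 1.0
    mos_penalty_weight: float = 100.0
    max_iterations: int = 20000
    n_restarts: int = 4
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_strata <= MAX_STRATA):
            raise UnitValidationError(
                f"n_strata must be in 1..{MAX_STRATA}, got {self.n_strata}"
            )
        if not (0 <= self.mos_tolerance < 1):
            raise UnitValidationError(
                f"mos_tolerance must be in [0, 1), got {self.mos_tolerance}"
            )


@dataclass
class Partition:
    """An assignment of every top-scale unit to exactly one stratum."""

    assignment: dict[str, str]
    feasible: bool = True
    violated_rules: tuple[str, ...] = ()
    objective: float | None = None

    def strata(self) -> dict[str, list[str]]:
        """Stratum id -> sorted member unit ids."""
        out: dict[str, list[str]] = {}
        for uid, sid in self.assignment.items():
            out.setdefault(str(sid), []).append(uid)
        return {sid: sorted(m) for sid, m in sorted(out.items(), key=lambda kv: _sid_key(kv[0]))}

    @property
    def n_strata(self) -> int:
        return len(set(self.assignment.values()))

    def summary(self, area: StudyArea) -> pd.DataFrame:
        """Per-stratum members, MOS sum, index means/SDs and modal rating."""
        rows = []
        for sid, members in self.strata().items():
            units = [area[u] for u in members]
            h = np.array([u.h_s for u in units if u.h_s is not None], dtype=float)
            a = np.array([u.a_s for u in units if u.a_s is not None], dtype=float)
            ratings = [str(u.rating) for u in units if u.rating is not None]
            modal = max(set(ratings), key=ratings.count) if ratings else None
            rows.append(
                {
                    "stratum_id": sid,
                    "n_units": len(units),
                    "members": ";".join(members),
                    "mos": float(sum(u.mos for u in units)),
                    "mean_h_s": float(h.mean()) if h.size else np.nan,
                    "sd_h_s": float(h.std()) if h.size else np.nan,  # population SD
                    "mean_a_s": float(a.mean()) if a.size else np.nan,
                    "sd_a_s": float(a.std()) if a.size else np.nan,
                    "modal_rating": modal,
                }
            )
        return pd.DataFrame(rows)


def _sid_key(sid: str):
    return (0, int(sid)) if str(sid).isdigit() else (1, str(sid))


@dataclass(frozen=True)
class RuleResult:
    passed: bool
    detail: str = ""


@dataclass
class ComplianceReport:
    """Pass/fail per probability-sampling rule plus homogeneity diagnostics."""

    rules: dict[str, RuleResult]
    mos_lo: int
    mos_hi: int
    homogeneity: pd.DataFrame | None = None

    @property
    def overall_pass(self) -> bool:
        return all(r.passed for r in self.rules.values())

    def to_dict(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "mos_bounds": [self.mos_lo, self.mos_hi],
            "rules": {k: {"passed": v.passed, "detail": v.detail} for k, v in self.rules.items()},
        }


# ---------------------------------------------------------------------------
# Rule arithmetic
# ---------------------------------------------------------------------------

def mos_bounds(mean_target_mos: float, tolerance: float = 0.10) -> tuple[int, int]:
    """Integer comparable-size bounds: round-half-up of mean*(1 -/+ tol).

    E.g. a per-stratum mean of 2,113 births/year at 10% tolerance gives the
    acceptable range (1,902, 2,324).
    """
    if mean_target_mos <= 0:
        raise UnitValidationError(f"mean_target_mos must be > 0, got {mean_target_mos}")
    if not (0 <= tolerance < 1):
        raise UnitValidationError(f"tolerance must be in [0, 1), got {tolerance}")
    return (
        round_half_up(mean_target_mos * (1 - tolerance)),
        round_half_up(mean_target_mos * (1 + tolerance)),
    )


def split_count(unit_mos: float, mean_target_mos: float) -> int:
    """How many strata an oversized unit should be split into.

    Round-half-up of the MOS ratio with a floor of 1: a city with 10,385
    expected births/year against a 2,113 target mean (ratio 4.91) splits
    into 5.  A unit *requires* splitting iff its MOS exceeds the upper
    comparable-size bound.
    """
    if unit_mos <= 0 or mean_target_mos <= 0:
        raise UnitValidationError("unit_mos and mean_target_mos must be > 0")
    return max(1, round_half_up(unit_mos / mean_target_mos))


def recruitment_plan(
    total_sample: int, n_strata: int, years: int, inflation: float
) -> "RecruitmentPlan":
    """Annual per-segment recruitment arithmetic.

    Fixed rounding sequence: per-stratum target = floor(total/n_strata);
    per-year = round(per-stratum / years); inflated = round(per-year *
    (1 + inflation)).  E.g. 1,000 children over 18 strata in 4 years with a
    30% loss/dropout allowance: 1,000/18 = 55; 55/4 = 14; 14 + 30% -> 18.
    """
    if total_sample <= 0 or n_strata <= 0 or years <= 0:
        raise UnitValidationError("total_sample, n_strata and years must be positive")
    if inflation < 0:
        raise UnitValidationError(f"inflation must be >= 0, got {inflation}")
    per_stratum = total_sample // n_strata
    per_year = round_half_up(per_stratum / years)
    inflated = round_half_up(per_year * (1 + inflation))
    return RecruitmentPlan(per_stratum, per_year, inflated)


@dataclass(frozen=True)
class RecruitmentPlan:
    per_stratum: int
    per_year: int
    per_year_inflated: int


# ---------------------------------------------------------------------------
# Validation and diagnostics
# ---------------------------------------------------------------------------

def _connected(graph: nx.Graph, members: Sequence[str]) -> bool:
    if len(members) <= 1:
        return True
    sub = graph.subgraph(members)
    return nx.is_connected(sub)


def validate_partition(
    area: StudyArea, partition: Partition, config: StratConfig
) -> ComplianceReport:
    """Independently check every probability-sampling rule.

    Rules evaluated: full coverage of the top-scale units, no overlap (by
    construction of the assignment map, a duplicate-free unit set), stratum
    count within 1..20 and equal to the configured target, contiguity of
    each stratum on the adjacency graph, and per-stratum MOS within the
    integer bounds derived from (total MOS / n_strata, tolerance).
    """
    top_ids = {u.unit_id for u in area.top_units}
    assigned = set(partition.assignment)
    unknown = assigned - top_ids
    if unknown:
        raise UnknownUnitError(f"partition references unknown units: {sorted(unknown)[:5]}")

    strata = partition.strata()
    n = len(strata)
    total_mos = sum(area[u].mos for u in assigned)
    lo, hi = mos_bounds(total_mos / max(n, 1), config.mos_tolerance)

    rules: dict[str, RuleResult] = {}
    missing = top_ids - assigned
    rules["coverage"] = RuleResult(
        not missing, f"{len(missing)} top-scale units unassigned" if missing else "all units assigned"
    )
    sizes = sum(len(m) for m in strata.values())
    rules["no_overlap"] = RuleResult(
        sizes == len(assigned), "each unit appears in exactly one stratum"
    )
    count_ok = 1 <= n <= MAX_STRATA and n == config.n_strata
    rules["strata_count"] = RuleResult(
        count_ok, f"{n} strata (target {config.n_strata}, max {MAX_STRATA})"
    )
    bad_contig = [sid for sid, m in strata.items() if not _connected(area.adjacency, m)]
    rules["contiguity"] = RuleResult(
        not bad_contig,
        f"disconnected strata: {bad_contig}" if bad_contig else "all strata connected",
    )
    mos_by = {sid: sum(area[u].mos for u in m) for sid, m in strata.items()}
    bad_mos = {sid: m for sid, m in mos_by.items() if not (lo <= m <= hi)}
    rules["mos_bounds"] = RuleResult(
        not bad_mos,
        f"strata outside [{lo}, {hi}]: {bad_mos}" if bad_mos else f"all strata within [{lo}, {hi}]",
    )
    homog = None
    if all(area[u].h_s is not None and area[u].a_s is not None for u in assigned):
        homog = homogeneity_report(area, partition)
    return ComplianceReport(rules=rules, mos_lo=lo, mos_hi=hi, homogeneity=homog)


def homogeneity_report(area: StudyArea, partition: Partition) -> pd.DataFrame:
    """Per-stratum mean and population-SD of h_s and a_s.

    The frame's ``attrs`` carry the between-strata variance share for each
    index (fraction of total variance explained by stratum means, member
    units weighted equally).
    """
    strata = partition.strata()
    if any(len(m) == 0 for m in strata.values()):
        raise UnitValidationError("stratum with zero members")
    rows = []
    for sid, members in strata.items():
        for u in members:
            unit = area[u]
            if unit.h_s is None or unit.a_s is None:
                raise UnitValidationError(f"unit {u!r} has no computed index values")
        h = np.array([area[u].h_s for u in members], dtype=float)
        a = np.array([area[u].a_s for u in members], dtype=float)
        rows.append(
            {
                "stratum_id": sid,
                "n_units": len(members),
                "mos": float(sum(area[u].mos for u in members)),
                "mean_h_s": h.mean(),
                "sd_h_s": h.std(),
                "mean_a_s": a.mean(),
                "sd_a_s": a.std(),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["between_share_h_s"] = between_strata_variance_share(area, partition, "h_s")
    df.attrs["between_share_a_s"] = between_strata_variance_share(area, partition, "a_s")
    return df


def between_strata_variance_share(
    area: StudyArea, partition: Partition, attr: str = "h_s"
) -> float:
    """Fraction of the total variance of an index carried by stratum means.

    0 when all stratum means coincide, 1 when strata are internally
    constant; degenerate (zero total variance) inputs return 0.
    """
    values, labels = [], []
    for uid, sid in partition.assignment.items():
        v = getattr(area[uid], attr)
        if v is None:
            raise UnitValidationError(f"unit {uid!r} has no {attr}")
        values.append(v)
        labels.append(sid)
    v = np.asarray(values, dtype=float)
    total = v.var()
    if total == 0:
        return 0.0
    grand = v.mean()
    between = 0.0
    for sid in set(labels):
        sel = v[[i for i, s in enumerate(labels) if s == sid]]
        between += sel.size * (sel.mean() - grand) ** 2
    return float(between / v.size / total)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def partition_objective(
    mos: np.ndarray,
    h: np.ndarray,
    a: np.ndarray,
    labels: np.ndarray,
    k: int,
    mean_mos: float,
    config: StratConfig,
) -> float:
    """Penalized objective; lower is better.  Vectorized over strata."""
    obj = 0.0
    for s in range(k):
        sel = labels == s
        n = int(sel.sum())
        if n == 0:
            obj += config.mos_penalty_weight  # empty stratum: strongly penalized
            continue
        obj += config.homogeneity_weight * (h[sel].var() + a[sel].var())
        rel = abs(mos[sel].sum() - mean_mos) / mean_mos
        excess = max(0.0, rel - config.mos_tolerance)
        obj += config.mos_penalty_weight * excess * excess
    return float(obj)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def build_strata(area: StudyArea, config: StratConfig) -> Partition:
    """Search for a compliant, homogeneous partition of the top-scale units.

    Seeded greedy region growing (first restart seeds at the units most
    dispersed in (h_s, a_s) space, later restarts at random units), a greedy
    MOS-repair phase, then boundary-unit moves with simulated-annealing
    acceptance.  Deterministic for a given study area, config and seed.  If
    no fully feasible partition is found within the iteration budget, the
    best partition found is returned flagged infeasible with the violated
    rules named.
    """
    units = sorted(area.top_units, key=lambda u: u.unit_id)
    ids = [u.unit_id for u in units]
    n = len(ids)
    k = config.n_strata
    if k > n:
        raise UnitValidationError(f"n_strata={k} exceeds the {n} available units")
    graph = area.adjacency.subgraph(ids)
    if n > 1 and not nx.is_connected(graph):
        raise InfeasibilityError(
            "adjacency graph is disconnected; strata cannot straddle components"
        )
    idx = {u: i for i, u in enumerate(ids)}
    nbrs = [np.array([idx[v] for v in graph.neighbors(u)], dtype=int) for u in ids]
    mos = np.array([u.mos for u in units], dtype=float)
    h = np.array([u.h_s if u.h_s is not None else 0.0 for u in units], dtype=float)
    a = np.array([u.a_s if u.a_s is not None else 0.0 for u in units], dtype=float)
    mean_mos = mos.sum() / k
    lo, hi = mos_bounds(mean_mos, config.mos_tolerance)
    rng = np.random.default_rng(config.random_seed)

    best_labels: np.ndarray | None = None
    best_key: tuple | None = None
    for restart in range(max(1, config.n_restarts)):
        seeds = _dispersed_seeds(h, a, k) if restart == 0 else rng.choice(n, size=k, replace=False)
        labels = _grow_regions(nbrs, mos, h, a, seeds, k)
        labels = _repair_mos(labels, nbrs, mos, k, lo, hi, rng)
        labels, feas = _feasibility_anneal(
            labels, nbrs, mos, k, mean_mos, lo, hi, config, rng
        )
        if feas:
            labels = _refine_homogeneity(
                labels, nbrs, mos, h, a, k, lo, hi, config, rng
            )
        obj = partition_objective(mos, h, a, labels, k, mean_mos, config)
        key = (not feas, obj)  # feasible first, then objective
        if best_key is None or key < best_key:
            best_key, best_labels = key, labels.copy()

    labels = best_labels
    assignment = {ids[i]: str(int(labels[i]) + 1) for i in range(n)}
    feasible, violated = _hard_rules_ok(labels, nbrs, mos, k, lo, hi)
    return Partition(
        assignment=assignment,
        feasible=feasible,
        violated_rules=tuple(violated),
        objective=partition_objective(mos, h, a, labels, k, mean_mos, config),
    )


def _dispersed_seeds(h: np.ndarray, a: np.ndarray, k: int) -> np.ndarray:
    """Farthest-point selection of k seed units in (h_s, a_s) space."""
    pts = np.column_stack([h, a])
    center = pts.mean(axis=0)
    seeds = [int(np.argmax(((pts - center) ** 2).sum(axis=1)))]
    while len(seeds) < k:
        d = np.min(
            ((pts[:, None, :] - pts[seeds][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        d[seeds] = -1.0
        seeds.append(int(np.argmax(d)))
    return np.array(seeds, dtype=int)


def _grow_regions(
    nbrs: list[np.ndarray],
    mos: np.ndarray,
    h: np.ndarray,
    a: np.ndarray,
    seeds: np.ndarray,
    k: int,
) -> np.ndarray:
    """Grow k contiguous regions from seeds until every unit is assigned.

    At each step the lowest-MOS region with any unassigned neighbour claims
    the frontier unit closest to its (h_s, a_s) centroid; ties break on unit
    index, so growth is deterministic.
    """
    n = mos.size
    labels = np.full(n, -1, dtype=int)
    for s, i in enumerate(seeds):
        labels[int(i)] = s
    region_mos = np.array([mos[int(i)] for i in seeds], dtype=float)
    sum_h = np.array([h[int(i)] for i in seeds], dtype=float)
    sum_a = np.array([a[int(i)] for i in seeds], dtype=float)
    count = np.ones(k)
    unassigned = int((labels == -1).sum())
    while unassigned:
        grown = False
        for s in np.argsort(region_mos, kind="stable"):
            frontier = set()
            for i in np.flatnonzero(labels == s):
                for j in nbrs[i]:
                    if labels[j] == -1:
                        frontier.add(int(j))
            if not frontier:
                continue
            ch, ca = sum_h[s] / count[s], sum_a[s] / count[s]
            pick = min(frontier, key=lambda j: ((h[j] - ch) ** 2 + (a[j] - ca) ** 2, j))
            labels[pick] = s
            region_mos[s] += mos[pick]
            sum_h[s] += h[pick]
            sum_a[s] += a[pick]
            count[s] += 1
            unassigned -= 1
            grown = True
            break
        if not grown:  # pragma: no cover - connected graph always grows
            raise InfeasibilityError("region growing stalled on a disconnected graph")
    return labels


def _movable(labels: np.ndarray, nbrs: list[np.ndarray], i: int) -> bool:
    """Can unit i leave its stratum without disconnecting it or emptying it?"""
    s = labels[i]
    members = np.flatnonzero(labels == s)
    if members.size <= 1:
        return False
    rest = set(int(m) for m in members if m != i)
    # BFS over the remaining members
    start = next(iter(rest))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in nbrs[u]:
            v = int(v)
            if v in rest and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == rest


def _repair_mos(
    labels: np.ndarray,
    nbrs: list[np.ndarray],
    mos: np.ndarray,
    k: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    max_passes: int = 200,
) -> np.ndarray:
    """Greedy boundary moves pushing every stratum's MOS inside [lo, hi]."""
    labels = labels.copy()
    mos_by = np.array([mos[labels == s].sum() for s in range(k)])
    for _ in range(max_passes):
        worst = int(np.argmax(np.maximum(mos_by - hi, lo - mos_by)))
        viol = max(mos_by[worst] - hi, lo - mos_by[worst])
        if viol <= 0:
            break
        best_move, best_gain = None, 0.0
        if mos_by[worst] > hi:  # donate a boundary unit to a lighter neighbour stratum
            for i in np.flatnonzero(labels == worst):
                if not _movable(labels, nbrs, int(i)):
                    continue
                for t in {int(labels[j]) for j in nbrs[i]} - {worst}:
                    before = _mos_pen(mos_by[worst], lo, hi) + _mos_pen(mos_by[t], lo, hi)
                    after = _mos_pen(mos_by[worst] - mos[i], lo, hi) + _mos_pen(
                        mos_by[t] + mos[i], lo, hi
                    )
                    gain = before - after
                    if gain > best_gain:
                        best_gain, best_move = gain, (int(i), t)
        else:  # starved: pull a boundary unit from a neighbour stratum
            members = np.flatnonzero(labels == worst)
            cand = {
                int(j)
                for i in members
                for j in nbrs[i]
                if labels[j] != worst and _movable(labels, nbrs, int(j))
            }
            for j in cand:
                t = int(labels[j])
                before = _mos_pen(mos_by[worst], lo, hi) + _mos_pen(mos_by[t], lo, hi)
                after = _mos_pen(mos_by[worst] + mos[j], lo, hi) + _mos_pen(
                    mos_by[t] - mos[j], lo, hi
                )
                gain = before - after
                if gain > best_gain:
                    best_gain, best_move = gain, (j, worst)
        if best_move is None:
            break
        i, t = best_move
        s = int(labels[i])
        labels[i] = t
        mos_by[s] -= mos[i]
        mos_by[t] += mos[i]
    return labels


def _mos_pen(m: float, lo: int, hi: int) -> float:
    return max(0.0, m - hi, lo - m) ** 2


def _feasibility_anneal(
    labels: np.ndarray,
    nbrs: list[np.ndarray],
    mos: np.ndarray,
    k: int,
    mean_mos: float,
    lo: int,
    hi: int,
    config: StratConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Anneal boundary moves on the relative MOS-violation penalty alone.

    Moves keep every stratum non-empty and connected by construction
    (`_movable` on the donor; the recipient gains an adjacent unit), so
    once the penalty reaches zero the partition satisfies every hard rule.
    Proposals are biased toward units in (or adjacent to) violating strata.
    """
    labels = labels.copy()
    n = labels.size
    mos_by = np.array([mos[labels == s].sum() for s in range(k)])

    def pen(m: float) -> float:
        return (max(0.0, m - hi, lo - m) / mean_mos) ** 2

    cur = float(sum(pen(m) for m in mos_by))
    best, best_pen = labels.copy(), cur
    iters = max(1, config.max_iterations)
    # temperature set by the typical single-move penalty change, not the
    # (possibly near-zero) starting penalty, so the walk can climb out of
    # local minima left by the greedy repair
    t0, t1 = 0.5 * (float(np.mean(mos)) / mean_mos) ** 2, 1e-10

    def propose_unit() -> int:
        bad = np.flatnonzero((mos_by < lo) | (mos_by > hi))
        if bad.size and rng.random() < 0.8:
            s_bad = int(bad[int(rng.integers(bad.size))])
            if mos_by[s_bad] > hi:  # shed a member of the heavy stratum
                members = np.flatnonzero(labels == s_bad)
                return int(members[int(rng.integers(members.size))])
            cand = list(  # pull a unit adjacent to the starved stratum
                {
                    int(j)
                    for m in np.flatnonzero(labels == s_bad)
                    for j in nbrs[m]
                    if labels[j] != s_bad
                }
            )
            if cand:
                return int(cand[int(rng.integers(len(cand)))])
        return int(rng.integers(n))

    def do_move(i: int, t: int) -> None:
        s = int(labels[i])
        labels[i] = t
        mos_by[s] -= mos[i]
        mos_by[t] += mos[i]

    for it in range(iters):
        if best_pen == 0.0:
            break
        temp = t0 * (t1 / t0) ** (it / iters)
        i = propose_unit()
        s = int(labels[i])
        targets = {int(labels[j]) for j in nbrs[i]} - {s}
        if not targets or not _movable(labels, nbrs, i):
            continue
        t = sorted(targets)[int(rng.integers(len(targets)))]
        if rng.random() < 0.3:
            # composite swap: i goes s->t while some j comes t->s, letting a
            # large unit trade places with a small one across the boundary
            do_move(i, t)
            back = [
                int(j)
                for j in np.flatnonzero(labels == t)
                if j != i
                and any(int(labels[q]) == s for q in nbrs[j])
                and _movable(labels, nbrs, int(j))
            ]
            if not back:
                do_move(i, s)
                continue
            j = back[int(rng.integers(len(back)))]
            old = pen(mos_by[s] + mos[i]) + pen(mos_by[t] - mos[i])  # pre-swap
            do_move(j, s)
            new = pen(mos_by[s]) + pen(mos_by[t])
            delta = new - old
            if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-15)):
                cur += delta
                if cur < best_pen - 1e-15:
                    best, best_pen = labels.copy(), cur
            else:
                do_move(j, t)
                do_move(i, s)
            continue
        delta = (
            pen(mos_by[s] - mos[i])
            + pen(mos_by[t] + mos[i])
            - pen(mos_by[s])
            - pen(mos_by[t])
        )
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-15)):
            do_move(i, t)
            cur += delta
            if cur < best_pen - 1e-15:
                best, best_pen = labels.copy(), cur
    feasible = bool(best_pen <= 0.0)
    return best, feasible


def _refine_homogeneity(
    labels: np.ndarray,
    nbrs: list[np.ndarray],
    mos: np.ndarray,
    h: np.ndarray,
    a: np.ndarray,
    k: int,
    lo: int,
    hi: int,
    config: StratConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Anneal the within-stratum variance sum over feasibility-preserving moves.

    Starts from a partition whose strata are all within the MOS bounds and
    rejects outright any move that would push the donor or recipient outside
    them, so hard-rule compliance is invariant.
    """
    labels = labels.copy()
    n = labels.size
    cnt = np.zeros(k)
    mos_by = np.zeros(k)
    sh = np.zeros(k)
    sh2 = np.zeros(k)
    sa = np.zeros(k)
    sa2 = np.zeros(k)
    for s in range(k):
        sel = labels == s
        cnt[s] = sel.sum()
        mos_by[s] = mos[sel].sum()
        sh[s] = h[sel].sum()
        sh2[s] = (h[sel] ** 2).sum()
        sa[s] = a[sel].sum()
        sa2[s] = (a[sel] ** 2).sum()

    def contrib(s: int) -> float:
        if cnt[s] == 0:
            return 0.0
        vh = sh2[s] / cnt[s] - (sh[s] / cnt[s]) ** 2
        va = sa2[s] / cnt[s] - (sa[s] / cnt[s]) ** 2
        return max(vh, 0.0) + max(va, 0.0)

    c = np.array([contrib(s) for s in range(k)])
    cur = float(c.sum())
    best, best_obj = labels.copy(), cur
    iters = max(1, config.max_iterations)
    t0, t1 = max(cur / max(k, 1), 1e-6) * 0.5, 1e-9

    def shift(i: int, frm: int, to: int) -> None:
        labels[i] = to
        for q, d in ((frm, -1), (to, +1)):
            cnt[q] += d
            mos_by[q] += d * mos[i]
            sh[q] += d * h[i]
            sh2[q] += d * h[i] * h[i]
            sa[q] += d * a[i]
            sa2[q] += d * a[i] * a[i]

    for it in range(iters):
        temp = t0 * (t1 / t0) ** (it / iters)
        i = int(rng.integers(n))
        s = int(labels[i])
        targets = {int(labels[j]) for j in nbrs[i]} - {s}
        if not targets:
            continue
        t = sorted(targets)[int(rng.integers(len(targets)))]
        if not _movable(labels, nbrs, i):
            continue
        # with tight MOS bands a lone transfer is rarely admissible, so the
        # workhorse move is an exchange of two boundary units between s and t
        if rng.random() < 0.7:
            shift(i, s, t)
            back = [
                int(j)
                for j in np.flatnonzero(labels == t)
                if j != i
                and mos_by[s] + mos[j] >= lo
                and mos_by[s] + mos[j] <= hi
                and mos_by[t] - mos[j] >= lo
                and mos_by[t] - mos[j] <= hi
                and any(int(labels[q]) == s for q in nbrs[j])
                and _movable(labels, nbrs, int(j))
            ]
            if not back:
                shift(i, t, s)
                continue
            j = back[int(rng.integers(len(back)))]
            shift(j, t, s)
            new_cs, new_ct = contrib(s), contrib(t)
            delta = new_cs + new_ct - c[s] - c[t]
            if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-15)):
                c[s], c[t] = new_cs, new_ct
                cur += delta
                if cur < best_obj - 1e-12:
                    best, best_obj = labels.copy(), cur
            else:
                shift(j, s, t)
                shift(i, t, s)
            continue
        if not (lo <= mos_by[s] - mos[i] and mos_by[t] + mos[i] <= hi):
            continue
        shift(i, s, t)
        new_cs, new_ct = contrib(s), contrib(t)
        delta = new_cs + new_ct - c[s] - c[t]
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-15)):
            c[s], c[t] = new_cs, new_ct
            cur += delta
            if cur < best_obj - 1e-12:
                best, best_obj = labels.copy(), cur
        else:
            shift(i, t, s)
    return best


def _hard_rules_ok(
    labels: np.ndarray,
    nbrs: list[np.ndarray],
    mos: np.ndarray,
    k: int,
    lo: int,
    hi: int,
) -> tuple[bool, list[str]]:
    violated = []
    present = np.unique(labels)
    if present.size != k:
        violated.append("strata_count")
    mos_ok = True
    for s in range(k):
        sel = labels == s
        if not sel.any():
            continue
        m = mos[sel].sum()
        if not (lo <= m <= hi):
            mos_ok = False
    if not mos_ok:
        violated.append("mos_bounds")
    # contiguity via BFS per stratum
    for s in range(k):
        members = set(map(int, np.flatnonzero(labels == s)))
        if len(members) <= 1:
            continue
        start = next(iter(members))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                v = int(v)
                if v in members and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if seen != members:
            violated.append("contiguity")
            break
    return (not violated), violated
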