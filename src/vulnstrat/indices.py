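"""Composite vulnerability index construction.

Two indices summarize each areal unit: a hazards/stressors exposure index
``H_s`` (population density, traffic density, stationary pollution-source
density) and an adaptive-capacity/social-character index ``A_s`` (education,
income, poverty, linguistic isolation, minority share).  Each raw indicator
is min-max standardized onto [0, range_width] over the whole dataset,

    SV = range_width * (raw - min) / (max - min),        range_width = 10,

oriented so that larger values move the index in its named direction, and
combined as a weighted mean with weights normalized to sum to one,

    index = sum_j w_j * SV_j.

Index values are cut into k = 5 ordinal classes (very low … very high) at
natural breaks: the Fisher-Jenks partition of the sorted values minimizing
the total within-class sum of squared deviations.  The unit's vulnerability
rating is the ordered class pair [H, A].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .study_model import (
    RANGE_WIDTH,
    IndicatorSpec,
    Scale,
    StudyArea,
    UnitValidationError,
    VulnerabilityRating,
)

__all__ = [
    "StandardizationSpec",
    "CompositeIndexSpec",
    "DegenerateIndicatorError",
    "ClassificationError",
    "AggregationError",
    "standardize",
    "population_weighted_mean",
    "orient_indicator",
    "composite_index",
    "jenks_breaks",
    "classify",
    "vulnerability_rating",
    "compute_indices",
]


class DegenerateIndicatorError(ValueError):
    """All raw values of an indicator are identical; min-max scaling is undefined."""


class ClassificationError(ValueError):
    """Too few distinct values for the requested number of classes."""


class AggregationError(ValueError):
    """Population-weighted aggregation over zero total population."""


@dataclass(frozen=True)
class StandardizationSpec:
    """Min-max scaling parameters for one indicator.

    ``min_value``/``max_value`` are taken over the entire dataset for that
    indicator (no external reference ranges).
    """

    min_value: float
    max_value: float
    range_width: float = RANGE_WIDTH

    def __post_init__(self) -> None:
        if self.range_width <= 0:
            raise UnitValidationError(f"range_width must be > 0, got {self.range_width}")
        if not (self.max_value > self.min_value):
            raise DegenerateIndicatorError(
                f"max_value ({self.max_value}) must exceed min_value ({self.min_value})"
            )

    @staticmethod
    def from_data(values: Sequence[float], range_width: float = RANGE_WIDTH) -> "StandardizationSpec":
        arr = np.asarray(values, dtype=float)
        return StandardizationSpec(float(arr.min()), float(arr.max()), range_width)


@dataclass(frozen=True)
class CompositeIndexSpec:
    """Indicator set and classification scale for one composite index."""

    indicators: tuple[IndicatorSpec, ...]
    n_classes: int = 5
    class_labels: tuple[str, ...] = ("very low", "low", "moderate", "high", "very high")

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise UnitValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.class_labels) != self.n_classes:
            raise UnitValidationError(
                f"{len(self.class_labels)} labels supplied for {self.n_classes} classes"
            )
        total = sum(s.weight for s in self.indicators)
        if not self.indicators or total <= 0:
            raise UnitValidationError("indicator weights must sum to a positive value")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([s.weight for s in self.indicators], dtype=float)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def standardize(
    raw_values: Sequence[float],
    spec: StandardizationSpec | None = None,
    range_width: float = RANGE_WIDTH,
    clamp: bool = False,
) -> np.ndarray:
    """Min-max standardize onto [0, range_width].

    When ``spec`` is omitted, min and max are computed from ``raw_values``
    themselves.  Values outside [min, max] raise unless ``clamp`` is set
    (then they clip to the endpoints).
    """
    arr = np.asarray(raw_values, dtype=float)
    if spec is None:
        spec = StandardizationSpec.from_data(arr, range_width)
    out = spec.range_width * (arr - spec.min_value) / (spec.max_value - spec.min_value)
    if clamp:
        return np.clip(out, 0.0, spec.range_width)
    eps = 1e-9 * spec.range_width  # tolerate roundoff at the endpoints
    if out.size and (out.min() < -eps or out.max() > spec.range_width + eps):
        bad = arr[(out < -eps) | (out > spec.range_width + eps)][0]
        raise UnitValidationError(
            f"raw value {bad} outside [{spec.min_value}, {spec.max_value}] and clamp=False"
        )
    return np.clip(out, 0.0, spec.range_width)


def population_weighted_mean(
    child_values: Sequence[float], child_populations: Sequence[float]
) -> float:
    """Population-weighted average of child-unit values (block-groups -> town)."""
    v = np.asarray(child_values, dtype=float)
    p = np.asarray(child_populations, dtype=float)
    if v.shape != p.shape or v.ndim != 1 or v.size < 1:
        raise UnitValidationError(
            f"values and populations must be equal-length 1-d vectors, got {v.shape} vs {p.shape}"
        )
    if (p < 0).any():
        raise UnitValidationError("populations must be non-negative")
    total = p.sum()
    if total <= 0:
        raise AggregationError("population sum is zero; weighted mean undefined")
    return float(v @ p / total)


def orient_indicator(
    standardized_values: Sequence[float],
    polarity: int,
    range_width: float = RANGE_WIDTH,
) -> np.ndarray:
    """Orient a standardized indicator so larger values raise its index.

    Polarity +1 leaves values unchanged; polarity -1 reflects them about the
    scale midpoint (``range_width - value``), e.g. a poverty rate at the top
    of its range contributes 0 to adaptive capacity.
    """
    if polarity not in (1, -1):
        raise UnitValidationError(f"polarity must be +1 or -1, got {polarity}")
    arr = np.asarray(standardized_values, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > range_width):
        raise UnitValidationError(f"standardized values must lie in [0, {range_width}]")
    return arr if polarity == 1 else range_width - arr


def composite_index(
    oriented_values: np.ndarray,
    weights: Sequence[float],
    range_width: float = RANGE_WIDTH,
) -> np.ndarray:
    """Weighted combination of oriented standardized indicators.

    ``oriented_values`` is an (n_units, n_indicators) matrix with no missing
    cells; weights are normalized internally, so the result is a convex
    combination and stays within [0, range_width].
    """
    m = np.asarray(oriented_values, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != m.shape[1]:
        raise UnitValidationError(f"{w.size} weights supplied for {m.shape[1]} indicators")
    if (w < 0).any() or w.sum() <= 0:
        raise UnitValidationError("weights must be non-negative and sum to a positive value")
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise UnitValidationError(f"missing indicator value at unit {i}, indicator {j}")
    return m @ (w / w.sum())


def jenks_breaks(values: Sequence[float], k: int) -> np.ndarray:
    """Natural-breaks (Fisher-Jenks) cut points for k classes.

    Finds the partition of the sorted values into k contiguous classes
    minimizing the total within-class sum of squared deviations, by the exact
    O(k n^2) dynamic program over class boundaries.  Returns the k-1 upper
    boundary data values of classes 1 … k-1, in ascending order; see
    :func:`classify` for the tie rule.  Deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 1:
        raise ClassificationError(f"k must be >= 1, got {k}")
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ClassificationError(f"{n_distinct} distinct values cannot form {k} classes")
    if k == 1:
        return np.empty(0)

    # prefix sums for O(1) within-class SSD of x[i:j]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:  # x[i:j], j exclusive
        cnt = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / cnt

    INF = np.inf
    # cost[c][j]: best total SSD splitting x[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            back[c, j] = arg
    # recover boundaries
    cuts = []
    j = n
    for c in range(k, 1, -1):
        j = back[c, j]
        cuts.append(x[j - 1])  # upper bound of the class ending at j-1
    return np.array(cuts[::-1])


def classify(values: Sequence[float], breaks: Sequence[float]) -> np.ndarray:
    """Assign 1-based ordinal classes given ascending cut points.

    A value equal to a cut point goes to the *lower* class (deterministic tie
    rule); values below the first break are class 1, above the last break
    class ``len(breaks) + 1``.
    """
    b = np.asarray(breaks, dtype=float)
    if b.size and (np.diff(b) < 0).any():
        raise UnitValidationError("breaks must be ascending")
    v = np.asarray(values, dtype=float)
    return np.searchsorted(b, v, side="left") + 1


def vulnerability_rating(h_class: int, a_class: int) -> VulnerabilityRating:
    """The ordered [H, A] pair; (5,1) is worst, (1,5) best — never a ratio."""
    return VulnerabilityRating(int(h_class), int(a_class))


# ---------------------------------------------------------------------------
# Study-area index pipeline
# ---------------------------------------------------------------------------

@dataclass
class IndexResult:
    """Per-unit index values and classes plus the breaks used."""

    h_breaks: np.ndarray
    a_breaks: np.ndarray
    ej_flags: dict[str, bool] = field(default_factory=dict)


def compute_indices(
    area: StudyArea,
    indicators: Sequence[IndicatorSpec],
    order: str = "aggregate_then_standardize",
    n_classes: int = 5,
    range_width: float = RANGE_WIDTH,
    exclude_minority: bool = False,
    ej_a_threshold: float = 2,
) -> IndexResult:
    """Compute H_s/A_s and 1-5 classes for every top-scale unit, in place.

    Raw indicators are read from block-group children when present (and
    aggregated to their parent with population weights), otherwise from the
    top-scale unit itself.  Block-group units with children data also receive
    h_s/a_s so that oversized units can later be split at the child scale.

    Parameters
    ----------
    order
        ``"aggregate_then_standardize"`` (default; min-max taken over the
        aggregated top-scale values) or ``"standardize_then_aggregate"``
        (min-max over block-group values, then population-weighted).
    exclude_minority
        Drop the minority-share indicator from A_s and instead flag
        environmental-justice units: high minority share (top standardized
        half) combined with low capacity class (``a_class <= ej_a_threshold``).
    """
    if order not in ("aggregate_then_standardize", "standardize_then_aggregate"):
        raise UnitValidationError(f"unknown order {order!r}")
    h_specs = [s for s in indicators if s.index == "H"]
    a_specs = [s for s in indicators if s.index == "A"]
    if exclude_minority:
        a_specs = [s for s in a_specs if s.name != "pct_minority"]
    if not h_specs or not a_specs:
        raise UnitValidationError("need at least one indicator per index")

    tops = sorted(area.top_units, key=lambda u: u.unit_id)
    bgs = sorted(area.block_groups, key=lambda u: u.unit_id)
    has_children = {u.unit_id: [] for u in tops}
    for bg in bgs:
        has_children[bg.parent_id].append(bg)

    def raw_matrix(units, specs) -> np.ndarray:
        out = np.empty((len(units), len(specs)))
        for i, u in enumerate(units):
            for j, s in enumerate(specs):
                if s.name not in u.raw_indicators:
                    raise UnitValidationError(
                        f"unit {u.unit_id!r}: missing indicator {s.name!r}"
                    )
                out[i, j] = u.raw_indicators[s.name]
        return out

    def oriented(units, specs) -> np.ndarray:
        raw = raw_matrix(units, specs)
        cols = []
        for j, s in enumerate(specs):
            sv = standardize(raw[:, j], range_width=range_width)
            cols.append(orient_indicator(sv, s.polarity, range_width))
        return np.column_stack(cols)

    def index_values(specs) -> tuple[np.ndarray, np.ndarray | None]:
        """(top-scale values, block-group values or None)."""
        w = np.array([s.weight for s in specs], dtype=float)
        if bgs:
            if order == "standardize_then_aggregate":
                bg_vals = composite_index(oriented(bgs, specs), w, range_width)
                by_id = dict(zip((b.unit_id for b in bgs), bg_vals))
                top_vals = np.array(
                    [
                        population_weighted_mean(
                            [by_id[c.unit_id] for c in has_children[t.unit_id]],
                            [c.population for c in has_children[t.unit_id]],
                        )
                        if has_children[t.unit_id]
                        else np.nan
                        for t in tops
                    ]
                )
                if np.isnan(top_vals).any():
                    raise UnitValidationError("top-scale unit without block-group children")
                return top_vals, bg_vals
            # aggregate raw to town, then standardize over towns
            raw_bg = raw_matrix(bgs, specs)
            by_row = {b.unit_id: i for i, b in enumerate(bgs)}
            agg = np.empty((len(tops), len(specs)))
            for i, t in enumerate(tops):
                kids = has_children[t.unit_id]
                if not kids:
                    raise UnitValidationError(
                        f"unit {t.unit_id!r} has no block-group children"
                    )
                pops = [c.population for c in kids]
                for j in range(len(specs)):
                    agg[i, j] = population_weighted_mean(
                        [raw_bg[by_row[c.unit_id], j] for c in kids], pops
                    )
            cols = []
            for j, s in enumerate(specs):
                sv = standardize(agg[:, j], range_width=range_width)
                cols.append(orient_indicator(sv, s.polarity, range_width))
            # block-group-scale values (standardized among block-groups) for splitting
            bg_vals = composite_index(oriented(bgs, specs), w, range_width)
            return composite_index(np.column_stack(cols), w, range_width), bg_vals
        # no child scale: indicators live on the top units directly
        return composite_index(oriented(tops, specs), w, range_width), None

    h_top, h_bg = index_values(h_specs)
    a_top, a_bg = index_values(a_specs)

    h_breaks = jenks_breaks(h_top, n_classes)
    a_breaks = jenks_breaks(a_top, n_classes)
    h_cls = classify(h_top, h_breaks)
    a_cls = classify(a_top, a_breaks)
    for i, u in enumerate(tops):
        u.h_s = float(np.clip(h_top[i], 0.0, range_width))
        u.a_s = float(np.clip(a_top[i], 0.0, range_width))
        u.h_class = int(h_cls[i])
        u.a_class = int(a_cls[i])
    if h_bg is not None:
        for i, bg in enumerate(bgs):
            bg.h_s = float(np.clip(h_bg[i], 0.0, range_width))
            bg.a_s = float(np.clip(a_bg[i], 0.0, range_width))

    ej: dict[str, bool] = {}
    if exclude_minority:
        minority = [s for s in indicators if s.name == "pct_minority"]
        if minority:
            units_for_raw = bgs if bgs else tops
            mv = standardize(raw_matrix(units_for_raw, minority)[:, 0], range_width=range_width)
            by_id = dict(zip((u.unit_id for u in units_for_raw), mv))
            for t in tops:
                kids = has_children[t.unit_id]
                share = (
                    population_weighted_mean(
                        [by_id[c.unit_id] for c in kids], [c.population for c in kids]
                    )
                    if kids
                    else by_id[t.unit_id]
                )
                ej[t.unit_id] = bool(share > range_width / 2 and t.a_class <= ej_a_threshold)
    return IndexResult(h_breaks=h_breaks, a_breaks=a_breaks, ej_flags=ej)
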