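"""Domain model for vulnerability-based spatial sampling stratification.

The study design partitions a county into contiguous strata with comparable
expected births per year (the measure of size, MOS), chosen so that the
hazard-exposure index ``H`` and the adaptive-capacity index ``A`` are as
homogeneous as possible within each stratum.  This module holds the spatial
containers those computations run over: areal units at two nested census
scales (block-groups nested in towns), the contiguity graph over top-scale
units, indicator metadata, and readers/writers for the plain-text exchange
formats (unit-table CSV, edge-list CSV, GeoJSON polygons, partition CSV).

It also packages the published Worcester County, Massachusetts reference
table (64 town-scale rows, 18 strata) used throughout the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Scale",
    "SpatialUnit",
    "IndicatorSpec",
    "StudyArea",
    "VulnerabilityRating",
    "DEFAULT_H_INDICATORS",
    "DEFAULT_A_INDICATORS",
    "DEFAULT_INDICATORS",
    "SchemaError",
    "UnitValidationError",
    "UnknownUnitError",
    "GeometryError",
    "read_unit_table",
    "write_unit_table",
    "read_adjacency",
    "write_adjacency",
    "derive_adjacency_from_polygons",
    "read_geojson_polygons",
    "load_worcester_fixture",
    "worcester_synthetic_adjacency",
    "read_partition_csv",
    "write_partition_csv",
]

RANGE_WIDTH = 10.0  #: standardized indicator scale is [0, 10]


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class UnitValidationError(ValueError):
    """A unit violates a domain invariant (negative MOS, bad class, ...)."""


class UnknownUnitError(KeyError):
    """An edge, partition row or lookup references a unit id that does not exist."""


class GeometryError(ValueError):
    """A polygon supplied for contiguity derivation is invalid."""


class Scale(str, Enum):
    """Census scale of an areal unit.

    ``city_block_group`` marks top-scale pseudo-units obtained by splitting an
    oversized city at the block-group level; they behave like towns in the
    stratification.
    """

    BLOCK_GROUP = "block_group"
    TOWN = "town"
    CITY_BLOCK_GROUP = "city_block_group"

    @property
    def is_top(self) -> bool:
        return self in (Scale.TOWN, Scale.CITY_BLOCK_GROUP)


@dataclass
class SpatialUnit:
    """One areal unit (block-group, town, or city sub-stratum pseudo-town).

    Parameters
    ----------
    unit_id
        Opaque unique identifier.
    name
        Human-readable name (not necessarily unique; Worcester City's five
        sub-strata all carry the city's name).
    scale
        Census scale; see :class:`Scale`.
    parent_id
        For block-groups, the id of the containing town.
    population
        Person count (2000-census semantics). Non-negative.
    mos
        Measure of size: expected births per year. Non-negative.
    raw_indicators
        Raw indicator values keyed by indicator name.
    h_s, a_s
        Standardized composite index values on [0, 10], when computed.
    h_class, a_class
        Natural-breaks classes 1 (very low) … 5 (very high), when computed.
    """

    unit_id: str
    name: str
    scale: Scale = Scale.TOWN
    parent_id: str | None = None
    population: float = 0.0
    mos: float = 0.0
    raw_indicators: dict[str, float] = field(default_factory=dict)
    h_s: float | None = None
    a_s: float | None = None
    h_class: int | None = None
    a_class: int | None = None

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.population < 0:
            raise UnitValidationError(
                f"unit {self.unit_id!r}: population must be >= 0, got {self.population}"
            )
        if self.mos < 0:
            raise UnitValidationError(
                f"unit {self.unit_id!r}: MOS must be >= 0, got {self.mos}"
            )
        for attr in ("h_s", "a_s"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= RANGE_WIDTH):
                raise UnitValidationError(
                    f"unit {self.unit_id!r}: {attr}={v} outside [0, {RANGE_WIDTH}]"
                )
        for attr in ("h_class", "a_class"):
            v = getattr(self, attr)
            if v is not None and v not in (1, 2, 3, 4, 5):
                raise UnitValidationError(
                    f"unit {self.unit_id!r}: {attr}={v} not in 1..5"
                )

    @property
    def rating(self) -> "VulnerabilityRating | None":
        if self.h_class is None or self.a_class is None:
            return None
        return VulnerabilityRating(self.h_class, self.a_class)


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one raw indicator feeding a composite index.

    ``polarity`` is +1 when a higher raw value should raise the index in its
    named direction and -1 when it should lower it (e.g. median income raises
    adaptive capacity, poverty rate lowers it).  ``weight`` is relative; the
    weights of one index are normalized to sum to 1 when combined.
    """

    name: str
    index: str  # "H" or "A"
    polarity: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.index not in ("H", "A"):
            raise UnitValidationError(f"indicator {self.name!r}: index must be 'H' or 'A'")
        if self.polarity not in (1, -1):
            raise UnitValidationError(f"indicator {self.name!r}: polarity must be +1 or -1")
        if self.weight < 0:
            raise UnitValidationError(f"indicator {self.name!r}: weight must be >= 0")


#: Hazards/stressors exposure: densities of people, traffic, and stationary
#: pollution sources. Higher density = more exposure.
DEFAULT_H_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("population_density", "H", +1),
    IndicatorSpec("traffic_density", "H", +1),
    IndicatorSpec("pollution_source_density", "H", +1),
)

#: Adaptive capacity/social character: census socio-demographics. Only median
#: income raises capacity; the others lower it.
DEFAULT_A_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("pct_high_school_only", "A", -1),
    IndicatorSpec("median_income", "A", +1),
    IndicatorSpec("pct_poverty", "A", -1),
    IndicatorSpec("pct_linguistic_isolation", "A", -1),
    IndicatorSpec("pct_minority", "A", -1),
)

DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = DEFAULT_H_INDICATORS + DEFAULT_A_INDICATORS


@dataclass(frozen=True, order=True)
class VulnerabilityRating:
    """Ordered pair [H, A] of 1-5 classes; 25 combinations exist.

    The pair is never collapsed to a ratio: one unit of hazard is not one
    unit of capacity. (5, 1) — very high hazard, very low capacity — is the
    designated worst rating; (1, 5) the best.
    """

    h_class: int
    a_class: int

    def __post_init__(self) -> None:
        for attr in ("h_class", "a_class"):
            v = getattr(self, attr)
            if v not in (1, 2, 3, 4, 5):
                raise UnitValidationError(f"{attr}={v} not in 1..5")

    @property
    def label(self) -> str | None:
        if (self.h_class, self.a_class) == (5, 1):
            return "worst"
        if (self.h_class, self.a_class) == (1, 5):
            return "best"
        return None

    def __str__(self) -> str:
        return f"[{self.h_class},{self.a_class}]"

    @staticmethod
    def all_ratings() -> list["VulnerabilityRating"]:
        return [VulnerabilityRating(h, a) for h in range(1, 6) for a in range(1, 6)]


class StudyArea:
    """All spatial units of a study area plus the top-scale contiguity graph.

    ``adjacency`` is an undirected simple graph whose nodes are exactly the
    top-scale unit ids (towns and city pseudo-towns).  ``child_adjacency``
    optionally carries block-group contiguity, used when an oversized unit is
    split at the child scale.
    """

    def __init__(
        self,
        units: Iterable[SpatialUnit],
        adjacency: nx.Graph | None = None,
        child_adjacency: nx.Graph | None = None,
        name: str = "",
        source: str = "",
    ) -> None:
        self.units: dict[str, SpatialUnit] = {}
        for u in units:
            if u.unit_id in self.units:
                raise UnitValidationError(f"duplicate unit id {u.unit_id!r}")
            self.units[u.unit_id] = u
        self.name = name
        self.source = source
        top = [uid for uid, u in self.units.items() if u.scale.is_top]
        if adjacency is None:
            adjacency = nx.Graph()
        adjacency = nx.Graph(adjacency)  # simple, undirected copy
        adjacency.remove_edges_from(nx.selfloop_edges(adjacency))
        for uid in top:
            if uid not in adjacency:
                adjacency.add_node(uid)
        unknown = set(adjacency.nodes) - set(top)
        if unknown:
            raise UnknownUnitError(
                f"adjacency references non-top-scale or unknown units: {sorted(unknown)[:5]}"
            )
        self.adjacency = adjacency
        self.child_adjacency = child_adjacency if child_adjacency is not None else nx.Graph()
        for u in self.units.values():
            if u.scale is Scale.BLOCK_GROUP:
                parent = self.units.get(u.parent_id or "")
                if parent is None or not parent.scale.is_top:
                    raise UnitValidationError(
                        f"block-group {u.unit_id!r}: parent {u.parent_id!r} missing or not top-scale"
                    )

    # -- views ------------------------------------------------------------
    @property
    def top_units(self) -> list[SpatialUnit]:
        return [u for u in self.units.values() if u.scale.is_top]

    @property
    def block_groups(self) -> list[SpatialUnit]:
        return [u for u in self.units.values() if u.scale is Scale.BLOCK_GROUP]

    def children_of(self, unit_id: str) -> list[SpatialUnit]:
        return [u for u in self.units.values() if u.parent_id == unit_id]

    def __getitem__(self, unit_id: str) -> SpatialUnit:
        try:
            return self.units[unit_id]
        except KeyError:
            raise UnknownUnitError(unit_id) from None

    def __len__(self) -> int:
        return len(self.units)

    def to_frame(self, scale: Scale | None = None) -> pd.DataFrame:
        """Tabular view of the units (one row per unit) for reporting."""
        rows = []
        for u in self.units.values():
            if scale is not None and u.scale is not scale:
                continue
            row = {
                "unit_id": u.unit_id,
                "name": u.name,
                "scale": u.scale.value,
                "parent_id": u.parent_id,
                "population": u.population,
                "mos": u.mos,
                "h_s": u.h_s,
                "a_s": u.a_s,
                "h_class": u.h_class,
                "a_class": u.a_class,
            }
            row.update(u.raw_indicators)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unit-table and adjacency I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("unit_id", "name", "scale", "population", "mos")
_OPTIONAL_COLUMNS = ("parent_id", "h_s", "a_s", "h_class", "a_class")


def read_unit_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[SpatialUnit]:
    """Read a unit attribute table (CSV, comma-separated, UTF-8, header row).

    ``schema`` maps canonical field names (``unit_id``, ``name``, ``scale``,
    ``population``, ``mos``, optionally ``parent_id`` and the index columns)
    to the actual column names in the file.  Columns not claimed by the
    schema are treated as raw indicator values.

    Raises
    ------
    SchemaError
        If a required column is absent.
    UnitValidationError
        If a row carries a negative population or MOS (the row's unit id is
        named in the message).
    """
    df = pd.read_csv(path, encoding="utf-8")
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS}
    for canon in _REQUIRED_COLUMNS:
        if colmap[canon] not in df.columns:
            raise SchemaError(f"unit table {path}: missing required column {colmap[canon]!r}")
    claimed = {colmap[c] for c in colmap if colmap[c] in df.columns}
    indicator_cols = [c for c in df.columns if c not in claimed]
    units = []
    for _, row in df.iterrows():
        uid = str(row[colmap["unit_id"]])
        parent = None
        if colmap["parent_id"] in df.columns and pd.notna(row[colmap["parent_id"]]):
            parent = str(row[colmap["parent_id"]])
        kwargs: dict = {}
        for attr, cast in (("h_s", float), ("a_s", float), ("h_class", int), ("a_class", int)):
            col = colmap[attr]
            if col in df.columns and pd.notna(row[col]):
                kwargs[attr] = cast(row[col])
        raw = {
            c: float(row[c])
            for c in indicator_cols
            if pd.notna(row[c]) and _is_number(row[c])
        }
        units.append(
            SpatialUnit(
                unit_id=uid,
                name=str(row[colmap["name"]]),
                scale=Scale(str(row[colmap["scale"]])),
                parent_id=parent,
                population=float(row[colmap["population"]]),
                mos=float(row[colmap["mos"]]),
                raw_indicators=raw,
                **kwargs,
            )
        )
    return units


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_unit_table(units: Iterable[SpatialUnit], path: str | Path) -> None:
    StudyArea(units).to_frame().to_csv(path, index=False)


def read_adjacency(
    path: str | Path,
    known_units: Iterable[str] | None = None,
    allow_isolated: bool = True,
) -> nx.Graph:
    """Read an undirected adjacency graph from a 2-column edge-list CSV.

    Duplicate and reversed edges collapse to one undirected edge.  Self-loops
    are rejected.  When ``known_units`` is given, every endpoint must be a
    known id and (unless ``allow_isolated``) every known unit must appear.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.shape[1] < 2:
        raise SchemaError(f"adjacency {path}: expected two columns (unit_id_a, unit_id_b)")
    g = nx.Graph()
    known = set(map(str, known_units)) if known_units is not None else None
    for _, row in df.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        if a == b:
            raise UnitValidationError(f"adjacency {path}: self-loop on unit {a!r}")
        if known is not None and (a not in known or b not in known):
            bad = a if a not in known else b
            raise UnknownUnitError(f"adjacency {path}: edge references unknown unit {bad!r}")
        g.add_edge(a, b)
    if known is not None:
        missing = known - set(g.nodes)
        if missing and not allow_isolated:
            raise UnitValidationError(
                f"adjacency {path}: units with no edges: {sorted(missing)[:5]}"
            )
        g.add_nodes_from(known)
    return g


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    pd.DataFrame(sorted(tuple(sorted(e)) for e in graph.edges), columns=["unit_id_a", "unit_id_b"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Polygon-derived contiguity
# ---------------------------------------------------------------------------

def derive_adjacency_from_polygons(geometries: Mapping[str, object]) -> nx.Graph:
    """Derive rook contiguity from polygons keyed by unit id.

    Two units are adjacent iff their polygons share a boundary of positive
    length (rook rule); polygons touching only at a point (queen-only
    neighbours) are not connected.  Accepts shapely geometries or GeoJSON
    geometry mappings.
    """
    from shapely.geometry import shape
    from shapely.geometry.base import BaseGeometry
    from shapely.strtree import STRtree

    geoms: dict[str, BaseGeometry] = {}
    for uid, g in geometries.items():
        geom = g if isinstance(g, BaseGeometry) else shape(g)
        if geom.is_empty or not geom.is_valid:
            raise GeometryError(f"unit {uid!r}: invalid or empty geometry")
        geoms[str(uid)] = geom

    ids = list(geoms)
    tree = STRtree([geoms[u] for u in ids])
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, uid in enumerate(ids):
        for j in tree.query(geoms[uid]):
            j = int(j)
            if j <= i:
                continue
            inter = geoms[uid].intersection(geoms[ids[j]])
            if inter.is_empty:
                continue
            # rook: require shared boundary of positive length
            if getattr(inter, "length", 0.0) > 0.0:
                graph.add_edge(uid, ids[j])
    return graph


def read_geojson_polygons(path: str | Path, id_property: str = "unit_id") -> dict[str, object]:
    """Read a GeoJSON FeatureCollection into ``{unit_id: geometry mapping}``."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    out = {}
    for f in feats:
        props = f.get("properties", {}) or {}
        if id_property not in props:
            raise SchemaError(f"GeoJSON feature missing property {id_property!r}")
        out[str(props[id_property])] = f["geometry"]
    return out


# ---------------------------------------------------------------------------
# Worcester County reference fixture (published stratification table)
# ---------------------------------------------------------------------------

def _fixture_path() -> Path:
    return Path(resources.files("vulnstrat") / "data" / "worcester_table2.csv")


def load_worcester_table() -> pd.DataFrame:
    """The published Worcester County summary table as a DataFrame.

    64 top-scale rows: 59 towns plus the 5 pre-split Worcester City
    sub-strata (the source publishes the city only as five block-group-level
    strata). Stratum-level columns (stratum population, stratum MOS) are
    printed on the last row of each stratum.
    """
    return pd.read_csv(_fixture_path(), encoding="utf-8")


def load_worcester_fixture(with_synthetic_adjacency: bool = True):
    """Load the packaged Worcester County study area and its published partition.

    Returns
    -------
    (StudyArea, Partition)
        Town-scale units carrying the published population, MOS, index
        values and classes, plus the published 18-stratum assignment.

    Notes
    -----
    The source never publishes the county's town contiguity graph, only map
    images.  By default the study area carries a *synthetic* adjacency
    (see :func:`worcester_synthetic_adjacency`) under which every published
    stratum is connected; pass ``with_synthetic_adjacency=False`` for an
    edgeless graph.  Worcester City's five sub-strata have no published
    index values (``h_s``/``a_s`` are absent for them) and a population of
    the printed stratum population.
    """
    from .stratify import Partition  # local import to avoid a cycle

    df = load_worcester_table()
    units: list[SpatialUnit] = []
    assignment: dict[str, str] = {}
    city_seq = 0
    for _, row in df.iterrows():
        scale = Scale(row["scale"])
        if scale is Scale.CITY_BLOCK_GROUP:
            city_seq += 1
            uid = f"worcester_{city_seq}"
            pop = float(row["stratum_pop"])
        else:
            uid = row["name"].lower().replace(" ", "_").replace(".", "")
            pop = float(row["population"])
        units.append(
            SpatialUnit(
                unit_id=uid,
                name=str(row["name"]),
                scale=scale,
                population=pop,
                mos=float(row["mos"]),
                h_s=float(row["h_s"]) if pd.notna(row["h_s"]) else None,
                a_s=float(row["a_s"]) if pd.notna(row["a_s"]) else None,
                h_class=int(row["h_class"]),
                a_class=int(row["a_class"]),
                raw_indicators={
                    "n_block_groups": float(row["n_block_groups"]),
                    "min_bg_pop": float(row["min_bg_pop"]),
                    "max_bg_pop": float(row["max_bg_pop"]),
                    "mean_bg_h_s": float(row["mean_bg_h_s"]),
                    "sd_bg_h_s": float(row["sd_bg_h_s"]),
                    "mean_bg_a_s": float(row["mean_bg_a_s"]),
                    "sd_bg_a_s": float(row["sd_bg_a_s"]),
                },
            )
        )
        assignment[uid] = str(int(row["stratum"]))
    adjacency = worcester_synthetic_adjacency(assignment) if with_synthetic_adjacency else None
    area = StudyArea(
        units,
        adjacency=adjacency,
        name="Worcester County, MA",
        source="published stratification summary table (transcribed)",
    )
    partition = Partition(assignment=assignment)
    return area, partition


def worcester_synthetic_adjacency(assignment: Mapping[str, str]) -> nx.Graph:
    """A synthetic town contiguity graph consistent with the published strata.

    The real town adjacency is not published (maps appear only as images), so
    this deterministic stand-in chains the members of each published stratum
    in table order and links consecutive strata, with a few extra cross-links
    so the graph is connected and not tree-like.  Every published stratum is
    connected in it by construction; it is *not* Worcester County's real
    geography and is labelled synthetic for that reason.
    """
    by_stratum: dict[str, list[str]] = {}
    for uid, sid in assignment.items():
        by_stratum.setdefault(str(sid), []).append(uid)
    order = sorted(by_stratum, key=lambda s: (len(s), s))  # "1".."18" numeric-ish
    g = nx.Graph()
    for sid in order:
        members = by_stratum[sid]
        g.add_nodes_from(members)
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    # link consecutive strata (first/last members) and skip-links two apart
    for i, sid in enumerate(order):
        for step in (1, 2):
            if i + step < len(order):
                nxt = by_stratum[order[i + step]]
                g.add_edge(by_stratum[sid][-1], nxt[0])
                g.add_edge(by_stratum[sid][0], nxt[-1])
    return g


# ---------------------------------------------------------------------------
# Partition CSV round-trip
# ---------------------------------------------------------------------------

def write_partition_csv(assignment: Mapping[str, str], path: str | Path) -> None:
    """Write a partition as a two-column CSV (unit_id, stratum_id), sorted."""
    pd.DataFrame(
        sorted((str(u), str(s)) for u, s in assignment.items()),
        columns=["unit_id", "stratum_id"],
    ).to_csv(path, index=False)


def read_partition_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    for col in ("unit_id", "stratum_id"):
        if col not in df.columns:
            raise SchemaError(f"partition {path}: missing column {col!r}")
    return dict(zip(df["unit_id"], df["stratum_id"]))
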