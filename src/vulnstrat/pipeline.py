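"""End-to-end stratification pipeline.

Runs the six-stage flow: ingest -> standardize/orient -> population-weighted
aggregation to the town scale -> composite indices -> natural-breaks
classification and [H,A] rating -> split oversized units at the block-group
scale -> contiguity-constrained stratum construction -> rule validation ->
reports.  Every stage's output is serializable, all randomness flows from
one seed, and a run manifest records config/input digests so a rerun is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .indices import IndexResult, classify, compute_indices, population_weighted_mean
from .study_model import (
    DEFAULT_INDICATORS,
    IndicatorSpec,
    Scale,
    SpatialUnit,
    StudyArea,
    read_adjacency,
    read_unit_table,
    write_partition_csv,
)
from .stratify import (
    ComplianceReport,
    Partition,
    StratConfig,
    build_strata,
    homogeneity_report,
    mos_bounds,
    split_count,
    validate_partition,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "RunManifest",
    "run_pipeline",
    "split_oversized_units",
]

logger = logging.getLogger("vulnstrat")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full run configuration: indicator set, index options, stratification."""

    indicators: tuple[IndicatorSpec, ...] = DEFAULT_INDICATORS
    order: str = "aggregate_then_standardize"
    n_classes: int = 5
    exclude_minority: bool = False
    strat: StratConfig = field(default_factory=StratConfig)

    def to_dict(self) -> dict:
        return {
            "indicators": [asdict(s) for s in self.indicators],
            "order": self.order,
            "n_classes": self.n_classes,
            "exclude_minority": self.exclude_minority,
            "strat": asdict(self.strat),
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        inds = tuple(IndicatorSpec(**s) for s in d.get("indicators", [])) or DEFAULT_INDICATORS
        strat = StratConfig(**d.get("strat", {}))
        return PipelineConfig(
            indicators=inds,
            order=d.get("order", "aggregate_then_standardize"),
            n_classes=d.get("n_classes", 5),
            exclude_minority=d.get("exclude_minority", False),
            strat=strat,
        )

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return PipelineConfig.from_dict(yaml.safe_load(text) or {})
        return PipelineConfig.from_dict(json.loads(text))


@dataclass
class RunManifest:
    """Provenance record: digests, seed, version and the step log."""

    config_hash: str
    input_digests: dict[str, str]
    seed: int
    version: str
    started: str
    steps: list[str] = field(default_factory=list)
    finished: str = ""

    def log(self, step: str) -> None:
        self.steps.append(step)
        logger.info(step)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PipelineResult:
    area: StudyArea
    partition: Partition
    report: ComplianceReport
    homogeneity: pd.DataFrame
    index_result: IndexResult | None
    manifest: RunManifest


def _digest(obj) -> str:
    try:
        is_file = isinstance(obj, (str, Path)) and len(str(obj)) < 4096 and Path(obj).is_file()
    except OSError:
        is_file = False
    if is_file:
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()[:16]
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def split_oversized_units(
    area: StudyArea, config: StratConfig, index_result: IndexResult | None = None
) -> StudyArea:
    """Replace any top-scale unit whose MOS exceeds the upper comparable-size
    bound with contiguous block-group groupings of comparable MOS.

    The split multiplicity is ``split_count(unit MOS, total MOS / n_strata)``;
    the child grouping reuses the stratum-construction search on the unit's
    block-group contiguity graph.  Each resulting pseudo-unit (scale
    ``city_block_group``) is wired to its sibling pseudo-units along crossing
    block-group edges and inherits all of the parent's town-level neighbours
    (the published maps that would resolve which neighbour touches which part
    of the city are not machine-readable).
    """
    tops = area.top_units
    total = sum(u.mos for u in tops)
    mean_mos = total / config.n_strata
    _, hi = mos_bounds(mean_mos, config.mos_tolerance)
    oversized = [u for u in tops if u.mos > hi]
    if not oversized:
        return area
    units = dict(area.units)
    adjacency = nx.Graph(area.adjacency)
    for big in oversized:
        kids = area.children_of(big.unit_id)
        if not kids:
            raise PipelineError(
                "split",
                ValueError(
                    f"unit {big.unit_id!r} has MOS {big.mos:.0f} > {hi} but no "
                    "block-group children to split at"
                ),
            )
        # round-half-up of the MOS ratio, but never so few parts that a part
        # must exceed the upper bound: an overweight single-unit stratum can
        # never comply, while an underweight part can still merge with
        # neighbouring towns during stratum construction
        k = max(split_count(big.mos, mean_mos), int(np.ceil(big.mos / hi)))
        kid_ids = [c.unit_id for c in kids]
        sub_adj = area.child_adjacency.subgraph(kid_ids)
        sub_units = [
            SpatialUnit(
                unit_id=c.unit_id,
                name=c.name,
                scale=Scale.TOWN,
                population=c.population,
                mos=c.mos,
                h_s=c.h_s,
                a_s=c.a_s,
            )
            for c in kids
        ]
        sub_area = StudyArea(sub_units, adjacency=sub_adj, name=f"{big.unit_id} split")
        # cap the sub-split tolerance so no part lands above the county bound
        tol_cap = hi * k / big.mos - 1.0 if big.mos > 0 else config.mos_tolerance
        sub_cfg = StratConfig(
            n_strata=k,
            mos_tolerance=float(min(config.mos_tolerance, max(0.02, tol_cap))),
            homogeneity_weight=config.homogeneity_weight,
            mos_penalty_weight=config.mos_penalty_weight,
            max_iterations=config.max_iterations,
            n_restarts=config.n_restarts,
            random_seed=config.random_seed,
        )
        sub_part = build_strata(sub_area, sub_cfg)
        groups = sub_part.strata()
        neighbours = [v for v in adjacency.neighbors(big.unit_id)]
        adjacency.remove_node(big.unit_id)
        del units[big.unit_id]
        pseudo_ids = []
        for gi, (gid, members) in enumerate(groups.items(), start=1):
            pid = f"{big.unit_id}_part{gi}"
            pops = [area[m].population for m in members]
            hs = [area[m].h_s for m in members]
            as_ = [area[m].a_s for m in members]
            have_idx = all(v is not None for v in hs + as_)
            pseudo = SpatialUnit(
                unit_id=pid,
                name=f"{big.name} (part {gi})",
                scale=Scale.CITY_BLOCK_GROUP,
                population=float(sum(pops)),
                mos=float(sum(area[m].mos for m in members)),
                h_s=population_weighted_mean(hs, pops) if have_idx else None,
                a_s=population_weighted_mean(as_, pops) if have_idx else None,
            )
            if have_idx and index_result is not None:
                pseudo.h_class = int(classify([pseudo.h_s], index_result.h_breaks)[0])
                pseudo.a_class = int(classify([pseudo.a_s], index_result.a_breaks)[0])
            units[pid] = pseudo
            pseudo_ids.append(pid)
            for m in members:
                units[m] = SpatialUnit(
                    **{**asdict(area[m]), "parent_id": pid}
                )
            for nb in neighbours:
                adjacency.add_edge(pid, nb)
        # sibling pseudo-units along crossing block-group edges
        owner: dict[str, str] = {}
        for pid, (gid, members) in zip(pseudo_ids, groups.items()):
            for m in members:
                owner[m] = pid
        for u, v in sub_adj.edges:
            if owner[u] != owner[v]:
                adjacency.add_edge(owner[u], owner[v])
    return StudyArea(
        units.values(),
        adjacency=adjacency,
        child_adjacency=area.child_adjacency,
        name=area.name,
        source=area.source,
    )


def run_pipeline(
    units: str | Path | Sequence[SpatialUnit] | StudyArea,
    adjacency: str | Path | nx.Graph | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    compute_index_values: bool = True,
) -> PipelineResult:
    """Execute the full stratification flow and optionally write artifacts.

    ``units`` may be a unit-table CSV path, a unit sequence, or a ready
    :class:`StudyArea` (in which case ``adjacency`` is ignored).  With
    ``compute_index_values=False`` the pre-computed h_s/a_s/classes on the
    units are used as-is (validate-only style runs on published tables).

    Outputs written to ``out_dir``: ``partition.csv``, ``strata_summary.csv``,
    ``compliance.json``, ``homogeneity.csv``, ``manifest.json``.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(
        config_hash=_digest(json.dumps(config.to_dict(), sort_keys=True)),
        input_digests={"units": _digest(units), "adjacency": _digest(adjacency)},
        seed=config.strat.random_seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - wrap with stage context
                raise PipelineError(name, e) from e
            manifest.log(f"{name}: ok")
            return out

        return deco

    @stage("ingest")
    def area() -> StudyArea:
        if isinstance(units, StudyArea):
            return units
        if isinstance(units, (str, Path)):
            parsed = read_unit_table(units)
        else:
            parsed = list(units)
        adj = adjacency
        if isinstance(adj, (str, Path)):
            adj = read_adjacency(
                adj, known_units=[u.unit_id for u in parsed if u.scale.is_top]
            )
        return StudyArea(parsed, adjacency=adj)

    @stage("indices")
    def index_result() -> IndexResult | None:
        if not compute_index_values:
            missing = [
                u.unit_id for u in area.top_units if u.h_s is None and u.h_class is None
            ]
            if missing:
                raise ValueError(
                    f"compute_index_values=False but units lack index values: {missing[:5]}"
                )
            return None
        return compute_indices(
            area,
            config.indicators,
            order=config.order,
            n_classes=config.n_classes,
            exclude_minority=config.exclude_minority,
        )

    @stage("split_oversized")
    def split_area() -> StudyArea:
        return split_oversized_units(area, config.strat, index_result)

    @stage("build_strata")
    def partition() -> Partition:
        return build_strata(split_area, config.strat)

    @stage("validate")
    def report() -> ComplianceReport:
        return validate_partition(split_area, partition, config.strat)

    @stage("report")
    def homogeneity() -> pd.DataFrame:
        try:
            return homogeneity_report(split_area, partition)
        except Exception:
            # index values absent (validate-only on class-level tables)
            return partition.summary(split_area)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    result = PipelineResult(
        area=split_area,
        partition=partition,
        report=report,
        homogeneity=homogeneity,
        index_result=index_result,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_partition_csv(partition.assignment, out / "partition.csv")
        partition.summary(split_area).to_csv(out / "strata_summary.csv", index=False)
        (out / "compliance.json").write_text(
            json.dumps(report.to_dict(), indent=2), encoding="utf-8"
        )
        homogeneity.to_csv(out / "homogeneity.csv", index=False)
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return result
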