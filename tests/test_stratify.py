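"""MOS arithmetic, rule validation, homogeneity diagnostics, and the solver."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import vulnstrat as vs
from vulnstrat.stratify import (
    InfeasibilityError,
    mos_bounds,
    partition_objective,
    recruitment_plan,
    round_half_up,
    split_count,
)
from vulnstrat.study_model import UnitValidationError

from conftest import make_area
from helpers import contiguous_partitions, partition_cost


# ---------------------------------------------------------------------------
# rule arithmetic
# ---------------------------------------------------------------------------

def test_round_half_up_convention():
    assert round_half_up(2.5) == 3
    assert round_half_up(4.91) == 5
    assert round_half_up(1901.7) == 1902


@pytest.mark.parametrize(
    "mean,tol,expected",
    [(2113, 0.10, (1902, 2324)), (1000, 0.10, (900, 1100)), (500, 0.0, (500, 500))],
)
def test_mos_bounds(mean, tol, expected):
    assert mos_bounds(mean, tol) == expected


def test_mos_bounds_rejects_bad_tolerance():
    with pytest.raises(UnitValidationError):
        mos_bounds(1000, 1.0)


@pytest.mark.parametrize(
    "mos,mean,expected",
    [(10385, 2113, 5), (2113, 2113, 1), (5282.5, 2113, 3), (100, 2113, 1)],
)
def test_split_count(mos, mean, expected):
    assert split_count(mos, mean) == expected


def test_recruitment_plan_arithmetic():
    plan = recruitment_plan(1000, 18, 4, 0.30)
    assert (plan.per_stratum, plan.per_year, plan.per_year_inflated) == (55, 14, 18)
    assert recruitment_plan(1000, 18, 4, 0).per_year_inflated == 14
    assert recruitment_plan(100, 100, 1, 0).per_year_inflated == 1


def test_strat_config_bounds():
    with pytest.raises(UnitValidationError):
        vs.StratConfig(n_strata=21)
    with pytest.raises(UnitValidationError):
        vs.StratConfig(n_strata=0)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _square_area():
    mos = {i: 100.0 for i in range(4)}
    h = {i: float(i) for i in range(4)}
    a = {i: float(3 - i) for i in range(4)}
    return make_area(mos, h, a, nx.cycle_graph(4))


def test_validator_flags_non_adjacent_stratum():
    area = _square_area()
    # 0 and 2 are opposite corners of the cycle: not adjacent
    part = vs.Partition(assignment={"0": "1", "2": "1", "1": "2", "3": "2"})
    rep = vs.validate_partition(area, part, vs.StratConfig(n_strata=2))
    assert not rep.rules["contiguity"].passed
    assert not rep.overall_pass


def test_validator_flags_missing_coverage():
    area = _square_area()
    part = vs.Partition(assignment={"0": "1", "1": "1", "2": "2"})
    rep = vs.validate_partition(area, part, vs.StratConfig(n_strata=2))
    assert not rep.rules["coverage"].passed


def test_validator_flags_mos_imbalance():
    mos = {0: 10.0, 1: 10.0, 2: 500.0, 3: 10.0}
    area = make_area(mos, {i: 0.0 for i in range(4)}, {i: 0.0 for i in range(4)}, nx.path_graph(4))
    part = vs.Partition(assignment={"0": "1", "1": "1", "2": "2", "3": "2"})
    rep = vs.validate_partition(area, part, vs.StratConfig(n_strata=2))
    assert not rep.rules["mos_bounds"].passed


def test_validator_passes_published_worcester_partition(worcester):
    area, partition = worcester
    rep = vs.validate_partition(area, partition, vs.StratConfig(n_strata=18))
    assert rep.rules["mos_bounds"].passed
    assert rep.overall_pass


# ---------------------------------------------------------------------------
# homogeneity diagnostics
# ---------------------------------------------------------------------------

def test_homogeneity_population_sd_convention():
    area = make_area(
        {0: 1.0, 1: 1.0, 2: 1.0},
        {0: 1.0, 1: 3.0, 2: 9.0},
        {0: 0.0, 1: 0.0, 2: 4.0},
        nx.path_graph(3),
    )
    part = vs.Partition(assignment={"0": "1", "1": "1", "2": "2"})
    df = vs.homogeneity_report(area, part).set_index("stratum_id")
    assert df.loc["1", "mean_h_s"] == 2.0
    assert df.loc["1", "sd_h_s"] == 1.0  # population SD of {1, 3}
    assert df.loc["2", "sd_h_s"] == 0.0  # singleton stratum


def test_between_share_zero_when_strata_identical():
    area = make_area(
        {i: 1.0 for i in range(4)},
        {0: 1.0, 1: 5.0, 2: 1.0, 3: 5.0},
        {0: 2.0, 1: 6.0, 2: 2.0, 3: 6.0},
        nx.cycle_graph(4),
    )
    part = vs.Partition(assignment={"0": "1", "1": "1", "2": "2", "3": "2"})
    assert vs.between_strata_variance_share(area, part, "h_s") == pytest.approx(0.0)
    assert vs.between_strata_variance_share(area, part, "a_s") == pytest.approx(0.0)


def test_between_share_one_when_strata_internally_constant():
    area = make_area(
        {i: 1.0 for i in range(4)},
        {0: 1.0, 1: 1.0, 2: 5.0, 3: 5.0},
        {i: 0.0 for i in range(4)},
        nx.path_graph(4),
    )
    part = vs.Partition(assignment={"0": "1", "1": "1", "2": "2", "3": "2"})
    assert vs.between_strata_variance_share(area, part, "h_s") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def test_path_of_six_splits_in_half(path6_area):
    """With equal MOS and identical indices, the only balanced contiguous
    2-partition of a 6-path is 3+3 (exhaustively checkable)."""
    cfg = vs.StratConfig(n_strata=2, mos_tolerance=0.10, random_seed=1)
    p = vs.build_strata(path6_area, cfg)
    assert p.feasible
    sizes = sorted(len(m) for m in p.strata().values())
    assert sizes == [3, 3]
    rep = vs.validate_partition(path6_area, p, cfg)
    assert rep.overall_pass


def test_single_unit_single_stratum():
    area = make_area({0: 50.0}, {0: 1.0}, {0: 1.0}, nx.empty_graph(1))
    p = vs.build_strata(area, vs.StratConfig(n_strata=1))
    assert p.feasible and p.n_strata == 1


def test_disconnected_graph_is_an_error():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (2, 3)])
    area = make_area({i: 1.0 for i in range(4)}, {i: 0.0 for i in range(4)}, {i: 0.0 for i in range(4)}, g)
    with pytest.raises(InfeasibilityError):
        vs.build_strata(area, vs.StratConfig(n_strata=2))


def test_more_strata_than_units_is_an_error(path6_area):
    with pytest.raises(UnitValidationError):
        vs.build_strata(path6_area, vs.StratConfig(n_strata=7))


def test_solver_reproducible(path6_area):
    cfg = vs.StratConfig(n_strata=3, random_seed=42)
    p1 = vs.build_strata(path6_area, cfg)
    p2 = vs.build_strata(path6_area, cfg)
    assert p1.assignment == p2.assignment


@pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 3)])
def test_solver_matches_exhaustive_optimum_on_grids(seed, k):
    """On toy grids the annealed search reaches the brute-force optimum over
    all contiguous k-partitions."""
    rng = np.random.default_rng(seed)
    g = nx.convert_node_labels_to_integers(nx.grid_2d_graph(2, 4))
    n = g.number_of_nodes()
    mos = {i: float(rng.uniform(80, 120)) for i in range(n)}
    h = {i: float(rng.uniform(0, 10)) for i in range(n)}
    a = {i: float(rng.uniform(0, 10)) for i in range(n)}
    area = make_area(mos, h, a, g)
    cfg = vs.StratConfig(n_strata=k, mos_tolerance=0.25, random_seed=seed, n_restarts=6)
    p = vs.build_strata(area, cfg)
    mean_mos = sum(mos.values()) / k
    lo, hi = mos_bounds(mean_mos, cfg.mos_tolerance)
    # the solver prefers hard-feasible partitions, so the matching oracle is
    # the best cost among MOS-compliant contiguous partitions
    costs = []
    for blocks in contiguous_partitions(
        nx.relabel_nodes(g, {i: str(i) for i in range(n)}), k
    ):
        if not all(lo <= sum(mos[int(u)] for u in b) <= hi for b in blocks):
            continue
        costs.append(
            partition_cost(
                blocks,
                {str(i): mos[i] for i in range(n)},
                {str(i): h[i] for i in range(n)},
                {str(i): a[i] for i in range(n)},
                mean_mos,
                cfg.mos_tolerance,
                hw=cfg.homogeneity_weight,
                mw=cfg.mos_penalty_weight,
            )
        )
    assert costs, "toy instance should admit a compliant partition"
    assert p.feasible
    assert p.objective == pytest.approx(min(costs), rel=1e-9, abs=1e-9)


def test_tightening_tolerance_shrinks_feasible_set():
    """Monotonicity checked by enumeration: every MOS-compliant contiguous
    partition at tol=0.05 is also compliant at tol=0.15."""
    rng = np.random.default_rng(3)
    g = nx.relabel_nodes(nx.cycle_graph(8), {i: str(i) for i in range(8)})
    mos = {u: float(rng.uniform(50, 150)) for u in g.nodes}
    k = 3
    mean_mos = sum(mos.values()) / k

    def feasible_set(tol):
        lo, hi = mos_bounds(mean_mos, tol)
        out = set()
        for blocks in contiguous_partitions(g, k):
            if all(lo <= sum(mos[u] for u in b) <= hi for b in blocks):
                out.add(frozenset(frozenset(b) for b in blocks))
        return out

    tight, loose = feasible_set(0.05), feasible_set(0.15)
    assert tight <= loose


def test_solver_beats_random_partition_on_block_structured_county():
    """Strata recovered on a county with block-structured indices separate
    the index field better than a random contiguous partition of the same
    stratum count."""
    rng = np.random.default_rng(9)
    area = vs.generate_county(vs.SynthConfig(seed=9, n_towns=48, h_a_correlation=-0.6))
    vs.compute_indices(area, vs.DEFAULT_INDICATORS)
    cfg = vs.StratConfig(n_strata=12, random_seed=9)
    p = vs.build_strata(area, cfg)
    assert p.feasible
    share = vs.between_strata_variance_share(area, p, "h_s") + vs.between_strata_variance_share(
        area, p, "a_s"
    )
    # random contiguous comparison partitions with the same stratum sizes,
    # grown by uniformly random frontier expansion
    ids = sorted(u.unit_id for u in area.top_units)
    g = area.adjacency.subgraph(ids)
    sizes = sorted((len(m) for m in p.strata().values()), reverse=True)

    def random_contiguous(rng):
        remaining = set(ids)
        labels = {}
        for s, target in enumerate(sizes):
            start = rng.choice(sorted(remaining))
            block = {start}
            remaining.discard(start)
            while len(block) < target:
                frontier = sorted(
                    {v for u in block for v in g.neighbors(u) if v in remaining}
                )
                if not frontier:
                    break
                pick = rng.choice(frontier)
                block.add(pick)
                remaining.discard(pick)
            for u in block:
                labels[u] = str(s)
        for u in sorted(remaining):  # attach leftovers to an adjacent block
            nb = [v for v in g.neighbors(u) if v in labels]
            labels[u] = labels[nb[0]] if nb else "0"
        return vs.Partition(assignment=labels)

    rand_shares = []
    for _ in range(5):
        rnd = random_contiguous(rng)
        rand_shares.append(
            vs.between_strata_variance_share(area, rnd, "h_s")
            + vs.between_strata_variance_share(area, rnd, "a_s")
        )
    assert share > np.mean(rand_shares)


def test_build_strata_feasible_on_worcester_fixture(worcester):
    area, _ = worcester
    cfg = vs.StratConfig(n_strata=18, mos_tolerance=0.10, random_seed=7)
    p = vs.build_strata(area, cfg)
    assert p.feasible
    rep = vs.validate_partition(area, p, cfg)
    assert rep.overall_pass
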