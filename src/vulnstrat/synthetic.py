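"""Synthetic county generator.

Emulates the statistical structure the stratification method assumes, so the
whole pipeline is testable without any external download:

* towns laid out on a jittered lattice with Delaunay-derived planar
  contiguity (connected and simple);
* block-groups nested in towns, with populations drawn from a lognormal
  matching the wide dispersion of census block-groups (defaults target a
  mean of 1,262 people and SD of 650);
* MOS (expected births/year) proportional to population with noise;
* raw hazard (h1-h3) and capacity (a1-a5) indicator fields driven by two
  spatially smooth latent Gaussian fields — an "urbanicity" factor loading
  positively on hazards and a capacity factor negatively correlated with it
  (the two composite indices of real counties tend to be inversely
  correlated: industrial cores score high-hazard/low-capacity, rural towns
  the opposite);
* optionally a fraction of oversized "city" towns whose MOS exceeds any
  reasonable per-stratum upper bound, forcing a child-scale split.

Geometry is abstract (contiguity, not shape, is what the method consumes).
All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from .study_model import (
    IndicatorSpec,
    Scale,
    SpatialUnit,
    StudyArea,
    UnitValidationError,
    DEFAULT_INDICATORS,
)

__all__ = ["SynthConfig", "generate_county"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic county.

    ``h_a_correlation`` is the target correlation between the latent hazard
    and capacity fields (and, up to indicator-noise attenuation that the
    generator compensates for, between the computed h_s and a_s); it must be
    non-positive.  ``bg_population_mean``/``sd`` parameterize the lognormal
    block-group population law.  ``city_fraction`` towns (rounded up when
    positive) are made oversized by multiplying their block-group count by
    ``city_scale``.
    """

    seed: int = 0
    n_towns: int = 60
    bg_per_town: tuple[int, int] = (2, 16)
    bg_population_mean: float = 1262.0
    bg_population_sd: float = 650.0
    births_per_capita: float = 0.047
    mos_noise_sd: float = 0.05
    h_a_correlation: float = -0.6
    field_length_scale: float = 2.0
    indicator_noise_sd: float = 0.3
    bg_noise_sd: float = 0.25
    city_fraction: float = 0.0
    city_scale: int = 12

    def __post_init__(self) -> None:
        if self.n_towns < 1:
            raise UnitValidationError(f"n_towns must be >= 1, got {self.n_towns}")
        if not (-1.0 <= self.h_a_correlation <= 0.0):
            raise UnitValidationError(
                f"h_a_correlation must lie in [-1, 0], got {self.h_a_correlation}"
            )
        lo, hi = self.bg_per_town
        if not (1 <= lo <= hi):
            raise UnitValidationError(f"bad bg_per_town range {self.bg_per_town}")
        if self.bg_population_mean <= 0 or self.bg_population_sd < 0:
            raise UnitValidationError("block-group population mean/SD must be positive")
        if self.births_per_capita <= 0:
            raise UnitValidationError("births_per_capita must be positive")


def _lattice_points(n: int, rng: np.random.Generator) -> np.ndarray:
    cols = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(cols), np.arange(int(np.ceil(n / cols))))
    pts = np.column_stack([xs.ravel(), ys.ravel()])[:n].astype(float)
    return pts + rng.uniform(-0.25, 0.25, size=pts.shape)


def _delaunay_graph(pts: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    if len(pts) == 2:
        g.add_edge(0, 1)
    elif len(pts) >= 3:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i in range(3):
                g.add_edge(int(simplex[i]), int(simplex[(i + 1) % 3]))
    return g


def _smooth_field(pts: np.ndarray, length_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with squared-exponential covariance."""
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    cov = np.exp(-d2 / (2.0 * max(length_scale, 1e-6) ** 2)) + 1e-8 * np.eye(len(pts))
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(pts))


def generate_county(config: SynthConfig) -> StudyArea:
    """Generate a synthetic study area (towns + block-groups + indicators + MOS).

    Deterministic for a given config (same seed twice -> identical area).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_towns
    pts = _lattice_points(n, rng)
    graph = _delaunay_graph(pts)

    # latent fields: urbanicity u drives hazards; capacity c is correlated
    # rho_latent with u, inflated to offset indicator-noise attenuation so the
    # computed h_s/a_s correlation lands near the configured target.
    u = _smooth_field(pts, config.field_length_scale, rng)
    v = _smooth_field(pts, config.field_length_scale, rng)
    s2 = config.indicator_noise_sd**2 + config.bg_noise_sd**2
    atten = 1.0 / np.sqrt((1 + s2 / 3.0) * (1 + s2 / 5.0))
    rho = float(np.clip(config.h_a_correlation / atten, -1.0, 0.0))
    # Gram-Schmidt the second field against the first so the latent coupling
    # equals rho in the realized sample, not merely in expectation — spatial
    # autocorrelation leaves too few effective degrees of freedom for the
    # sample correlation to concentrate on its own
    us = _std(u)
    if n > 1 and us.std() > 0:
        v_res = v - (v @ us) / (us @ us) * us
    else:
        v_res = v
    c = rho * us + np.sqrt(max(0.0, 1 - rho * rho)) * _std(v_res)

    # oversized city towns: the most urban ones
    n_city = int(np.ceil(config.city_fraction * n)) if config.city_fraction > 0 else 0
    city_idx = set(np.argsort(u)[::-1][:n_city].tolist())

    mu, sigma = _lognormal_params(config.bg_population_mean, config.bg_population_sd)
    h_specs = [s for s in DEFAULT_INDICATORS if s.index == "H"]
    a_specs = [s for s in DEFAULT_INDICATORS if s.index == "A"]

    units: list[SpatialUnit] = []
    child_adj = nx.Graph()
    town_ids = []
    for i in range(n):
        tid = f"t{i:03d}"
        town_ids.append(tid)
        nbg = int(rng.integers(config.bg_per_town[0], config.bg_per_town[1] + 1))
        if i in city_idx:
            nbg *= config.city_scale
        bg_ids, bg_pops, bg_mos = [], [], []
        bg_units = []
        for b in range(nbg):
            pop = float(rng.lognormal(mu, sigma))
            m = max(0.0, pop * config.births_per_capita * (1 + rng.normal(0, config.mos_noise_sd)))
            bid = f"{tid}_bg{b:03d}"
            raw = {}
            ub = u[i] + rng.normal(0, config.bg_noise_sd)
            cb = c[i] + rng.normal(0, config.bg_noise_sd)
            for s in h_specs:
                raw[s.name] = float(ub + rng.normal(0, config.indicator_noise_sd))
            for s in a_specs:
                raw[s.name] = float(
                    s.polarity * cb + rng.normal(0, config.indicator_noise_sd)
                )
            bg_units.append(
                SpatialUnit(
                    unit_id=bid,
                    name=bid,
                    scale=Scale.BLOCK_GROUP,
                    parent_id=tid,
                    population=pop,
                    mos=m,
                    raw_indicators=raw,
                )
            )
            bg_ids.append(bid)
            bg_pops.append(pop)
            bg_mos.append(m)
        # block-group contiguity within the town: a small grid
        cols = max(1, int(np.ceil(np.sqrt(nbg))))
        child_adj.add_nodes_from(bg_ids)
        for b in range(nbg):
            r, ccol = divmod(b, cols)
            if ccol + 1 < cols and b + 1 < nbg:
                child_adj.add_edge(bg_ids[b], bg_ids[b + 1])
            if b + cols < nbg:
                child_adj.add_edge(bg_ids[b], bg_ids[b + cols])
        town_pop = float(np.sum(bg_pops))
        town = SpatialUnit(
            unit_id=tid,
            name=f"town {i}" + (" (city)" if i in city_idx else ""),
            scale=Scale.TOWN,
            population=town_pop,
            mos=float(np.sum(bg_mos)),
        )
        units.append(town)
        units.extend(bg_units)

    adjacency = nx.relabel_nodes(graph, dict(enumerate(town_ids)))
    return StudyArea(
        units,
        adjacency=adjacency,
        child_adjacency=child_adj,
        name=f"synthetic county (seed {config.seed})",
        source="synthetic generator",
    )


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))
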