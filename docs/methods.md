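# Methods

`vulnstrat` implements a vulnerability-based spatial stratification workflow
for probability-sampling designs: it summarizes each areal unit by two
composite indices, classifies them, and aggregates contiguous units into
sampling strata with comparable measures of size. This note records the
model, its assumptions, the numerical conventions, and the design choices
made where the design was genuinely open.

## The model

**Units and scales.** The base analysis scale is the census block-group,
nested in towns (the intermediate, locally coherent scale at which strata
are assembled). A third scale, `city_block_group`, marks pseudo-towns
produced when an oversized city is split at the block-group level. The
spatial structure the method actually consumes is the *contiguity graph*
over top-scale units — shape and cartography play no role.

**Composite indices.** Each unit carries a hazards/stressors exposure index
`H_s` built from three density proxies (population, average daily traffic,
stationary pollution sources) and an adaptive-capacity/social-character
index `A_s` built from five census indicators (high-school-only education
share, median household income, poverty share, linguistic-isolation share,
minority share). Every raw indicator is min-max standardized over the whole
dataset onto `[0, range_width]` with `range_width = 10`:

    SV = range_width * (raw − min) / (max − min)

then *oriented* so larger values always push the index in its named
direction (polarity −1 indicators are reflected, `10 − SV`; e.g. poverty
lowers capacity, income raises it), and combined as a weighted mean with
weights normalized to sum to one. The result is again in `[0, 10]`.

*Weights* default to equal within each index — the same convention the
Human Development Index uses for its three components — and are fully
configurable through `IndicatorSpec`.

*Aggregation order.* Block-group indicators are aggregated to their parent
town as population-weighted means. Two orders are supported:
`aggregate_then_standardize` (default; raw values aggregated, min/max taken
over towns) and `standardize_then_aggregate` (block-group-level min/max,
then population weighting). The default follows the natural reading of the
procedure — aggregate, then standardize at the reporting scale — but the
orders genuinely differ when block-group dispersion is large, which is why
both are exposed.

**Classification and rating.** Index values are cut into `k = 5` ordinal
classes (very low … very high) at natural breaks: the exact Fisher–Jenks
partition of the sorted values minimizing total within-class sum of squared
deviations, computed by the O(k·n²) dynamic program (no installed library
provides this primitive, so it is implemented here and cross-checked in the
tests against brute-force enumeration). Boundary ties classify *down* —
a value equal to a cut point takes the lower class — which is deterministic
and matters for units sitting exactly on a break. The unit's vulnerability
rating is the ordered pair `V = [H, A]`, 25 combinations from `(1,5)`
(best) to `(5,1)` (worst). The pair is deliberately never collapsed to a
ratio: one unit of hazard is not commensurate with one unit of capacity,
so `H/A = 1/1` and `5/5` must remain distinguishable.

An optional environmental-justice mode excludes the minority-share
indicator from `A_s` (capacity should not be inferred from race in
isolation) and instead flags units combining a high minority share with low
capacity on the remaining indicators.

## Stratification rules and search

A valid design must (hard rules):

* cover every top-scale unit exactly once,
* keep each stratum connected on the contiguity graph,
* use a limited number of strata (guidance 12–15, hard maximum 20),
* give each stratum a measure of size (MOS, expected births/year) within
  `mean ± tolerance`, default tolerance 0.10, where `mean = ΣMOS / n_strata`
  of the supplied data.

Bounds are integers, rounded half-up: a mean of 2,113 at 10% gives
(1,902, 2,324). Within the hard rules the objective is homogeneity: minimize
`Σ_strata [var(h_s) + var(a_s)]` (population-variance convention, matching
the population-SD convention of all reported dispersion statistics).

**Oversized units.** A unit whose own MOS exceeds the upper bound can never
comply and is split at the block-group scale before stratification. The
published-case arithmetic gives the multiplicity as the half-up-rounded MOS
ratio (10,385 / 2,113 = 4.91 → 5). The pipeline additionally never splits
into so few parts that a part *must* exceed the upper bound
(`k = max(round(ratio), ceil(MOS/hi))`): an overweight single-unit stratum
is unfixable, whereas an underweight part can still merge with neighbouring
towns during stratum construction. The child grouping reuses the stratum
search on the unit's internal block-group graph, with the sub-tolerance
capped so no part lands above the county bound. Each resulting pseudo-unit
inherits all of the parent's town-level neighbours (published maps that
would resolve part-level adjacency are not machine-readable) plus edges to
sibling parts along crossing block-group edges.

**Search.** Contiguity-constrained partitioning with size balance is
NP-hard; the solver formalizes what was historically done by manual
iteration as a staged heuristic, deterministic given the seed:

1. *Seeded region growing.* The first restart seeds at the `K` units most
   dispersed in `(h_s, a_s)` space (farthest-point selection); later
   restarts use random seeds. The lowest-MOS region with a free neighbour
   repeatedly claims the frontier unit closest to its index centroid.
2. *Greedy MOS repair.* Boundary units move between adjacent strata while
   the move strictly reduces the total bound-violation penalty.
3. *Feasibility anneal.* Simulated annealing on the relative MOS-violation
   penalty alone, with proposals biased toward violating strata. Moves are
   single boundary transfers or composite two-unit exchanges (a large unit
   trading places with a small one across a boundary); every move keeps all
   strata non-empty and connected by construction, so zero penalty implies
   full hard-rule compliance. The temperature is scaled to the typical
   single-move penalty change, not the (possibly near-zero) starting
   penalty, so the walk can climb out of the repair phase's local minima.
4. *Homogeneity refinement.* Annealing on the within-stratum variance sum
   restricted to feasibility-preserving moves. Because the MOS band is
   narrow relative to unit sizes, lone transfers are rarely admissible; the
   workhorse move is again the boundary exchange, which is nearly
   MOS-neutral.

The best partition over restarts is returned, preferring hard-feasible
solutions; if none is found within the iteration budget the best candidate
is returned flagged infeasible with the violated rules named — mirroring
real designs, which sometimes relax similarity in awkward border strata
rather than break the size rule. An independent validator
(`validate_partition`) re-derives every rule from scratch; solver and
validator agreement is a tested invariant.

On toy graphs (≤ 12 units) the search provably reaches the exhaustive
optimum over all contiguous partitions (tested by enumeration); on 60-town
problems it returns compliant partitions in a few seconds on one CPU.

## Recruitment arithmetic

The per-segment annual recruitment target uses a fixed rounding sequence
chosen to reproduce the published arithmetic exactly: per-stratum target =
`floor(total / n_strata)`, per-year = `round(per_stratum / years)`, inflated
= `round(per_year × (1 + inflation))`. For 1,000 children, 18 strata,
4 years and a 30% loss/dropout allowance: 1,000/18 = 55; 55/4 = 14;
14 + 30% → 18.

## The packaged Worcester County table

The package ships the published town-level summary of the Worcester County,
Massachusetts design (64 top-scale rows: 59 towns plus the city's five
block-group-level sub-strata; 18 strata; 595 block-groups). Conventions:

* Stratum-level MOS reconciliation uses the *printed stratum* values, not
  recomputed town sums — the source's printed sums differ by ±1 from
  column sums because towns were rounded independently.
* The published A classes are not perfectly monotone in the published
  `A_s` values; reproducing the printed class labels is therefore not a
  supported claim, and the packaged classes are carried as data.
* The stratum-18 row count follows the printed table (13 towns) where the
  narrative says 12; the table is taken as authoritative.
* The county's real town contiguity graph was never published (only map
  images). `load_worcester_fixture` therefore attaches a *synthetic*
  adjacency, generated deterministically from the published stratum
  memberships: members of each published stratum are chained, consecutive
  strata linked, plus skip links. Every published stratum is connected
  under it by construction. It supports exercising the contiguity-aware
  machinery on realistic sizes but is not Worcester's geography, and no
  test treats it as such.

## Synthetic counties

The generator produces study areas with the statistical structure the
method assumes, so every stage is testable offline:

* Towns sit on a jittered lattice with Delaunay-derived contiguity
  (connected, simple, planar). Geometry is abstract by design — the method
  consumes adjacency, not shape.
* Block-group populations are lognormal with configurable mean/SD
  (defaults 1,262 / 650, the wide dispersion typical of census
  block-groups); block-group counts per town are uniform on a configurable
  range; MOS = population × births-per-capita (default 0.047, the
  town-level ratio implied by the packaged county) with 5% noise.
* Indicators load on two spatially smooth Gaussian latent fields: an
  "urbanicity" factor driving all three hazard proxies and a capacity
  factor driving the five social indicators through their polarities. The
  capacity field is coupled to urbanicity at a configured negative
  correlation (default −0.6): industrial cores score high-hazard /
  low-capacity, rural periphery the opposite. Two numerical choices make
  the configured value land in the realized sample: the second field is
  Gram–Schmidt-orthogonalized against the first before mixing (spatial
  autocorrelation leaves too few effective degrees of freedom for the
  sample correlation to concentrate on its own), and the latent coupling is
  inflated by the analytic attenuation factor of the indicator noise.
* A configurable fraction of towns is made oversized ("cities") by
  multiplying their block-group count, guaranteeing the split stage is
  exercised.

What the generator does *not* emulate: real cartographic boundaries,
spatially heterogeneous birth rates, indicator distributions with census
tails (percentages are latent-Gaussian, not bounded), or missing data.
Passing tests therefore demonstrate the machinery and its statistical
contracts, not performance on any particular real county.

## Problem sizes and reproducibility

Default experiment sizes are chosen for desk-scale verification: toy graphs
of ≤ 12 units for exhaustive-enumeration comparisons, 60-town counties
(matching the packaged county's scale) for end-to-end runs, and 200+ town
counties for calibration checks. All randomness flows from a single seed
per run; reruns with the same inputs, configuration and seed reproduce
partitions byte-identically, and the run manifest records config and input
digests alongside the step log.

## Known limitations

* The solver is a heuristic; optimality is guaranteed only where
  enumeration can check it. On adversarial graphs (near-trees with tight
  bounds) it may return a flagged-infeasible best effort even when a
  feasible partition exists.
* MOS bounds anchor to `ΣMOS / n_strata` of the supplied data; if a design
  anchors to an externally fixed mean, compute bounds with `mos_bounds`
  directly.
* Splitting redistributes a city's external adjacency to all of its parts,
  which can admit strata a sharper map would forbid.
* Index construction assumes complete indicator matrices; there is no
  imputation.
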