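# vulnstrat

Vulnerability-based spatial sampling stratification for longitudinal
population studies.

Large birth-cohort designs recruit through area probability samples: the
study region is divided into strata that must fully cover it, be
contiguous, be few in number (preferably 12–15, never more than 20), and
carry comparable measures of size — MOS, the expected births per year —
within ±10% of the per-stratum mean. Within those rules, strata should be
as homogeneous as possible in the environmental and sociodemographic
conditions that plausibly shape child health, so that the design captures
the region's heterogeneity up front. `vulnstrat` is a toolkit for building
such designs, aimed at study statisticians and spatial epidemiologists.

## Method

Each areal unit (census block-group, nested in towns) is summarized by two
composite indices on a 0–10 scale:

* **H** — hazards/stressors exposure: population density, average daily
  traffic density, stationary pollution-source density;
* **A** — adaptive capacity / social character: high-school-only education
  share, median household income, poverty share, linguistic-isolation
  share, minority share.

Every indicator is min-max standardized over the dataset,
`SV = 10·(raw − min)/(max − min)`, oriented so larger values move the index
in its named direction (income raises capacity; poverty lowers it), and
combined as a weighted mean `Σ wⱼ·SVⱼ` (equal weights by default).
Population-weighted aggregation carries block-group values to towns. Index
values are classified into five classes at Fisher–Jenks natural breaks and
each unit receives the ordered vulnerability rating **V = [H, A]** — 25
combinations from (1,5), best, to (5,1), worst; deliberately never a ratio.

Stratum construction is contiguity-constrained regionalization: a seeded
region-growing + simulated-annealing search assembles contiguous groups of
towns with MOS inside the bounds while minimizing within-stratum variance
of the two indices; an independent validator re-checks every rule. Units
whose own MOS exceeds the upper bound (a large city) are first split into
comparable contiguous pieces at the block-group scale. See
[docs/methods.md](docs/methods.md) for conventions, the solver design, and
limitations.

The package ships the published Worcester County, Massachusetts design
summary (64 town-scale rows, 18 strata, 595 block-groups) as a reference
fixture, plus a seeded synthetic-county generator that reproduces the
structure the method assumes — nested scales, wide block-group population
dispersion, and the characteristic *negative* correlation between hazard
and capacity fields — so the full pipeline is testable offline.

## Worked example

Validate the published Worcester design against the sampling rules:

```python
import vulnstrat as vs

area, published = vs.load_worcester_fixture()
report = vs.validate_partition(area, published, vs.StratConfig(n_strata=18))
print("strata:", published.n_strata)
print("MOS bounds:", report.mos_lo, "-", report.mos_hi)
print("rules:", {name: r.passed for name, r in report.rules.items()})

lo, hi = vs.mos_bounds(2113, 0.10)
print("published bounds:", (lo, hi))
print("city split:", vs.split_count(10385, 2113))
plan = vs.recruitment_plan(1000, 18, 4, 0.30)
print("recruits/segment/year:", plan.per_year_inflated)
```

prints

```
strata: 18
MOS bounds: 1902 - 2325
rules: {'coverage': True, 'no_overlap': True, 'strata_count': True, 'contiguity': True, 'mos_bounds': True}
published bounds: (1902, 2324)
city split: 5
recruits/segment/year: 18
```

The 18 published strata all satisfy the MOS rule (printed range 1,969–2,310
against bounds 1,902–2,324 anchored at the published mean of 2,113; the
validator's 2,325 comes from anchoring at the unrounded data mean, 2,113.4).
The city's MOS of 10,385 is 4.91× the target mean, so it splits into five
block-group-level strata, and the recruitment arithmetic
(1,000/18 = 55; 55/4 = 14; 14 + 30% ≈ 18) gives 18 recruits per segment per
year. Note the fixture's adjacency is a synthetic stand-in (the real town
contiguity map was never published in machine-readable form); contiguity
results on the fixture demonstrate the machinery, not Worcester's geography.

Build a design from scratch on a synthetic county:

```python
area = vs.generate_county(vs.SynthConfig(seed=17, n_towns=60))
cfg = vs.PipelineConfig(strat=vs.StratConfig(n_strata=15, random_seed=17))
res = vs.run_pipeline(area, config=cfg)
print("feasible:", res.partition.feasible)
print("overall pass:", res.report.overall_pass)
df = res.homogeneity
print(df[["stratum_id", "n_units", "mos", "sd_h_s", "sd_a_s"]].head(4).round(2).to_string(index=False))
print("between-strata share h_s: %.2f" % df.attrs["between_share_h_s"])
```

prints

```
feasible: True
overall pass: True
stratum_id  n_units     mos  sd_h_s  sd_a_s
         1        7 2004.98    2.45    2.75
         2        3 2155.13    1.38    0.46
         3        4 1979.06    0.89    0.68
         4        4 1878.57    0.72    0.45
between-strata share h_s: 0.75
```

i.e. a fully compliant 15-stratum partition in which three quarters of the
hazard-index variance lies *between* strata. Reruns with the same seed
reproduce the partition byte-identically.

A thin CLI wraps the same functions:

```bash
vulnstrat synth --seed 17 --towns 60 --out county
vulnstrat run --units county_units.csv --adjacency county_adjacency.csv \
              --n-strata 15 --seed 17 --out design/
vulnstrat validate --units county_units.csv --adjacency county_adjacency.csv \
                   --partition design/partition.csv
```

`validate` exits 0 only on full rule compliance.

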