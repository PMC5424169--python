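# Methods

## Model overview and assumptions

The simulator is an annual-cycle, individual-based, forward-in-time
model of stage-structured perennial plants on a grid of square cells.
Its central assumptions:

* **Selection acts on seedling survival only.** Climatic variation is
  assumed to filter establishment, not adult survival or fecundity;
  adults persist with a climate-independent annual probability s_a.
  This is what produces both the extinction debt (maladapted adults
  persist while producing doomed offspring) and the slow evolutionary
  response (low population turnover).
* **Local adaptation.** Each cell's environment defines the selective
  optimum for three quantitative traits mapped one-to-one onto the
  environmental variables (temperature, precipitation, carbonate).
  Populations are founded locally adapted (trait means equal to local
  conditions).
* **Uncorrelated selection and mutation.** The selection matrix W is
  diagonal and mutational effects are isotropic — no genetic trade-offs
  between traits.
* **Closed grids.** Landscapes are islands: seeds crossing the boundary
  are lost (a `reflecting` alternative is not implemented; grids
  represent isolated massifs).

## Yearly event order

mating → seed dispersal → aging → germination/seedbank survival →
clonal reproduction → seedling competition → **census** → seedling
viability selection (→ ceiling regulation, burn-in only).

The census sits between competition and selection, so recorded seedling
numbers and the "adaptive seedling survival" statistic (the mean Gaussian
viability of censused seedlings) reflect competition but not yet
selection, and recorded trait moments are pre-selection.

**Seedbank timing.** Fresh seeds enter the bank *after* the germination
event of their production year, so their first germination opportunity
comes exactly one year after seed set; a species with `max_seed_age = 1`
therefore has no persistent seedbank. A cohort gets germination
opportunities at ages 1..A (A = `max_seed_age`) and is discarded when it
would exceed A. Non-germinating seeds survive each year with probability
`seed_survival`.

**Stage timing.** Seedlings surviving selection become first-year
pre-adults at the next aging event, spend exactly two pre-adult years
(surviving each with probability s_a), and enter the adult pool at the
third census after germination.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| L | loci | 10 | unlinked additive diploid loci per genome, pleiotropic for all 3 traits |
| μ | /allele/yr | 0.001 | middle of the sensitivity grid {0.01, 0.001, 0.0001} |
| v | trait² | 0.05 | variance of each trait component of a mutational effect |
| h² target | — | 0.3 | founding narrow-sense heritability; V_E derived from it |
| s_a | /yr | 0.9 | adult (and pre-adult) annual survival; {0.7, 0.8, 0.9} span life expectancies of 3–10 years |
| V_s | trait² | 1 × V_SENM | niche width as the weakest plausible selection; multipliers 0.5, 0.33 strengthen it |
| ceiling | adults | 8,000 | burn-in cap above any equilibrium, preventing the unbounded expansion possible on static gradients |
| K_max | adults | 1000/300/500/5000 | nominal single-patch adult capacities of the four species presets |

Species presets carry the documented qualitative contrasts (seed number,
seedbank longevity 1/5/7/1 years, clonality, dispersal ability); their
fecundity/germination/clonal rates are this package's own defaults,
chosen for demographic viability at the preset capacities. A scaled-down
`micro` preset (K = 300) is the default focal species for desk-scale
studies.

## Standardization and calibration

* **Environmental scale.** Traits, optima and selection variances live
  on z-score scales fitted to the initial (2010) landscape, making V_s
  multipliers comparable across variables; raster I/O keeps raw units.
  A variable with zero variance across occupied cells carries no niche
  information and is released from selection (V_s → very large).
* **k_c (competition).** Calibrated by root-finding on the deterministic
  single-patch stage recursion (no selection mortality, perfectly
  adapted) so the adult equilibrium equals K_max. Realized populations
  in spatial runs sit well below K_max because selection and migration
  loads cut recruitment.
* **V_E (heritability).** Founding standing variation is created by
  applying the standard mutation operator 100 times to every allele of
  founders whose genotypic values equal the local optimum. V_E is then
  set once from the realized founder genetic variance as
  V_E = V_G (1 − h²)/h², and held fixed; heritability is emergent
  afterwards. With μ = 0.001 the founder V_G (≈ 100·2Lμv = 0.1) is close
  to the mutation–selection-balance variance, so h² ≈ 0.3 remains
  approximately valid through time. The superficially similar
  alternative — one N(0, v) jitter per allele — would set founder
  V_G = 2Lv = 1.0 (an order of magnitude above balance) and hence a V_E
  so large that realistic climate shifts barely select; it was rejected
  for that internal inconsistency.
* **Single-genotype baseline.** No-evolution runs give every individual
  the per-grid mean environment over predicted-occupied cells as a fixed
  genotype (mutation disabled, dispersal intact) and reuse the V_E of
  the corresponding evolving configuration so phenotypic noise is
  comparable.

## Synthetic data generator

`fixtures` emulates a small alpine block: a linear elevation ramp
(800 m by default) with lapse-rate temperature (6.5 °C/km) plus
cell-level noise, precipitation increasing with elevation plus a smooth
random field, and carbonate bedrock as a smoothed random field squashed
to 0–100%. The focal niche sits at 75% of the ramp — near the top, as
for high-alpine endemics — so warming contracts the statically suitable
band immediately and eventually pushes it off-grid. Scenario severities
apply spatially uniform trends of 0.1875 / 0.34375 / 0.5 °C per decade
(1.5 / 2.75 / 4 °C by 2090; the severe case is RCP8.5-like) with small
precipitation declines. Pseudo-niche-model predictions displace the true
niche centre by a per-model number of niche widths, yielding a TSS
spread whose weakest member falls below the 0.3 discard line.

What the generator does **not** emulate: realistic topography, spatial
autocorrelation of interannual weather (climate changes only via smooth
decadal trends), correlations among bioclimatic variables, and
observation error in the presence data. Passing tests on these fixtures
therefore demonstrates the internal consistency of the eco-evolutionary
machinery and the qualitative phenomenology (extinction debt, adaptive
collapse and rescue, age-structure shifts), not calibrated forecasts for
real species.

## Study conditions at desk scale

The replicated micro-study used by the test suite runs one synthetic
species (micro preset) on a 16 × 16 grid with 200 burn-in years, the
severe scenario, μ = 0.001, V_s = V_SENM and 3 replicates sharing one
burnt-in snapshot — small enough to complete in a few minutes on one
CPU while exercising every operation in the package. The severe scenario
is the study condition because on this fixture moderate warming is fully
rescued by adaptation (no extinction debt to observe). The burn-in of
200 years (rather than thousands) is adequate here because demographic
equilibrium is reached within decades and founder genetic variance is
already near mutation–selection balance; the burn-in diagnostics (trend
of total adults over the final 10% of years) verify this.

## Numerical choices

* **Thresholding ties** in the TSS-maximizing presence threshold resolve
  to the lowest candidate probability.
* **Dispersal** rounds continuous displacements to cell offsets; the
  kernel mean is therefore reproduced up to half a cell.
* **Ceiling regulation** retains a uniform random subset of established
  plants (seedlings + pre-adults + adults jointly) when a patch exceeds
  the cap, and empties patches (including seedbanks) outside the
  predicted range during burn-in. A guard trips if any patch exceeds
  10 × the ceiling.
* **Determinism.** One NumPy Generator drives a run; replicates and
  pipeline stages derive independent streams from spawned seed
  sequences. Identical (seed, config) runs produce identical record
  tables, and population snapshots (directories of `.npy` arrays plus a
  JSON manifest, seedbank cohorts in canonical age order) are
  byte-stable under save → load → save.
* **Degenerate inputs** are signalled, not silently absorbed: empty
  truth classes for TSS, all-equal probability maps, fewer than two
  occupied cells for a niche width, zero phenotypic variance for
  heritability, infeasible life histories (zero-density growth < 1) for
  the k_c calibration.

## Design choices where the design was open

* Mutation counts are per-allele Bernoulli(μ) over the 2L allele copies,
  not genome-level Poisson.
* Clonal offspring pass through the mutation step: mutation is treated
  as a property of genome copying, whatever the reproductive route.
* Pre-adults are counted in the competition term (they are established
  plants) — a `count_pre_adults` switch restores adults-only.
* A cell is "occupied" if it holds at least one established plant
  (seedling, pre-adult or adult); seeds in the bank do not count. An
  `occupancy_stage="adults"` switch restricts to adults.
* Ensemble weights are raw TSS values normalized over retained models.
* Mate choice is uniform among patch adults with selfing allowed.

## Known limitations

* Under a constant climate an uncapped population expands slowly beyond
  the statically suitable band (genetic variance is not constrained), so
  constant-climate controls drift upward in occupancy rather than
  holding exactly flat; this is inherent to unconstrained adaptation on
  a static gradient and is the reason burn-in uses ceiling regulation.
* The static-mask "suitability" recorded during forcing comes from the
  same logistic niche response that generated the truth data — a
  stand-in for projections of fitted niche models, not a fitted model.
* No pollen flow, density-dependent fecundity, dominance, epistasis or
  linkage; between-grid migration is disallowed (grids are independent).
* Runtime scales with total seed production; very fecund species on
  large grids are the main cost driver.
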