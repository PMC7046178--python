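# Methods

## Model structure

The simulator couples four components on a rectangular patch grid:

1. **Landscape and climate** (`landscape`). Climate varies only along the
   gradient axis (columns). Integer climate zones are constant within
   200 m bands; during the shift phase the band pattern moves toward the
   cold end by an integer number of patch widths per year, so warmer
   zones (11, 12, …) enter at the warm edge while the coldest zones leave
   the grid. Zones are integers throughout; there is no sub-patch
   interpolation of climate. A partially entered band is treated as
   present (the warmest zone is `10 + ceil(shift/band_width)` mid-shift).
   Each shift year's movement is applied at the start of that year, so
   the occupancy recorded at the end of the shift phase reflects the
   fully displaced climate field.

2. **Climate response** (`response`). One response curve per genotype
   maps climate distance d = |optimum − zone| to a multiplier
   ClimEff ∈ [0, 1] applied to every maximum demographic rate. Curves are
   symmetric, weakly decreasing tables evaluated with linear
   interpolation at fractional distances and 0 beyond the table. The
   same curve governs all rates of a genotype, and curves are identical
   across life histories, isolating the locally-adapted-vs-plastic
   contrast from everything else.

3. **Demography** (`demography`). Stage-structured annual cycle:
   germination → survival → pollen production/dispersal → seed
   production/dispersal → transition; individuals reproduce at their
   pre-transition stage, and annual adults die at year end after
   reproducing. All fates are Bernoulli per individual, drawn as
   binomials per (patch, genotype, stage) cohort. Competition enters as
   `Rate = Max.Rate × (ClimEff − CompEff × CA)` clamped to [0, 1], where
   CA is the summed size of strictly larger individuals (germination:
   all established individuals). Fecundity has no competition term.
   Annuals are regulated instead by a 7000-seedlings-per-patch cap,
   applied as a survival-to-reproduction probability 7000/n. Seeds that
   fail to germinate are removed (no seed bank).

4. **Dispersal** (`dispersal`). The 2Dt kernel is parameterized by its
   mean distance; the scale u is recovered from the closed-form mean
   (shape p = 1 by default, giving the classic fat tail: most propagules
   stay in the source patch, a few travel far). Patch-to-patch
   probabilities integrate the density over destination footprints from
   the source center — subsampled midpoint quadrature, with the origin
   cell integrated exactly in polar coordinates from the closed-form
   radial CDF because the density is strongly peaked there. All four
   boundaries absorb: propagules leaving the grid are lost, since the
   landscape is a slice of a larger range and wrap-around would couple
   the warm and cold edges.

## Genetics

A single diploid locus with alleles A1/A2/A3 (climate values 4/6/8)
yields six genotypes with heterozygote optima at the homozygote means.
Pollen grains carry one Mendelian-sampled allele; pollen pools are
accumulated per patch as expected allele counts (half each for
heterozygotes) rather than per-grain draws, and paternal alleles are
drawn from pool frequencies. Selfing is implicitly allowed through
within-patch pollen retention; there is no mutation and no evolution of
plasticity. Plastic species are a single genotype (optimum 6) with one
broad curve, so the Mendelian machinery reduces to breeding true.

## Poisson form of reproduction and dispersal

Seed and pollen numbers per individual are Poisson with mean
`Max × ClimEff` (the model specifies only the mean; Poisson keeps counts
integer and stochastic). Because each propagule then disperses
independently, the post-dispersal counts at every destination are
independent Poisson variables whose means are the expected emission
fields convolved with the discretized kernel. The engine therefore draws
post-dispersal seed pools and pollen pools directly as Poisson fields
with FFT-convolved means (zero padding = absorbing boundary). This is
*exactly* the same distribution as producing integer counts per patch
and allocating them multinomially — not an expected-value approximation —
and is what makes 200-year, 4-replicate tree scenarios run in seconds
per replicate on one CPU. The per-source multinomial operator
(`dispersal.disperse`) is retained for dispersing externally supplied
integer counts and for tests, with a deterministic expected-value mode.

## Default response curves (calibration)

Exact curve values are a calibration choice; the defaults, all
configurable, are:

* **Locally adapted genotypes**: d → [1.0, 0.75, 0.40, 0.10, 0.0].
  Narrow curves whose staggered optima (4, 5, 6, 6, 7, 8) give the
  species near-maximal fitness across zones 3–9 and positive fitness
  over zones 1–11.
* **Plastic genotype** (optimum 6): the linear ramp
  ClimEff(d) = max(0, 1 − d/5) → [1.0, 0.8, 0.6, 0.4, 0.2, 0.0].
  A linear decline toward the range margin is the simplest shape
  consistent with observed demographic declines with marginality; it is
  strictly broader than any single locally adapted curve, yet strictly
  below the locally adapted species' pointwise fitness envelope at every
  nonzero distance. Those two properties are the structural premise of
  the comparison — the plastic species tolerates every zone a single
  genotype cannot, while the locally adapted species outperforms it
  toward the range edges — and the defaults are the minimal tables
  satisfying both.
* **Widely plastic genotype**: the zone-indexed pointwise maximum of the
  six locally adapted curves (a hypothetical genotype combining broad
  tolerance with edge fitness).
* **Softened locally adapted** (the `PLF` scenarios): every penalty
  halved, ClimEff′ = 1 − (1 − ClimEff)/2, making cumulative multi-year
  climate impacts on a perennial comparable to single-year impacts on an
  annual.

Quantitative occupancy and range-loss levels are conditional on these
tables; the directional contrasts (equilibrium range ordering, genotype
sorting, the fast-shift reversal for trees) are robust to moderate
reshaping.

## Scenarios, phases and replication

Life-history presets (annual / perennial / tree) carry the maximum
germination, survival, transition and fecundity schedules, sizes and
competition coefficients, and the equilibration lengths (20 / 100 / 200
years ≈ 20 generations). Scenario codes (`AL.20`, `TP.40.F`, …) resolve
species, adaptation mode, mean seed dispersal, landscape variant and
phase durations; restabilization equals equilibration (10× for `.R+`).
Landscape variants: standard; coldest band 3× wide (extended grid);
doubled shift speed; both combined; and an 8 km shallow gradient with
4×-wide bands shifting 80 m/yr.

Initialization places each genotype wherever its year-0 ClimEff is
positive — deliberately broader than the expected equilibrium — at 200
seeds (annual), 20 small adults (perennial) or 20 saplings (tree) per
patch per genotype. These densities are calibration knobs chosen to be
large enough to avoid stochastic extinction during equilibration.

Each replicate runs on an independent RNG stream spawned from the
scenario seed (`numpy` `SeedSequence`), so results are exactly
reproducible for a given (configuration, seed) and replicates are
independent. Occupancy (patches holding ≥ 1 reproductive adult — annual
adults; perennial/tree small+ stages; a configurable mask) is recorded
every year; full count grids are kept at the three phase boundaries.
Annual adult occupancy is recorded before the year-end die-off, so it
reflects the plants that reproduced that year.

## Numerical choices and degenerate inputs

* Stencil truncation for the multinomial operator: half-width from the
  closed-form radial tail so omitted mass < 10⁻³ (error if the implied
  radius is under one patch); engine convolution kernels instead span
  every in-grid offset, so nothing reachable is truncated.
* FFT convolution can produce tiny negative values; means are clipped at
  zero before Poisson draws.
* Empty pollen pools give zero seeds (pollen limitation); empty patches
  are reported as missing in allele-frequency and modal-genotype maps;
  modal-genotype ties break toward the lower canonical genotype index.
* Percent range change from a zero starting occupancy is undefined and
  reported as NaN.
* Rates are clamped to [0, 1] after the competition term; counts are
  64-bit integers throughout (annual seed pools reach ~10⁶ per patch).

## What the simulations do and do not show

The landscape is a best case: climate is the only constraint (no soils,
disturbance, interspecific competition or fragmentation), habitat is
continuous, and the gradient is steeper than most latitudinal ones.
Genetics are a single locus with fixed alleles — best read as
populations (cold-adapted, intermediate, warm-adapted) rather than
literal genotypes — with no mutation and no evolving plasticity.
Dispersal is isotropic and stationary. Passing tests therefore
demonstrate the internal logic of the local-adaptation/life-history/
dispersal interaction, not predictions for particular real species.
One consequence of the calibrated defaults worth noting: with the high
printed fecundities and the fat-tailed kernel, any patch with even a few
percent of maximum fitness receives ample seed, so colonization lags at
the leading edge are short and simulated range losses during the shift
are mostly set by trailing-edge suitability. Calibrations with
near-zero fitness over the outer zones of the plastic species' range
would lengthen plastic lags and enlarge losses accordingly.

## Problem sizes

The shipped experiments run at full scale: 50 × 100 patches (400
columns for the shallow-gradient variant), complete equilibration/shift/
restabilization phases, and 4 replicates per scenario, in both the
acceptance script (~3 minutes total) and the end-to-end tests.
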