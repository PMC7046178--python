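# rangeshift

A spatially explicit, stochastic simulator of plant range shifts along a
moving climate gradient. It contrasts **locally adapted** species — six
diploid genotypes at a single climate locus, each with a narrow thermal
optimum — with **plastic** species — a single genotype with one broad
tolerance curve — across three life histories (annual, perennial, tree),
and measures how well each tracks a climate shift through occupancy at
three timepoints: after equilibration (*Stable*), at the end of a 20-year
shift (*Shift*), and after re-equilibration (*Restab*).

It is aimed at researchers studying eco-evolutionary dynamics of range
shifts: how local adaptation, dispersal distance, generation time and the
speed/steepness of a climate gradient interact to set colonization lags at
the leading edge and extinction at the trailing edge.

## Model

The landscape is a grid of 20 × 20 m patches (standard: 50 × 100, a
1 × 2 km slice of an elevation gradient) partitioned into 200 m-wide
climate bands with integer zones 10 (warm) … 1 (cold). After an
equilibration phase, bands shift one patch width per year for 20 years
(configurable), so zones run 12 … 3 at the end.

Each genotype carries a climate-effect multiplier ClimEff ∈ [0, 1], a
function of the distance *d* between its optimum and the local zone.
Alleles A1, A2, A3 have climate values 4, 6, 8; heterozygote optima are
the allele means. Every demographic rate is

```
Rate = Max.Rate × (ClimEff[d] − CompEff × CA),   clamped to [0, 1]
```

where CA is the total size (occupied area for perennials, basal area for
trees) of larger individuals in the patch, and fecundity is climate-only:

```
Seed/Pollen = Max.Seed/Pollen × ClimEff[d]
```

Each year applies, in order: germination (no persistent seed bank),
survival, pollen production and dispersal, seed production and dispersal,
and stage transition. Fates are Bernoulli per individual (binomial per
cohort), N1 ~ Bern(N0, Rate). Seeds draw a maternal allele uniformly
from the mother and a paternal allele from the patch's pollen-pool allele
frequencies; patches without pollen set no seed. Annuals are capped at
7000 seedlings per patch and die after reproducing.

Seeds and pollen disperse by a fat-tailed 2Dt kernel
f(r) = p/(πu) (1 + r²/u)^−(p+1) with mean distance
√(πu)/2 · Γ(p−½)/Γ(p); only the mean is specified per life history
(p defaults to 1) and the scale u is recovered from it. The kernel is
integrated over patch footprints; grid boundaries are absorbing.

## Worked example

```
$ rangeshift simulate AL.20 --seed 1 --replicates 4
AL.20: annual, 6 genotype(s), seed mean 20.0 m, 20+20+20 years, 4 replicate(s), seed 1
   stable:   5000.0 patches occupied (100.0 % of landscape)
    shift:   4500.0 patches occupied ( 90.0 % of landscape)
   restab:   4500.0 patches occupied ( 90.0 % of landscape)
```

The locally adapted annual with 20 m mean seed dispersal fills the whole
5000-patch landscape after equilibration. During the shift it loses the
warmest emerging band (zone 12, where no genotype has positive fitness) —
a 10 % range loss — and holds the rest because cold-adapted genotypes are
already in place where conditions improve; occupancy does not recover by
Restab because zone 12 remains unsuitable. `rangeshift catalog` lists all
scenario codes (`AP.1`, `PPW.20`, `TL.40.F`, …); `--out DIR` writes
per-year occupancy CSVs, phase-boundary grid snapshots (counts, modal
genotype, allele frequencies) and a replicate mean ± SD summary, and
`rangeshift summarize DIR` recomputes the summary table from them.

The same machinery is available as a library:

```python
from rangeshift import parse_code, run_scenario, percent_change

result = run_scenario(parse_code("TL.40", replicates=4), seed=1,
                      through_phase="shift")
stable = result.occupancy_at("stable").mean()
shift = result.occupancy_at("shift").mean()
print(percent_change(stable, shift))   # ≈ -4.6 (% range change)
```

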