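"""Within-year demography: germination, competition, survival, stage
transitions, and seed/pollen production with Mendelian genotype assignment.

Three stage-structured life histories are shipped as presets:

* ``annual`` — seed and adult; adults die after reproducing; density
  regulation through a per-patch seedling cap;
* ``perennial`` — seedling, small, medium and large adults; competition
  through the surface area occupied by larger individuals;
* ``tree`` — seedling, sapling, then small/medium/large adults;
  competition through the basal area (BA) of larger individuals.

Every realized rate is Max.Rate x (ClimEff - CompEff x CA), clamped to
[0, 1], where CA is the total size of the relevant competitors in the
patch; individual fates are Bernoulli, drawn as binomials per cohort.
Fecundity is climate-only.  Seed and pollen numbers per individual are
Poisson with mean Max x ClimEff.

Count arrays are indexed ``(stage, genotype, row, col)``; seed pools
``(genotype, row, col)``; pollen pools ``(allele, row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .response import (
    DEFAULT_ALLELES,
    LOCALLY_ADAPTED_CURVE,
    PLASTIC_CURVE,
    AlleleSet,
    ResponseCurve,
    six_genotypes,
    soften_curve,
    widely_plastic_curve,
)

__all__ = [
    "StageSchedule",
    "GeneticSystem",
    "PopulationState",
    "ANNUAL",
    "PERENNIAL",
    "TREE",
    "species_preset",
    "competitor_load",
    "realized_rate",
    "annual_density_cap",
    "germinate",
    "survive",
    "transition",
    "pollen_emission",
    "seed_emission",
]


@dataclass(frozen=True)
class StageSchedule:
    """One life history's stage structure and demographic maxima.

    ``sizes`` is the per-individual size in m^2 (occupied area for
    perennials, basal area for trees) used as the competition currency;
    ``comp_survival[s]`` scales the total size of strictly larger
    individuals when computing stage ``s`` survival and transition, and
    ``comp_germination`` scales the total size of all established
    individuals for germination.  Annuals carry no sizes; their only
    density regulation is the per-patch ``seedling_cap``.
    """

    name: str
    stage_names: tuple[str, ...]
    max_germination: float
    max_seeds: tuple[float, ...]
    max_pollen: tuple[float, ...]
    max_survival: tuple[float, ...]
    max_transition: tuple[float, ...]
    sizes: tuple[float, ...] | None
    comp_germination: float
    comp_survival: tuple[float, ...]
    seedling_cap: int | None
    equilibration_years: int
    annual: bool = False
    init_stage: int = 0  # stage at which populations are initialized
    init_density: int = 20  # individuals (or seeds) per eligible patch/genotype

    def __post_init__(self) -> None:
        n = len(self.stage_names)
        for attr in ("max_seeds", "max_pollen", "max_survival", "max_transition", "comp_survival"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} must have one entry per stage")
        if self.sizes is not None and len(self.sizes) != n:
            raise ValueError("sizes must have one entry per stage")
        if self.max_transition[-1] != 0:
            raise ValueError("the largest stage never transitions")

    @property
    def n_stages(self) -> int:
        return len(self.stage_names)

    @property
    def reproductive(self) -> np.ndarray:
        """Boolean mask over stages that produce seed or pollen (the
        'adult' stages used for occupancy)."""
        return (np.asarray(self.max_seeds) > 0) | (np.asarray(self.max_pollen) > 0)


ANNUAL = StageSchedule(
    name="annual",
    stage_names=("adult",),
    max_germination=0.3,
    max_seeds=(300,),
    max_pollen=(8_000,),
    max_survival=(0.0,),
    max_transition=(0.0,),
    sizes=None,
    comp_germination=0.0,
    comp_survival=(0.0,),
    seedling_cap=7_000,
    equilibration_years=20,
    annual=True,
    init_stage=-1,  # initialized as seeds
    init_density=200,
)

PERENNIAL = StageSchedule(
    name="perennial",
    stage_names=("seedling", "small", "medium", "large"),
    max_germination=0.45,
    max_seeds=(0, 150, 1_000, 5_000),
    max_pollen=(0, 800, 10_000, 100_000),
    max_survival=(0.3, 0.5, 0.65, 0.7),
    max_transition=(0.3, 0.15, 0.1, 0.0),
    sizes=(0.004, 0.06, 0.25, 2.0),
    comp_germination=0.003,
    comp_survival=(0.005, 0.003, 0.001, 0.0005),
    seedling_cap=None,
    equilibration_years=100,
    init_stage=1,  # small adults
)

TREE = StageSchedule(
    name="tree",
    stage_names=("seedling", "sapling", "small", "medium", "large"),
    max_germination=0.6,
    max_seeds=(0, 0, 150, 1_000, 5_000),
    max_pollen=(0, 0, 800, 10_000, 100_000),
    max_survival=(0.6, 0.85, 0.96, 0.98, 0.99),
    max_transition=(0.15, 0.11, 0.06, 0.02, 0.0),
    sizes=(0.0001, 0.003, 0.07, 0.14, 0.5),
    comp_germination=0.08,
    comp_survival=(0.1, 0.07, 0.02, 0.01, 0.0),
    seedling_cap=None,
    equilibration_years=200,
    init_stage=1,  # saplings
)

_PRESETS = {"annual": ANNUAL, "perennial": PERENNIAL, "tree": TREE}


def species_preset(name: str) -> StageSchedule:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown species preset {name!r}") from None


# ---------------------------------------------------------------------------
# genetics


@dataclass(frozen=True)
class GeneticSystem:
    """Genotypes, their climate-response curves and Mendelian machinery.

    ``emission[g, a]`` is the expected fraction of genotype g's pollen
    grains carrying allele a (1 for homozygotes, 1/2 each for
    heterozygotes).  ``mating[g, a, h]`` is the probability that a seed of
    mother genotype g sired by a pollen grain of allele a has genotype h
    (the maternal allele is drawn uniformly from the mother's pair).
    ``dosage[g, a]`` counts allele copies per individual, for frequency
    maps.
    """

    genotype_names: tuple[str, ...]
    optima: np.ndarray
    curves: tuple[ResponseCurve, ...]
    allele_labels: tuple[str, ...]
    emission: np.ndarray
    mating: np.ndarray
    dosage: np.ndarray

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_names)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)

    def clim_eff_columns(self, zones: np.ndarray) -> np.ndarray:
        """(n_genotypes, n_cols) ClimEff for each genotype along a zone row."""
        return np.stack(
            [np.asarray(c.at_zone(o, zones), dtype=float) for o, c in zip(self.optima, self.curves)]
        )

    @property
    def init_eligible_breadth(self) -> np.ndarray:
        return np.array([c.breadth for c in self.curves])


def _build_mendelian(genotypes, allele_labels):
    """Emission, mating and dosage tensors for a set of diploid genotypes."""
    idx = {a: i for i, a in enumerate(allele_labels)}
    pair_to_g = {tuple(sorted(g.alleles)): k for k, g in enumerate(genotypes)}
    G, A = len(genotypes), len(allele_labels)
    emission = np.zeros((G, A))
    dosage = np.zeros((G, A))
    mating = np.zeros((G, A, G))
    for k, g in enumerate(genotypes):
        for a in g.alleles:
            emission[k, idx[a]] += 0.5
            dosage[k, idx[a]] += 1.0
        for b_i, b in enumerate(allele_labels):
            for a in g.alleles:
                h = pair_to_g[tuple(sorted((a, b)))]
                mating[k, b_i, h] += 0.5
    return emission, mating, dosage


def locally_adapted_system(
    alleles: AlleleSet = DEFAULT_ALLELES, curve: ResponseCurve = LOCALLY_ADAPTED_CURVE
) -> GeneticSystem:
    """Six locally adapted genotypes sharing one distance-indexed curve."""
    genotypes = six_genotypes(alleles)
    emission, mating, dosage = _build_mendelian(genotypes, alleles.labels)
    return GeneticSystem(
        genotype_names=tuple(g.name for g in genotypes),
        optima=np.array([g.optimum(alleles) for g in genotypes]),
        curves=tuple(curve for _ in genotypes),
        allele_labels=alleles.labels,
        emission=emission,
        mating=mating,
        dosage=dosage,
    )


def softened_system(alleles: AlleleSet = DEFAULT_ALLELES) -> GeneticSystem:
    """Locally adapted genotypes with every climate penalty halved."""
    return locally_adapted_system(alleles, soften_curve(LOCALLY_ADAPTED_CURVE))


def _single_genotype_system(name: str, optimum: float, curve: ResponseCurve) -> GeneticSystem:
    return GeneticSystem(
        genotype_names=(name,),
        optima=np.array([optimum]),
        curves=(curve,),
        allele_labels=("P",),
        emission=np.ones((1, 1)),
        mating=np.ones((1, 1, 1)),
        dosage=np.full((1, 1), 2.0),
    )


def plastic_system(optimum: float = 6.0, curve: ResponseCurve = PLASTIC_CURVE) -> GeneticSystem:
    """A single broadly tolerant genotype with no genetic subdivision."""
    return _single_genotype_system("P", optimum, curve)


def widely_plastic_system(
    alleles: AlleleSet = DEFAULT_ALLELES, curve: ResponseCurve = LOCALLY_ADAPTED_CURVE
) -> GeneticSystem:
    """A single genotype tracing the locally adapted species' fitness envelope."""
    la = [(g.optimum(alleles), curve) for g in six_genotypes(alleles)]
    return _single_genotype_system("PW", 6.0, widely_plastic_curve(la))


def genetic_system(mode: str, softened: bool = False, alleles: AlleleSet = DEFAULT_ALLELES) -> GeneticSystem:
    if mode == "locally_adapted":
        return softened_system(alleles) if softened else locally_adapted_system(alleles)
    if softened:
        raise ValueError("the softened curve applies to the locally adapted mode")
    if mode == "plastic":
        return plastic_system()
    if mode == "widely_plastic":
        return widely_plastic_system(alleles)
    raise ValueError(f"unknown adaptation mode {mode!r}")


# ---------------------------------------------------------------------------
# state


@dataclass
class PopulationState:
    """Integer counts per (stage, genotype, patch) plus seed/pollen pools."""

    counts: np.ndarray  # (n_stages, G, R, C) int64
    seed_pool: np.ndarray  # (G, R, C) int64
    pollen_pool: np.ndarray  # (n_alleles, R, C) int64

    @classmethod
    def empty(cls, schedule: StageSchedule, genetics: GeneticSystem, shape: tuple[int, int]):
        R, C = shape
        return cls(
            counts=np.zeros((schedule.n_stages, genetics.n_genotypes, R, C), dtype=np.int64),
            seed_pool=np.zeros((genetics.n_genotypes, R, C), dtype=np.int64),
            pollen_pool=np.zeros((genetics.n_alleles, R, C), dtype=np.int64),
        )

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.seed_pool.copy(), self.pollen_pool.copy())

    @property
    def total_established(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# rates and loads


def competitor_load(
    counts: np.ndarray, schedule: StageSchedule, focal_stage: int | None
) -> np.ndarray:
    """CA: total competitor size (m^2 area or BA) per patch.

    For survival/transition of ``focal_stage`` only strictly larger stages
    compete; for germination (``focal_stage=None``) all established
    individuals do.  Annuals (no sizes) always return 0.
    """
    R, C = counts.shape[-2:]
    if schedule.sizes is None:
        return np.zeros((R, C))
    sizes = np.asarray(schedule.sizes)
    lo = 0 if focal_stage is None else focal_stage + 1
    if lo >= schedule.n_stages:
        return np.zeros((R, C))
    per_stage = counts[lo:].sum(axis=1)  # sum over genotypes -> (stages, R, C)
    return np.tensordot(sizes[lo:], per_stage, axes=(0, 0))


def realized_rate(max_rate: float, clim_eff, comp_coeff: float, ca) -> np.ndarray:
    """Rate = Max.Rate x (ClimEff - CompEff x CA), clamped to [0, 1]."""
    rate = max_rate * (np.asarray(clim_eff, dtype=float) - comp_coeff * np.asarray(ca, dtype=float))
    return np.clip(rate, 0.0, 1.0)


def annual_density_cap(n_seedlings, cap: int = 7_000):
    """Survival-to-reproduction probability once a patch exceeds the cap."""
    n = np.asarray(n_seedlings, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(n > cap, cap / np.where(n > 0, n, 1.0), 1.0)
    out = np.clip(prob, 0.0, 1.0)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# yearly events (each mutates the state in place)


def germinate(
    state: PopulationState,
    eff: np.ndarray,
    schedule: StageSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Germinate the seed pools into the recruit stage; empty the pools.

    ``eff`` is the (G, R, C) ClimEff field.  Perennial/tree germination is
    reduced by crowding from all established individuals; annual
    germination is climate-only, followed by the per-patch seedling cap
    applied as survival to reproduction.  There is no persistent seed
    bank: non-germinating seeds are removed.  Returns the recruit field.
    """
    if schedule.annual:
        rate = realized_rate(schedule.max_germination, eff, 0.0, 0.0)
        germs = rng.binomial(state.seed_pool, np.broadcast_to(rate, state.seed_pool.shape))
        if schedule.seedling_cap is not None:
            total = germs.sum(axis=0)
            keep = annual_density_cap(total, schedule.seedling_cap)
            germs = rng.binomial(germs, np.broadcast_to(keep, germs.shape))
        state.counts[0] += germs
    else:
        ca = competitor_load(state.counts, schedule, focal_stage=None)
        rate = realized_rate(schedule.max_germination, eff, schedule.comp_germination, ca)
        germs = rng.binomial(state.seed_pool, np.broadcast_to(rate, state.seed_pool.shape))
        state.counts[0] += germs
    state.seed_pool[:] = 0
    return germs


def survive(
    state: PopulationState,
    eff: np.ndarray,
    schedule: StageSchedule,
    rng: np.random.Generator,
) -> None:
    """Binomial survival per cohort; larger individuals depress the rate.

    Annual adults have maximum survival 0 but die only after reproducing,
    so the engine removes them at year end rather than here.
    """
    if schedule.annual:
        return
    loads = [competitor_load(state.counts, schedule, s) for s in range(schedule.n_stages)]
    for s in range(schedule.n_stages):
        rate = realized_rate(
            schedule.max_survival[s], eff, schedule.comp_survival[s], loads[s][None, :, :]
        )
        state.counts[s] = rng.binomial(state.counts[s], rate)


def transition(
    state: PopulationState,
    eff: np.ndarray,
    schedule: StageSchedule,
    rng: np.random.Generator,
) -> None:
    """Move survivors up one stage with the realized transition rate.

    The largest stage never transitions.  Rates and competitor loads are
    evaluated on the pre-transition counts (simultaneous update).
    """
    if schedule.annual:
        return
    movers = []
    for s in range(schedule.n_stages - 1):
        if schedule.max_transition[s] == 0:
            movers.append(None)
            continue
        ca = competitor_load(state.counts, schedule, s)
        rate = realized_rate(
            schedule.max_transition[s], eff, schedule.comp_survival[s], ca[None, :, :]
        )
        movers.append(rng.binomial(state.counts[s], rate))
    for s, mv in enumerate(movers):
        if mv is None:
            continue
        state.counts[s] -= mv
        state.counts[s + 1] += mv


def pollen_emission(
    state: PopulationState, eff: np.ndarray, schedule: StageSchedule, genetics: GeneticSystem
) -> np.ndarray:
    """Expected pollen output per patch by allele, before dispersal.

    Each reproductive individual emits Poisson pollen with mean
    Max.Pollen x ClimEff; a heterozygote's grains split between its two
    alleles with Mendelian probability 1/2 each.  Returns the
    (n_alleles, R, C) expected-rate field; the engine draws the realized
    post-dispersal pollen pools as Poisson counts.
    """
    maxp = np.asarray(schedule.max_pollen, dtype=float)
    per_genotype = np.tensordot(maxp, state.counts.astype(float), axes=(0, 0)) * eff  # (G,R,C)
    return np.tensordot(genetics.emission.T, per_genotype, axes=(1, 0))  # (A,R,C)


def seed_emission(
    state: PopulationState,
    eff: np.ndarray,
    schedule: StageSchedule,
    genetics: GeneticSystem,
    pollen_pool: np.ndarray,
) -> np.ndarray:
    """Expected seed output per patch by offspring genotype, pre-dispersal.

    Mothers produce Poisson seeds with mean Max.Seed x ClimEff (fecundity
    is climate-only).  Each seed draws its maternal allele uniformly from
    the mother's pair and its paternal allele from the patch pollen pool's
    allele frequencies; a patch with an empty pollen pool sets no seed
    (pollen limitation).  Returns the (G, R, C) expected-rate field.
    """
    maxs = np.asarray(schedule.max_seeds, dtype=float)
    mu = np.tensordot(maxs, state.counts.astype(float), axes=(0, 0)) * eff  # (G,R,C)
    tot = pollen_pool.sum(axis=0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(tot > 0, pollen_pool / np.where(tot > 0, tot, 1.0), 0.0)
    return np.einsum("grc,arc,gah->hrc", mu, freq, genetics.mating)
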