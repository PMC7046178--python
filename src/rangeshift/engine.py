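"""Simulation engine: initialization, the yearly loop and the three phases.

A run has three phases with recorded boundaries:

* **Stable** — equilibration under the initial static climate (roughly 20
  generations: 20 years for annuals, 100 for perennials, 200 for trees);
* **Shift** — the climate bands move toward the cold end for 20 years;
* **Restab** — restabilization under the final static climate, as long as
  the equilibration (10x for the "Restab+" variant).

Each year applies, in order: germination, survival, pollen production and
dispersal, seed production (with Mendelian genotype assignment from the
patch pollen pool) and dispersal, and stage transition.  Individuals
reproduce at their pre-transition stage; annual adults are removed at
year end after reproducing.

Produced seed and pollen counts are Poisson per individual and every
propagule disperses independently, so the post-dispersal counts are drawn
directly as Poisson fields whose means are the expected emission fields
convolved with the discretized 2Dt kernel (zero padding makes the
boundary absorbing).  This is distributionally identical to producing
integer counts per patch and allocating them multinomially, and keeps
full-scale runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    GeneticSystem,
    PopulationState,
    StageSchedule,
    germinate,
    pollen_emission,
    seed_emission,
    survive,
    transition,
)
from .dispersal import Kernel2Dt, convolve_expected, grid_kernel, kernel_from_mean
from .landscape import ClimateSchedule, LandscapeSpec, climate_columns, zones_at_offset

__all__ = ["ScenarioConfig", "RunResult", "initialize", "step_year", "run_scenario"]

PHASES = ("stable", "shift", "restab")


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved experiment: species, genetics, dispersal, landscape
    and phase durations."""

    code: str
    species: StageSchedule
    genetics: GeneticSystem
    seed_mean: float
    pollen_mean: float
    landscape: LandscapeSpec
    climate: ClimateSchedule  # shift_start_year is set to equilibration_years
    equilibration_years: int
    shift_years: int
    restab_years: int
    replicates: int = 4
    kernel_p: float = 1.0
    init_density: int | None = None  # None -> species default

    @property
    def total_years(self) -> int:
        return self.equilibration_years + self.shift_years + self.restab_years

    def phase_end_year(self, phase: str) -> int:
        """Index of the last year of a phase."""
        ends = {
            "stable": self.equilibration_years - 1,
            "shift": self.equilibration_years + self.shift_years - 1,
            "restab": self.total_years - 1,
        }
        return ends[phase]

    @property
    def seed_kernel(self) -> Kernel2Dt:
        return kernel_from_mean(self.seed_mean, self.kernel_p)

    @property
    def pollen_kernel(self) -> Kernel2Dt:
        return kernel_from_mean(self.pollen_mean, self.kernel_p)


@dataclass
class RunResult:
    """Per-replicate occupancy time series and phase-boundary snapshots.

    ``occupancy[rep, year, 0]`` is the number of patches occupied by at
    least one reproductive adult of any genotype; ``occupancy[rep, year,
    1 + g]`` the per-genotype counts.  ``snapshots[rep, phase]`` holds the
    end-of-year established counts (annual adults included, pre-removal)
    and the seed pools at each recorded phase boundary.
    """

    config: ScenarioConfig
    seed: int
    occupancy: np.ndarray  # (replicates, years, 1 + G) int64
    snapshots: dict = field(default_factory=dict)

    def occupancy_at(self, phase: str) -> np.ndarray:
        """Species occupancy per replicate at a phase boundary."""
        return self.occupancy[:, self.config.phase_end_year(phase), 0]

    def genotype_occupancy_at(self, phase: str) -> np.ndarray:
        return self.occupancy[:, self.config.phase_end_year(phase), 1:]


def initialize(config: ScenarioConfig, rng: np.random.Generator | None = None) -> PopulationState:
    """Seed each genotype across every patch where its year-0 ClimEff > 0.

    Annuals start as seeds, perennials as small adults, trees as saplings,
    at a fixed per-patch density per genotype — deliberately broader than
    the expected equilibrium so equilibration trims ranges inward rather
    than waiting on colonization.  Deterministic (rng accepted for
    interface symmetry).
    """
    spec, sched = config.landscape, config.climate
    genetics, species = config.genetics, config.species
    zones = climate_columns(spec, sched, year=0)
    eff0 = genetics.clim_eff_columns(zones)  # (G, C)
    eligible = eff0 > 0.0
    density = config.init_density if config.init_density is not None else species.init_density
    state = PopulationState.empty(species, genetics, (spec.n_rows, spec.n_cols))
    per_patch = (eligible[:, None, :] * density).astype(np.int64)
    fill = np.broadcast_to(per_patch, state.seed_pool.shape).copy()
    if species.init_stage < 0:
        state.seed_pool[:] = fill
    else:
        state.counts[species.init_stage] = fill
    return state


class _YearContext:
    """Precomputed per-run machinery: grid kernels and ClimEff tables."""

    def __init__(self, config: ScenarioConfig):
        spec = config.landscape
        self.config = config
        self.seed_k = grid_kernel(config.seed_kernel, spec.patch_size, spec.n_rows, spec.n_cols)
        self.pollen_k = grid_kernel(config.pollen_kernel, spec.patch_size, spec.n_rows, spec.n_cols)
        self._eff_cache: dict[int, np.ndarray] = {}

    def eff(self, year: int) -> np.ndarray:
        """(G, R, C) ClimEff field experienced during ``year``.

        Each shift year's band movement is applied at the start of that
        year, so the last shift year already sees the completed shift and
        the recorded end-of-shift occupancy reflects the full displacement.
        """
        s = self.config.climate.shift_offset(year + 1)
        if s not in self._eff_cache:
            zones = zones_at_offset(self.config.landscape, s)
            cols = self.config.genetics.clim_eff_columns(zones)
            self._eff_cache[s] = np.ascontiguousarray(
                np.broadcast_to(
                    cols[:, None, :],
                    (cols.shape[0], self.config.landscape.n_rows, cols.shape[1]),
                )
            )
        return self._eff_cache[s]


def step_year(
    state: PopulationState, year: int, ctx: _YearContext, rng: np.random.Generator
) -> np.ndarray:
    """Advance one year in place; return the end-of-year established counts.

    The returned array includes annual adults before their year-end
    removal, so occupancy reflects the plants that reproduced that year.
    """
    config = ctx.config
    species, genetics = config.species, config.genetics
    eff = ctx.eff(year)

    germinate(state, eff, species, rng)
    survive(state, eff, species, rng)

    pollen_rate = pollen_emission(state, eff, species, genetics)
    state.pollen_pool = rng.poisson(convolve_expected(pollen_rate, ctx.pollen_k))

    seed_rate = seed_emission(state, eff, species, genetics, state.pollen_pool)
    state.seed_pool = rng.poisson(convolve_expected(seed_rate, ctx.seed_k))

    transition(state, eff, species, rng)

    end_counts = state.counts.copy()
    if species.annual:
        state.counts[:] = 0
    return end_counts


def _occupancy_row(counts: np.ndarray, species: StageSchedule) -> np.ndarray:
    """[species occupancy, per-genotype occupancy] from an end-of-year
    established-count array (patch occupied = >= 1 reproductive adult)."""
    adults = counts[species.reproductive].sum(axis=0)  # (G, R, C)
    per_g = (adults > 0).sum(axis=(1, 2))
    total = (adults.sum(axis=0) > 0).sum()
    return np.concatenate([[total], per_g]).astype(np.int64)


def run_scenario(
    config: ScenarioConfig,
    seed: int = 0,
    through_phase: str = "restab",
    record_snapshots: bool = True,
) -> RunResult:
    """Run all replicates of a scenario with independent RNG streams.

    ``through_phase`` may stop the run at "stable" or "shift" when the
    later phases are not needed.  Identical (config, seed) pairs yield
    identical results.
    """
    if through_phase not in PHASES:
        raise ValueError(f"through_phase must be one of {PHASES}")
    n_years = config.phase_end_year(through_phase) + 1
    G = config.genetics.n_genotypes
    occupancy = np.zeros((config.replicates, n_years, 1 + G), dtype=np.int64)
    result = RunResult(config=config, seed=seed, occupancy=occupancy)

    ctx = _YearContext(config)
    boundary_years = {
        config.phase_end_year(ph): ph
        for ph in PHASES
        if config.phase_end_year(ph) < n_years
    }
    streams = np.random.SeedSequence(seed).spawn(config.replicates)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        state = initialize(config, rng)
        for year in range(n_years):
            end_counts = step_year(state, year, ctx, rng)
            occupancy[rep, year] = _occupancy_row(end_counts, config.species)
            if record_snapshots and year in boundary_years:
                result.snapshots[(rep, boundary_years[year])] = {
                    "counts": end_counts,
                    "seed_pool": state.seed_pool.copy(),
                    "year": year,
                }
    return result
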