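"""Initialization, the yearly loop, phases and the scenario catalog."""

import dataclasses

import numpy as np
import pytest

from rangeshift.demography import ANNUAL, TREE, locally_adapted_system
from rangeshift.engine import ScenarioConfig, _YearContext, initialize, run_scenario, step_year
from rangeshift.landscape import ClimateSchedule, LandscapeSpec, climate_columns
from rangeshift.scenarios import CATALOG_CODES, parse_code, scenario_catalog


def tiny_config(code="AL.20", **overrides):
    cfg = parse_code(code, replicates=1)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


# --- initialization -------------------------------------------------------


def test_plastic_tree_initialized_as_saplings_only():
    cfg = parse_code("TP.40")
    state = initialize(cfg)
    occupied_stages = {s for s in range(TREE.n_stages) if state.counts[s].any()}
    assert occupied_stages == {1}  # saplings
    assert state.seed_pool.sum() == 0


def test_annual_initialized_as_seeds():
    cfg = parse_code("AL.20")
    state = initialize(cfg)
    assert state.counts.sum() == 0
    assert state.seed_pool.sum() > 0


def test_cold_adapted_genotype_absent_from_warmest_band():
    cfg = parse_code("AL.20")
    state = initialize(cfg)
    g = cfg.genetics.genotype_names.index("A1A1")  # optimum 4
    warm_cols = slice(0, cfg.landscape.band_width)  # zone 10
    assert state.seed_pool[g, :, warm_cols].sum() == 0
    assert state.seed_pool[g].sum() > 0


def test_initial_total_matches_density_times_eligible_patches():
    cfg = parse_code("PL.20")
    state = initialize(cfg)
    zones = climate_columns(cfg.landscape, cfg.climate, 0)
    eligible_cols = (cfg.genetics.clim_eff_columns(zones) > 0).sum()
    expected = eligible_cols * cfg.landscape.n_rows * cfg.species.init_density
    assert state.counts.sum() == expected


# --- yearly loop ----------------------------------------------------------


def test_empty_state_stays_empty(rng):
    cfg = tiny_config("TL.40")
    ctx = _YearContext(cfg)
    state = initialize(cfg)
    state.counts[:] = 0
    state.seed_pool[:] = 0
    for year in range(3):
        step_year(state, year, ctx, rng)
    assert state.counts.sum() == 0 and state.seed_pool.sum() == 0


def test_no_seed_bank_after_failed_germination(rng):
    """Seeds in a climate where no genotype can germinate vanish within a
    year: non-germinating seeds are removed."""
    spec = LandscapeSpec(n_rows=2, n_cols=10, band_width=10, warmest_zone_initial=10,
                         coldest_zone_initial=10)
    cfg = tiny_config("AL.20", landscape=spec,
                      climate=ClimateSchedule(shift_start_year=100, shift_duration=0))
    ctx = _YearContext(cfg)
    state = initialize(cfg)
    g = cfg.genetics.genotype_names.index("A1A1")  # optimum 4, zone 10: eff 0
    state.seed_pool[:] = 0
    state.seed_pool[g] = 500
    step_year(state, 0, ctx, rng)
    assert state.counts.sum() == 0
    assert state.seed_pool.sum() == 0


def test_optimal_tree_patch_persists_and_recruits(rng):
    """Large trees at their optimum keep producing seedlings for a decade
    (survival 0.99 with fecundity 5000 and germination 0.6)."""
    cfg = tiny_config("TL.40")
    ctx = _YearContext(cfg)
    state = initialize(cfg)
    state.counts[:] = 0
    state.seed_pool[:] = 0
    g = cfg.genetics.genotype_names.index("A2A2")  # optimum 6, home zone 6
    home_col = int(np.argmax(climate_columns(cfg.landscape, cfg.climate, 0) == 6))
    state.counts[4, g, 25, home_col + 5] = 20
    for year in range(10):
        step_year(state, year, ctx, rng)
    assert state.counts[4].sum() > 0  # adults persist
    assert state.counts[0].sum() > 0  # seedlings recruited


def test_annual_adults_removed_at_year_end(rng):
    cfg = tiny_config("AL.20")
    ctx = _YearContext(cfg)
    state = initialize(cfg)
    end_counts = step_year(state, 0, ctx, rng)
    assert end_counts.sum() > 0  # adults reproduced this year
    assert state.counts.sum() == 0  # and died at year end
    assert state.seed_pool.sum() > 0  # leaving seeds for next year


# --- phases, determinism, catalog ----------------------------------------


@pytest.mark.parametrize(
    "code, years",
    [("AL.20", 60), ("TP.40", 420), ("AP.1.R+", 240), ("PL.20", 220)],
)
def test_phase_timelines(code, years):
    assert parse_code(code).total_years == years


def test_identical_seed_reproduces_run_exactly():
    cfg = parse_code("AL.20", replicates=2)
    r1 = run_scenario(cfg, seed=11, through_phase="stable")
    r2 = run_scenario(cfg, seed=11, through_phase="stable")
    assert (r1.occupancy == r2.occupancy).all()
    k = (0, "stable")
    assert (r1.snapshots[k]["counts"] == r2.snapshots[k]["counts"]).all()
    r3 = run_scenario(cfg, seed=12, through_phase="stable")
    assert (r1.occupancy != r3.occupancy).any()


def test_replicates_are_independent_streams():
    cfg = parse_code("AL.20", replicates=3)
    res = run_scenario(cfg, seed=5, through_phase="stable", record_snapshots=False)
    assert not (res.occupancy[0] == res.occupancy[1]).all()


def test_catalog_codes_all_parse():
    cat = scenario_catalog()
    assert set(cat) == set(CATALOG_CODES)
    ppw = cat["PPW.20"]
    assert ppw.species.name == "perennial" and ppw.genetics.n_genotypes == 1
    assert ppw.genetics.curves[0].zone_indexed
    plf = cat["PLF.20"]
    assert plf.genetics.n_genotypes == 6
    assert plf.genetics.curves[0].table[1] == pytest.approx(1 - (1 - 0.75) / 2)
    fast = cat["TL.40.F"]
    assert fast.climate.patches_per_year == 2
    shallow = cat["TL.40.L"]
    assert shallow.landscape.n_cols == 400 and shallow.climate.patches_per_year == 4
    extended = cat["TP.80.FE"]
    assert extended.landscape.cold_band_multiplier == 3


@pytest.mark.parametrize("bad", ["XL.20", "A.20", "AL", "AL.x", "AL.20.Q"])
def test_malformed_codes_rejected(bad):
    with pytest.raises(ValueError):
        parse_code(bad)
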