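"""Within-year demographic events against independent binomial/Mendelian
oracles, and the competition/rate arithmetic."""

import numpy as np
import pytest
from scipy import stats

from rangeshift.demography import (
    ANNUAL,
    PERENNIAL,
    TREE,
    PopulationState,
    annual_density_cap,
    competitor_load,
    germinate,
    locally_adapted_system,
    plastic_system,
    realized_rate,
    seed_emission,
    survive,
    transition,
    pollen_emission,
)

LA = locally_adapted_system()


def tree_state(shape=(1, 1)):
    return PopulationState.empty(TREE, LA, shape)


def uniform_eff(value, genetics, shape):
    return np.full((genetics.n_genotypes, *shape), float(value))


# --- competition and rates ------------------------------------------------


def test_competitor_load_empty_patch_is_zero():
    st = tree_state()
    assert competitor_load(st.counts, TREE, focal_stage=0)[0, 0] == 0.0


def test_competitor_load_counts_only_larger_stages():
    st = tree_state()
    st.counts[4, 0, 0, 0] = 10  # ten large trees, 0.5 m^2 BA each
    assert competitor_load(st.counts, TREE, focal_stage=0)[0, 0] == pytest.approx(5.0)
    # the largest stage has no larger competitors
    assert competitor_load(st.counts, TREE, focal_stage=4)[0, 0] == 0.0
    # germination load counts everything established
    st.counts[0, 0, 0, 0] = 100  # seedlings, 0.0001 m^2 each
    assert competitor_load(st.counts, TREE, None)[0, 0] == pytest.approx(5.0 + 0.01)


def test_realized_rate_formula_and_clamping():
    # tree small-adult survival with modest crowding
    assert realized_rate(0.96, 1.0, 0.02, 2.0) == pytest.approx(0.9216)
    assert realized_rate(0.7, 0.1, 0.0005, 400.0) == 0.0  # clamped at zero
    assert realized_rate(0.85, 1.0, 0.07, 0.0) == pytest.approx(0.85)


@pytest.mark.parametrize("n, prob", [(9000, 7000 / 9000), (7000, 1.0), (100, 1.0), (0, 1.0)])
def test_annual_density_cap(n, prob):
    assert annual_density_cap(n) == pytest.approx(prob)


# --- stochastic events against binomial oracles ---------------------------


def test_germination_binomial_oracle(rng):
    """Annual germination at the optimum is Binomial(seeds, 0.3): the mean
    over 2000 replicate patches must fall within 3 SE of 300/1000 seeds."""
    n_reps, seeds, p = 2000, 1000, ANNUAL.max_germination
    st = PopulationState.empty(ANNUAL, LA, (1, n_reps))
    st.seed_pool[0, 0, :] = seeds
    germinate(st, uniform_eff(1.0, LA, (1, n_reps)), ANNUAL, rng)
    mean = st.counts[0, 0, 0, :].mean()
    se = np.sqrt(seeds * p * (1 - p) / n_reps)
    assert abs(mean - seeds * p) < 3 * se
    assert (st.seed_pool == 0).all()  # no persistent seed bank


def test_zero_seeds_give_zero_germinants(rng):
    st = PopulationState.empty(ANNUAL, LA, (2, 2))
    germinate(st, uniform_eff(1.0, LA, (2, 2)), ANNUAL, rng)
    assert st.counts.sum() == 0


def test_annual_cap_limits_crowded_patches(rng):
    st = PopulationState.empty(ANNUAL, LA, (1, 400))
    st.seed_pool[:, 0, :] = 10_000  # 60K seeds per patch over six genotypes
    germinate(st, uniform_eff(1.0, LA, (1, 400)), ANNUAL, rng)
    per_patch = st.counts[0].sum(axis=0)[0]
    # expected survivors-to-reproduction exactly at the cap
    assert per_patch.mean() == pytest.approx(7000, rel=0.02)


def test_survival_binomial_oracle(rng):
    """Perennial large-adult survival 0.7: mean of Binomial(500, 0.7) over
    2000 replicate patches within 3 SE of 350."""
    n_reps, n0, p = 2000, 500, PERENNIAL.max_survival[3]
    st = PopulationState.empty(PERENNIAL, LA, (1, n_reps))
    st.counts[3, 0, 0, :] = n0
    survive(st, uniform_eff(1.0, LA, (1, n_reps)), PERENNIAL, rng)
    se = np.sqrt(n0 * p * (1 - p) / n_reps)
    assert abs(st.counts[3, 0, 0, :].mean() - n0 * p) < 3 * se


def test_survival_rate_extremes(rng):
    st = tree_state((1, 2))
    st.counts[0, :, 0, :] = 50
    survive(st, uniform_eff(0.0, LA, (1, 2)), TREE, rng)
    assert st.counts.sum() == 0  # ClimEff 0 kills everything
    st.counts[4, :, 0, :] = 50
    before = st.counts.sum()
    survive(st, uniform_eff(1.0, LA, (1, 2)), TREE, rng)
    # survival never increases the population
    assert st.counts.sum() <= before


def test_transition_binomial_oracle_and_top_stage(rng):
    n_reps, n0 = 2000, 200
    st = PopulationState.empty(TREE, LA, (1, n_reps))
    st.counts[0, 0, 0, :] = n0  # seedlings, transition 0.15
    st.counts[4, 0, 0, :] = 7  # large adults never transition
    transition(st, uniform_eff(1.0, LA, (1, n_reps)), TREE, rng)
    assert (st.counts[4, 0, 0, :] == 7).all()
    p = TREE.max_transition[0] * (1.0 - TREE.comp_survival[0] * 7 * TREE.sizes[4])
    moved = st.counts[1, 0, 0, :]
    se = np.sqrt(n0 * p * (1 - p) / n_reps)
    assert abs(moved.mean() - n0 * p) < 3 * se
    assert (st.counts >= 0).all()


def test_transition_without_survivors_moves_nobody(rng):
    st = tree_state((2, 2))
    transition(st, uniform_eff(1.0, LA, (2, 2)), TREE, rng)
    assert st.counts.sum() == 0


# --- reproduction and Mendelian genetics ----------------------------------


def test_pollen_emission_heterozygote_splits_alleles():
    st = PopulationState.empty(ANNUAL, LA, (1, 1))
    g = LA.genotype_names.index("A1A2")
    st.counts[0, g, 0, 0] = 10
    lam = pollen_emission(st, uniform_eff(1.0, LA, (1, 1)), ANNUAL, LA)
    a1, a2, a3 = (lam[LA.allele_labels.index(a), 0, 0] for a in ("A1", "A2", "A3"))
    assert a1 == a2 == pytest.approx(10 * ANNUAL.max_pollen[0] / 2)
    assert a3 == 0.0


def test_pollen_zero_when_climate_unsuitable():
    st = PopulationState.empty(TREE, LA, (1, 1))
    st.counts[4, :, 0, 0] = 5
    lam = pollen_emission(st, uniform_eff(0.0, LA, (1, 1)), TREE, LA)
    assert lam.sum() == 0.0


def test_seed_emission_mendelian_cross():
    """Mother A1A3 fertilized by pure-A2 pollen sets half A1A2, half A2A3."""
    st = PopulationState.empty(ANNUAL, LA, (1, 1))
    mom = LA.genotype_names.index("A1A3")
    st.counts[0, mom, 0, 0] = 1
    pool = np.zeros((3, 1, 1), dtype=np.int64)
    pool[LA.allele_labels.index("A2")] = 100
    lam = seed_emission(st, uniform_eff(1.0, LA, (1, 1)), ANNUAL, LA, pool)
    total = lam.sum()
    assert total == pytest.approx(ANNUAL.max_seeds[0])
    assert lam[LA.genotype_names.index("A1A2"), 0, 0] == pytest.approx(total / 2)
    assert lam[LA.genotype_names.index("A2A3"), 0, 0] == pytest.approx(total / 2)


def test_empty_pollen_pool_sets_no_seed():
    st = PopulationState.empty(ANNUAL, LA, (1, 1))
    st.counts[0, :, 0, 0] = 100
    pool = np.zeros((3, 1, 1), dtype=np.int64)
    lam = seed_emission(st, uniform_eff(1.0, LA, (1, 1)), ANNUAL, LA, pool)
    assert lam.sum() == 0.0


def test_mendelian_allele_conservation_chi_square(rng):
    """Offspring allele frequency equals (maternal + pollen pool)/2; a
    chi-square test on ~1e5 Poisson-sampled seeds must not reject."""
    st = PopulationState.empty(ANNUAL, LA, (1, 1))
    mom = LA.genotype_names.index("A1A2")
    st.counts[0, mom, 0, 0] = 400  # ~1.2e5 expected seeds
    pool = np.zeros((3, 1, 1), dtype=np.int64)
    pool[0, 0, 0] = 300  # A1
    pool[2, 0, 0] = 100  # A3
    lam = seed_emission(st, uniform_eff(1.0, LA, (1, 1)), ANNUAL, LA, pool)
    seeds = rng.poisson(lam[:, 0, 0])
    assert seeds.sum() > 1e5
    copies = LA.dosage.T @ seeds  # allele copies among offspring
    maternal = np.array([0.5, 0.5, 0.0])
    paternal = np.array([0.75, 0.0, 0.25])
    expected = 0.5 * (maternal + paternal) * copies.sum()
    mask = expected > 0
    chi2 = ((copies[mask] - expected[mask]) ** 2 / expected[mask]).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=2)


def test_plastic_species_breeds_true(rng):
    P = plastic_system()
    st = PopulationState.empty(ANNUAL, P, (1, 1))
    st.counts[0, 0, 0, 0] = 10
    pool = np.ones((1, 1, 1), dtype=np.int64)
    lam = seed_emission(st, uniform_eff(1.0, P, (1, 1)), ANNUAL, P, pool)
    assert lam.shape[0] == 1 and lam.sum() > 0
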