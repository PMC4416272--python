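"""Breeding-scheme simulator: distributional checks and scheme invariants."""

import numpy as np
import pytest

from meritsim.params import GeneticParams, SchemeConfig
from meritsim.pedigree import FEMALE, MALE
from meritsim.simulate import (
    simulate_base_population,
    simulate_breeding_scheme,
    transmit_tbv,
)


class TestBasePopulation:
    def test_founder_tbv_covariance(self, rng, params):
        """Sample covariance of many founders reproduces G0 within 3 SE."""
        n = 100_000
        tbv = simulate_base_population(params, n, rng)
        s = np.cov(tbv.T)
        g0 = params.g0
        # SE of a covariance entry of a MVN sample is ~ sqrt((g_ii g_jj + g_ij^2)/n)
        se = np.sqrt((np.outer(np.diag(g0), np.diag(g0)) + g0**2) / n)
        assert np.all(np.abs(s - g0) < 3.5 * se)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GeneticParams(genetic_sd=np.array([1, 1, 0, 1, 1.0]))

    def test_fixed_seed_reproducible(self, params):
        a = simulate_base_population(params, 100, np.random.default_rng(5))
        b = simulate_base_population(params, 100, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestTransmission:
    def test_mendelian_sampling_covariance(self, rng, params):
        g0 = params.g0
        n = 100_000
        zero = np.zeros((n, 5))
        off = transmit_tbv(zero, zero, np.zeros(n), np.zeros(n), g0, rng)
        s = np.cov(off.T)
        se = np.sqrt((np.outer(np.diag(g0), np.diag(g0)) + g0**2) / n) * 0.5
        assert np.all(np.abs(s - 0.5 * g0) < 3.5 * se)

    def test_offspring_mean_is_parent_average(self, rng, params):
        sire = np.tile([1.0, 2, 3, 4, 5], (50_000, 1))
        dam = np.tile([-1.0, 0, 1, 2, 3], (50_000, 1))
        off = transmit_tbv(sire, dam, np.zeros(50_000), np.zeros(50_000),
                           params.g0, rng)
        pa = 0.5 * (sire[0] + dam[0])
        se = np.sqrt(0.5 * np.diag(params.g0) / 50_000)
        assert np.all(np.abs(off.mean(axis=0) - pa) < 3.5 * se)

    def test_fully_inbred_parents_no_sampling_variance(self, rng, params):
        off = transmit_tbv(np.ones((10, 5)), np.ones((10, 5)),
                           np.ones(10), np.ones(10), params.g0, rng)
        assert np.allclose(off, 1.0)


class TestScheme:
    def test_determinism(self, smoke_sim):
        from meritsim.params import SchemeConfig

        again = simulate_breeding_scheme(smoke_sim.params, SchemeConfig.smoke(), seed=11)
        assert np.array_equal(again.tbv, smoke_sim.tbv)
        assert np.array_equal(again.rec_animal, smoke_sim.rec_animal)
        assert np.array_equal(again.pedigree.sire, smoke_sim.pedigree.sire)

    def test_positive_genetic_trend(self, smoke_sim):
        """Directional selection: late cohorts exceed the base by > 1 genetic SD."""
        tt = smoke_sim.true_tmi / smoke_sim.params.true_index_sd
        by = smoke_sim.pedigree.birth_year
        base = tt[by <= 0].mean()
        late = tt[by >= 28].mean()
        assert late - base > 1.0

    def test_random_mating_no_trend(self, params):
        cfg = SchemeConfig(n_herds=6, cows_per_herd=20, n_years=12,
                           n_proven_sires=5, n_young_sires=5,
                           min_proven_daughters=2, base_years=(5, 7),
                           analysis_years=(3, 12), selection_criterion="random")
        slopes = []
        for rep in range(3):
            sim = simulate_breeding_scheme(params, cfg, seed=31, replicate=rep)
            tt = sim.true_tmi / params.true_index_sd
            by = sim.pedigree.birth_year
            years = np.arange(2, 13)
            means = np.array([tt[by == y].mean() for y in years])
            slopes.append(np.polyfit(years, means, 1)[0])
        assert abs(np.mean(slopes)) < 0.05

    def test_sex_limited_recording(self, smoke_sim):
        sex = smoke_sim.pedigree.sex[smoke_sim.rec_animal]
        male_traits = smoke_sim.rec_trait[sex == MALE]
        female_traits = smoke_sim.rec_trait[sex == FEMALE]
        assert set(male_traits) == {2}
        assert set(female_traits) == {0, 1, 3, 4}
        # roughly 60% of males NDG-recorded
        males = smoke_sim.pedigree.sex == MALE
        recorded_males = np.isin(np.arange(smoke_sim.n_animals),
                                 smoke_sim.rec_animal[sex == MALE])
        rate = recorded_males[males].mean()
        assert 0.5 < rate < 0.7

    def test_record_phenotypes_rule(self, rng, params):
        from meritsim.simulate import record_phenotypes
        from meritsim.params import SchemeConfig

        sex = np.array([FEMALE, MALE] * 200, dtype=np.int8)
        out = record_phenotypes(sex, SchemeConfig.smoke(), rng)
        assert all(list(t) == [0, 1, 3, 4] for t, s in zip(out, sex) if s == FEMALE)
        male_sets = [list(t) for t, s in zip(out, sex) if s == MALE]
        assert all(t in ([2], []) for t in male_sets)
        rate = np.mean([t == [2] for t in male_sets])
        assert 0.45 < rate < 0.75

    def test_no_repeated_records(self, smoke_sim):
        pairs = smoke_sim.rec_animal * 10 + smoke_sim.rec_trait
        assert len(np.unique(pairs)) == len(pairs)

    def test_infeasible_config_rejected(self, params):
        cfg = SchemeConfig(n_herds=2, cows_per_herd=5, n_years=8,
                           n_proven_sires=0, n_young_sires=2,
                           base_years=(3, 5), analysis_years=(2, 8),
                           selection_criterion="pedigree_index")
        with pytest.raises(RuntimeError, match="sires"):
            simulate_breeding_scheme(params, cfg, seed=3)


class TestScenarios:
    def test_scenarios_share_pedigree_and_tbv(self, smoke_sim):
        """Same draw serves every residual scenario (common random numbers)."""
        r0 = smoke_sim.records_for(smoke_sim.params.with_scenario(0.0))
        r2 = smoke_sim.records_for(smoke_sim.params.with_scenario(1.0))
        assert np.array_equal(r0.animal, r2.animal)
        assert np.array_equal(r0.trait, r2.trait)
        assert not np.allclose(r0.value, r2.value)

    @pytest.mark.parametrize("frac,expected", [(0.0, 0.0), (1.0, 0.85)])
    def test_realized_residual_correlation(self, smoke_sim, frac, expected):
        p = smoke_sim.params.with_scenario(frac)
        rs = smoke_sim.records_for(p)
        hy = np.array([smoke_sim.herd_year_effects[(h, y)][t]
                       for h, y, t in zip(rs.herd, rs.year, rs.trait)])
        e = rs.value - hy - smoke_sim.tbv[rs.animal, rs.trait]
        fy = {a: v for a, v, t in zip(rs.animal, e, rs.trait) if t == 0}
        py = {a: v for a, v, t in zip(rs.animal, e, rs.trait) if t == 1}
        common = sorted(set(fy) & set(py))
        r = np.corrcoef([fy[a] for a in common], [py[a] for a in common])[0, 1]
        assert r == pytest.approx(expected, abs=0.03)

    def test_phenotypic_variance_matches_h2(self, smoke_sim):
        """var(phenotype - herd-year effect) ~= sigma_a²/h² in the base cohort."""
        p = smoke_sim.params
        rs = smoke_sim.records_for(p)
        hy = np.array([smoke_sim.herd_year_effects[(h, y)][t]
                       for h, y, t in zip(rs.herd, rs.year, rs.trait)])
        founder_cows = (smoke_sim.pedigree.sire[rs.animal] == -1) & (rs.trait == 0)
        var = np.var(rs.value[founder_cows] - hy[founder_cows])
        assert var == pytest.approx(p.sigma_p2[0], rel=0.12)
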