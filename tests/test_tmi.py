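"""TMI construction: aggregation, selection index, reliabilities, standardization."""

import numpy as np
import pytest

from meritsim.params import GeneticParams
from meritsim.tmi import (
    multitrait_tmi_reliability,
    si_covariance,
    si_index,
    standardize,
    tmi_from_ebv,
)


class TestAggregation:
    def test_zero_ebv_zero_index(self, params):
        assert tmi_from_ebv(np.zeros((3, 5)), params) == pytest.approx([0, 0, 0])

    def test_single_trait_unit(self, params):
        assert tmi_from_ebv(np.array([[1.0, 0, 0, 0, 0]]), params)[0] == pytest.approx(5.4)

    def test_unit_on_every_trait_gives_100(self, params):
        assert tmi_from_ebv(np.ones((1, 5)), params)[0] == pytest.approx(100.0)

    def test_missing_trait_rejected(self, params):
        with pytest.raises(ValueError, match="traits"):
            tmi_from_ebv(np.ones((1, 4)), params)


class TestSICovariance:
    def test_perfect_reliability_recovers_genetic_covariance(self):
        assert si_covariance(0.85, 1.0, 1.0) == pytest.approx(0.85)

    @pytest.mark.parametrize("r2i,r2j,rg", [(0.0, 0.9, 0.5), (0.9, 0.0, 0.5),
                                            (0.7, 0.9, 0.0)])
    def test_vanishing_cases(self, r2i, r2j, rg):
        assert si_covariance(rg, r2i, r2j) == 0.0


class TestSIIndex:
    def test_perfect_information_limit(self, params):
        """All r² = 1: b = v, TMI = v'u, reliability 1."""
        rng = np.random.default_rng(0)
        ebv = rng.standard_normal((20, 5))
        tmi, rel, b = si_index(ebv, np.ones((20, 5)), params)
        v = params.index_weights
        assert np.abs(b - v[None, :]).max() < 1e-8
        assert tmi == pytest.approx(ebv @ v)
        assert rel == pytest.approx(np.ones(20))

    def test_uncorrelated_traits_closed_form(self):
        """Diagonal genetics: b = v per trait and the reliability collapses
        to sum v² r² sigma² / v'G0v (verified by hand for two traits)."""
        params = GeneticParams(
            trait_names=("A", "B"), h2=np.array([0.3, 0.2]),
            genetic_corr=np.eye(2), genetic_sd=np.array([1.0, 2.0]),
            econ_weights=np.array([60.0, 40.0]))
        rng = np.random.default_rng(1)
        ebv = rng.standard_normal((10, 2))
        rel = np.tile([0.5, 0.8], (10, 1))
        tmi, r_tmi, b = si_index(ebv, rel, params)
        v = params.econ_weights / params.genetic_sd
        assert np.abs(b - v[None, :]).max() < 1e-8
        assert tmi == pytest.approx(ebv @ v)
        by_hand = (v[0]**2 * 0.5 * 1.0 + v[1]**2 * 0.8 * 4.0) / (
            v[0]**2 * 1.0 + v[1]**2 * 4.0)
        assert r_tmi == pytest.approx(np.full(10, by_hand))

    def test_zero_reliability_animal_regularized(self, params):
        tmi, rel, b = si_index(np.zeros((1, 5)), np.zeros((1, 5)), params)
        assert tmi[0] == 0.0
        assert rel[0] == pytest.approx(0.0, abs=1e-6)

    def test_invalid_reliability_rejected(self, params):
        with pytest.raises(ValueError):
            si_index(np.zeros((1, 5)), np.full((1, 5), 1.2), params)


class TestTMIReliability:
    def test_zero_pev_full_reliability(self, params):
        assert multitrait_tmi_reliability(np.zeros((5, 5)), params) == pytest.approx(1.0)

    def test_pev_equal_g0_no_information(self, params):
        assert multitrait_tmi_reliability(params.g0, params) == pytest.approx(0.0)

    def test_single_trait_index_reduces_to_trait_reliability(self):
        params = GeneticParams(econ_weights=np.array([100.0, 0, 0, 0, 0]))
        pev = np.diag([0.3, 0.9, 0.9, 0.9, 0.9])
        # r²_TMI = 1 - PEV_11/sigma²_a1 = 0.7
        assert multitrait_tmi_reliability(pev, params) == pytest.approx(0.7)

    def test_negative_pev_rejected(self, params):
        with pytest.raises(ValueError, match="semidefinite"):
            multitrait_tmi_reliability(-params.g0, params)


class TestStandardization:
    def test_base_mean_maps_to_100(self):
        rng = np.random.default_rng(2)
        tmi = rng.standard_normal(200) * 30
        by = np.repeat(np.arange(10, 30), 10)
        std = standardize(tmi, by, base_years=(18, 22), sd_genetic=5.0)
        base = (by >= 18) & (by <= 22)
        assert std[base].mean() == pytest.approx(100.0)

    def test_one_genetic_sd_is_12_points(self):
        tmi = np.array([0.0, 5.0])
        by = np.array([18, 20])
        std = standardize(tmi, by, base_years=(18, 22), sd_genetic=5.0)
        assert std[1] - std[0] == pytest.approx(12.0)

    def test_rank_preserving(self):
        rng = np.random.default_rng(3)
        tmi = rng.standard_normal(100)
        by = np.full(100, 20)
        std = standardize(tmi, by, sd_genetic=2.0)
        assert np.array_equal(np.argsort(std), np.argsort(tmi))

    def test_empty_base_cohort_rejected(self):
        with pytest.raises(ValueError, match="base years"):
            standardize(np.ones(5), np.zeros(5), base_years=(18, 22), sd_genetic=1.0)

    def test_reliability_deflated_fallback(self):
        """Without truth, the raw SD is deflated by the mean reliability."""
        rng = np.random.default_rng(4)
        r2 = 0.49
        est = rng.standard_normal(4000) * 3.0  # any estimated index spread
        by = np.full(4000, 20)
        std = standardize(est, by, mean_rel=r2)
        # scale = 12 / (sd(est)/sqrt(r2)), so the standardized SD is 12 sqrt(r2)
        assert np.std(std) == pytest.approx(12 * np.sqrt(r2), rel=1e-6)
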