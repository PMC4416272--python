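"""Yield deviations, EOP/EDC weights, and the de-regression round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meritsim.mme import ModelSpec, RecordSet, build_mme, solve_mme, univariate_evaluation
from meritsim.params import GeneticParams
from meritsim.pedigree import FEMALE, MALE, Pedigree, build_a_inverse
from meritsim.two_step import (
    _roundtrip_residual,
    deregress,
    edc,
    eop,
    fixed_solution_levels,
    own_information_reliability,
    own_performance_reliability,
    second_step_multitrait,
    yield_deviations,
)
from helpers import random_pedigree, random_records


class TestEOP:
    def test_zero_reliability_gives_zero(self):
        assert eop(1.5, 0.0) == 0.0

    def test_single_own_record_gives_exactly_one(self):
        """With r² = h², EOP = alpha h²/(1-h²) = 1 for any h²."""
        for h2 in (0.40, 0.39, 0.27, 0.12, 0.02):
            alpha = (1 - h2) / h2
            assert eop(alpha, own_performance_reliability(1, h2)) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert eop(1.5, 0.6) == pytest.approx(1.5 / 0.4 - 1.5)

    def test_invalid_reliability_rejected(self):
        with pytest.raises(ValueError):
            eop(1.0, 1.0)


class TestEDC:
    def test_values_and_monotonicity(self):
        assert edc(0.0, 0.4) == 0.0
        assert edc(0.5, 0.4) == pytest.approx(9.0)
        r = np.linspace(0, 0.95, 50)
        assert np.all(np.diff(edc(r, 0.25)) > 0)

    def test_reliability_bound_rejected(self):
        with pytest.raises(ValueError):
            edc(1.0, 0.4)

    def test_own_information_removes_parent_average(self):
        h2 = 0.3
        # parent-average-only animal: own-information reliability is zero
        r_pa = 0.25 * (0.8 + 0.4)
        assert own_information_reliability(np.array([r_pa]), np.array([0.8]),
                                           np.array([0.4]), h2)[0] == pytest.approx(0.0)
        # own information beyond the parent average survives the subtraction
        out = own_information_reliability(np.array([0.6]), np.array([0.8]),
                                          np.array([0.4]), h2)[0]
        assert 0 < out < 0.6


class TestYieldDeviations:
    def test_two_record_toy(self, params):
        """One herd-year with values 10 and 12: estimates absorb the mean."""
        ped = Pedigree([-1, -1], [-1, -1], [FEMALE, FEMALE], [0, 0])
        rs = RecordSet([0, 1], [0, 0], [10.0, 12.0], [0, 0], [1, 1])
        uni = univariate_evaluation(rs, ped, 0, params, reliabilities=False)
        fixed = {0: fixed_solution_levels(uni)}
        yd = yield_deviations(rs, fixed)
        # by symmetry the estimated herd-year effect is exactly the mean 11
        assert fixed[0][1] == pytest.approx(11.0)
        assert yd.value == pytest.approx([-1.0, 1.0])

    def test_constant_herd_year_absorbed(self, params):
        ped = Pedigree([-1] * 3, [-1] * 3, [FEMALE] * 3, [0] * 3)
        rs = RecordSet([0, 1, 2], [0, 0, 0], [7.0, 7.0, 7.0], [0, 0, 0], [1, 1, 1])
        uni = univariate_evaluation(rs, ped, 0, params, reliabilities=False)
        yd = yield_deviations(rs, {0: fixed_solution_levels(uni)})
        assert np.allclose(yd.value, 0.0, atol=1e-8)

    def test_missing_level_rejected(self, params):
        rs = RecordSet([0], [0], [1.0], [3], [9])
        with pytest.raises(ValueError, match="no herd-year solution"):
            yield_deviations(rs, {0: {}})


class TestDeregression:
    def _univariate_setup(self, seed, n=120):
        rng = np.random.default_rng(seed)
        params = GeneticParams()
        ped = random_pedigree(rng, n)
        rs = random_records(rng, ped)
        uni = univariate_evaluation(rs, ped, 0, params, reliabilities=False)
        recorded = np.zeros(ped.n)
        np.add.at(recorded, rs.animal[rs.trait == 0], 1.0)
        return params, ped, rs, uni, recorded

    def test_round_trip_is_the_defining_property(self):
        params, ped, rs, uni, recorded = self._univariate_setup(seed=2, n=400)
        w = np.where(recorded > 0, 1.0, 0.0)
        y, idx, mu = deregress(uni.ebv[:, 0], w, ped, params.sigma_a2[0],
                               params.sigma_e2[0], verify_tol=1e-4)
        ai = build_a_inverse(ped)
        resid = _roundtrip_residual(y, idx, w, ped, params.sigma_a2[0],
                                    params.sigma_e2[0], ai, uni.ebv[:, 0])
        assert resid < 1e-6

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=8, deadline=None)
    def test_round_trip_random_instances(self, seed):
        params, ped, rs, uni, recorded = self._univariate_setup(seed, n=80)
        rng = np.random.default_rng(seed + 1)
        # arbitrary positive weights on recorded animals (EDC-like spread)
        w = np.where(recorded > 0, rng.uniform(0.5, 20.0, ped.n), 0.0)
        y, idx, _ = deregress(uni.ebv[:, 0], w, ped, params.sigma_a2[0],
                              params.sigma_e2[0], verify_tol=1e-4)
        assert idx.shape[0] == int((w > 0).sum())

    def test_single_unrelated_animal_limit(self, params):
        """drEBV -> EBV as the weight grows (alpha/w -> 0)."""
        ped = Pedigree([-1], [-1], [FEMALE], [0])
        ai = build_a_inverse(ped)
        u = np.array([0.8])
        for w, tol in ((1e6, 1e-4), (1.0, 10.0)):
            y, idx, mu = deregress(u, np.array([w]), ped, 1.0,
                                   params.sigma_e2[0], a_inv=ai)
            # y = mu + u(1 + alpha/w) for a single unrelated animal
            alpha = params.sigma_e2[0] / 1.0
            assert y[0] - mu == pytest.approx(u[0] * (1 + alpha / w), abs=1e-9)

    def test_zero_weight_animal_gets_no_pseudo_record(self):
        params, ped, rs, uni, recorded = self._univariate_setup(seed=7)
        w = np.where(recorded > 0, 1.0, 0.0)
        _, idx, _ = deregress(uni.ebv[:, 0], w, ped, params.sigma_a2[0],
                              params.sigma_e2[0])
        assert set(idx) == set(np.where(w > 0)[0])


class TestSecondStep:
    def test_complete_data_equals_multitrait(self, rng):
        """All animals recorded for all traits in one herd-year: YD second
        step reproduces the reference multitrait EBV."""
        params = GeneticParams(residual_fraction=0.5)
        base = random_pedigree(rng, 60)
        ped = Pedigree(base.sire, base.dam, base.sex,
                       np.zeros(base.n, dtype=np.int64))  # single birth cohort
        n = ped.n
        animal = np.repeat(np.arange(n), 5)
        trait = np.tile(np.arange(5), n)
        value = rng.standard_normal(n * 5)
        rs = RecordSet(animal, trait, value, np.zeros(n * 5, int), np.zeros(n * 5, int))
        multi = solve_mme(build_mme(rs, ped, ModelSpec(params=params)))
        fixed = {}
        for t in range(5):
            uni = univariate_evaluation(rs, ped, t, params, reliabilities=False)
            fixed[t] = fixed_solution_levels(uni)
        yd = yield_deviations(rs, fixed)
        res = second_step_multitrait(yd, ped, params)
        # one herd-year and one birth year: identical estimable structure
        assert np.abs(res.ebv - multi.ebv).max() < 1e-6

    def test_all_zero_pseudo_records_give_zero_ebv(self, rng, params):
        ped = random_pedigree(rng, 30)
        rs = RecordSet(np.arange(30), np.zeros(30, int), np.zeros(30))
        res = second_step_multitrait(rs, ped, params)
        assert np.abs(res.ebv).max() < 1e-12

    def test_animal_outside_pedigree_rejected(self, rng, params):
        ped = random_pedigree(rng, 10)
        rs = RecordSet([25], [0], [1.0])
        with pytest.raises(ValueError, match="unknown animal"):
            second_step_multitrait(rs, ped, params)
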