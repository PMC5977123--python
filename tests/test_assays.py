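import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnplem.assays import (
    FociRecord,
    PlateRecord,
    SFEstimate,
    UptakeMeasurement,
    fold_change,
    foci_density,
    gnp_count_from_gold_mass,
    percent_decrease_with_error,
    plating_efficiency,
    summarize_sf,
    survival_fraction,
    welch_t_test,
)


def plates(*pairs, condition="ctrl"):
    return [
        PlateRecord(condition=condition, cells_plated=n, colonies=c, replicate=i)
        for i, (c, n) in enumerate(pairs)
    ]


class TestPlatingEfficiency:
    def test_single_plate(self):
        assert plating_efficiency(plates((100, 200))) == 0.5

    def test_pooling_over_plates(self):
        assert plating_efficiency(plates((50, 100), (50, 100))) == 0.5

    def test_zero_colonies_warns(self):
        with pytest.warns(UserWarning, match="plating efficiency is 0"):
            assert plating_efficiency(plates((0, 100))) == 0.0

    def test_no_plates_rejected(self):
        with pytest.raises(ValueError):
            plating_efficiency([])


class TestSurvivalFraction:
    def test_direct_formula(self):
        p = PlateRecord("t", 400, 50)
        assert survival_fraction(p, 0.5) == 0.25

    def test_matching_control_gives_unity(self):
        p = PlateRecord("t", 100, 50)
        assert survival_fraction(p, 0.5) == 1.0

    def test_zero_pe_rejected(self):
        with pytest.raises(ValueError):
            survival_fraction(PlateRecord("t", 100, 10), 0.0)


class TestSummarize:
    def test_hand_arithmetic(self):
        est = summarize_sf([0.2, 0.3])
        assert est.mean == pytest.approx(0.25)
        assert est.sem == pytest.approx(0.05)
        assert est.n == 2

    def test_identical_replicates_zero_sem(self):
        assert summarize_sf([0.4, 0.4, 0.4]).sem == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_sf([0.5])

    def test_mean_above_one_rejected(self):
        with pytest.raises(ValueError, match="survival fraction mean"):
            summarize_sf([1.2, 1.3])


class TestPercentDecrease:
    @pytest.mark.parametrize(
        "ref,other,pct,err",
        [
            (SFEstimate(0.31, 0.008, 3), SFEstimate(0.25, 0.014, 3), 19.4, 5.0),
            (SFEstimate(0.23, 0.011, 3), SFEstimate(0.16, 0.007, 3), 30.4, 4.5),
        ],
    )
    def test_sensitization_with_delta_method_error(self, ref, other, pct, err):
        got_pct, got_err = percent_decrease_with_error(ref, other)
        assert got_pct == pytest.approx(pct, abs=0.05)
        assert got_err == pytest.approx(err, abs=0.05)

    def test_equal_arms_zero(self):
        a = SFEstimate(0.5, 0.01, 3)
        assert percent_decrease_with_error(a, a)[0] == 0.0

    def test_sign_flips_when_arms_swap(self):
        a, b = SFEstimate(0.5, 0.01, 3), SFEstimate(0.4, 0.01, 3)
        assert percent_decrease_with_error(a, b)[0] > 0
        assert percent_decrease_with_error(b, a)[0] < 0


class TestFociDensity:
    def test_single_nucleus(self):
        d, _ = foci_density([FociRecord(0, 4, 100.0)])
        assert d == 0.04

    def test_doubling_areas_halves_density(self):
        recs = [FociRecord(i, 3, 75.0) for i in range(5)]
        doubled = [FociRecord(i, 3, 150.0) for i in range(5)]
        assert foci_density(doubled)[0] == pytest.approx(foci_density(recs)[0] / 2)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        recs = [FociRecord(i, int(c), float(a)) for i, (c, a) in
                enumerate(zip(rng.poisson(5, 30), rng.uniform(50, 300, 30)))]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        got, ref = foci_density(shuffled), foci_density(recs)
        assert got[0] == pytest.approx(ref[0], rel=1e-12)
        assert got[1] == pytest.approx(ref[1], rel=1e-12)


class TestUptakeArithmetic:
    def test_one_particle_mass(self):
        assert gnp_count_from_gold_mass(UptakeMeasurement(1.01e-17, 10.0)) == pytest.approx(1.0, rel=2e-3)

    def test_study_scale_count(self):
        n = gnp_count_from_gold_mass(UptakeMeasurement(5.66e-13, 10.0))
        assert n == pytest.approx(56_000, rel=0.01)

    def test_zero_mass(self):
        assert gnp_count_from_gold_mass(UptakeMeasurement(0.0, 10.0)) == 0.0

    @pytest.mark.parametrize("a,b,expected", [(56_000, 358_000, 6.39), (56_000, 367_000, 6.55)])
    def test_fold_change_in_printed_range(self, a, b, expected):
        fc = fold_change(a, b)
        assert fc == pytest.approx(expected, abs=0.005)
        assert 6 <= fc <= 7

    def test_fold_change_identity_and_zero(self):
        assert fold_change(5, 5) == 1.0
        with pytest.raises(ValueError):
            fold_change(0, 5)


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_test([0.2, 0.3, 0.25], [0.2, 0.3, 0.25])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_huge_separation(self):
        rng = np.random.default_rng(1)
        _, p = welch_t_test(rng.normal(0.01, 0.001, 10), rng.normal(0.9, 0.001, 10))
        assert p < 1e-6

    def test_agrees_with_permutation_oracle(self):
        """Welch p within 0.02 of an exhaustive-ish permutation p at n=9 vs 9."""
        rng = np.random.default_rng(3)
        a = rng.normal(0.31, 0.02, 9)
        b = rng.normal(0.25, 0.02, 9)
        t_obs, p_welch = welch_t_test(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            t_perm, _ = welch_t_test(pooled[:9], pooled[9:])
            if abs(t_perm) >= abs(t_obs):
                count += 1
        p_perm = count / n_perm
        assert abs(p_welch - p_perm) < 0.02

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    colonies=st.lists(st.integers(0, 100), min_size=2, max_size=10),
    plated=st.integers(100, 1000),
)
def test_pe_invariant_to_plate_order(colonies, plated):
    recs = plates(*[(c, plated) for c in colonies])
    assert plating_efficiency(recs) == plating_efficiency(recs[::-1])
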