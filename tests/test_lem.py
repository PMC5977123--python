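import math

import numpy as np
import pytest

from gnplem import (
    CellGeometry,
    IrradiationConfig,
    LQParams,
    PlacementConfig,
    VesicleSpec,
    kernel_dose_at,
    make_power_law_kernel,
    sample_gnp_positions,
)
from gnplem.dose_kernel import KernelCalibration
from gnplem.geometry import GNPPlacement
from gnplem.lem import (
    NucleusDoseSample,
    lem_survival_fraction,
    lq_survival,
    run_scenario,
    sf_reduction_percent,
    superpose_nucleus_dose,
)
from gnplem.units import NM_PER_UM


class TestSurvivalFraction:
    def test_uniform_field_matches_lq_closed_form(self, lq):
        """Uniform 2 Gy with alpha=0.002, beta=0.079 gives exp(-0.32)."""
        sample = NucleusDoseSample(np.zeros((500, 3)), np.full(500, 2.0), 2.0)
        sf = lem_survival_fraction(sample, lq)
        assert sf == pytest.approx(math.exp(-0.32), abs=1e-12)
        assert round(sf, 5) == 0.72615

    def test_zero_dose_gives_unity_survival(self, lq):
        sample = NucleusDoseSample(np.zeros((100, 3)), np.zeros(100), 0.0)
        assert lem_survival_fraction(sample, lq) == 1.0

    def test_heterogeneous_field_kills_more_than_uniform_same_mean(self, lq):
        """Jensen: with beta > 0, a two-level field with the same mean dose
        yields lower survival than the uniform field."""
        uniform = NucleusDoseSample(np.zeros((2, 3)), np.array([2.0, 2.0]), 2.0)
        split = NucleusDoseSample(np.zeros((2, 3)), np.array([1.0, 3.0]), 2.0)
        assert lem_survival_fraction(split, lq) < lem_survival_fraction(uniform, lq)


class TestReductionPercent:
    @pytest.mark.parametrize(
        "sf_gnp,sf_bg,expected_rounded",
        [(0.25, 0.31, 19), (0.16, 0.23, 30)],
    )
    def test_study_sensitization_values(self, sf_gnp, sf_bg, expected_rounded):
        assert round(sf_reduction_percent(sf_gnp, sf_bg)) == expected_rounded

    def test_no_change_is_zero(self):
        assert sf_reduction_percent(0.5, 0.5) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sf_reduction_percent(0.5, 0.0)


class TestSuperposition:
    def test_empty_placement_gives_prescribed_dose(self, geom, kernel_10nm):
        cfg = PlacementConfig(scenario="uniform_cytoplasm", n_gnp=0, seed=0)
        placement = sample_gnp_positions(geom, cfg)
        irr = IrradiationConfig(n_integration_points=200, seed=0)
        sample = superpose_nucleus_dose(placement, kernel_10nm, geom, irr)
        assert np.all(sample.dose == 2.0)

    def test_single_gnp_contribution_matches_kernel_lookup(self, geom, kernel_10nm):
        """Each point's dose is 2 x (1 + kernel at its distance to the GNP)."""
        g = np.array([[5.0, 0.0, 0.0]])
        placement = GNPPlacement(g, 10.0, PlacementConfig("uniform_cytoplasm", 1))
        irr = IrradiationConfig(n_integration_points=500, seed=1)
        sample = superpose_nucleus_dose(placement, kernel_10nm, geom, irr)
        r_nm = np.linalg.norm(sample.points - g, axis=1) * NM_PER_UM
        expected = 2.0 * (1.0 + kernel_dose_at(kernel_10nm, r_nm))
        np.testing.assert_allclose(sample.dose, expected, rtol=1e-9)

    def test_indexed_equals_bruteforce_oracle(self, geom, kernel_10nm):
        """Cutoff-indexed superposition equals the all-pairs double loop."""
        cfg = PlacementConfig(scenario="uniform_cytoplasm", n_gnp=100, seed=5)
        placement = sample_gnp_positions(geom, cfg)
        irr = IrradiationConfig(n_integration_points=100, seed=5)
        fast = superpose_nucleus_dose(placement, kernel_10nm, geom, irr, method="indexed")
        slow = superpose_nucleus_dose(placement, kernel_10nm, geom, irr, method="bruteforce")
        np.testing.assert_allclose(fast.dose, slow.dose, rtol=1e-12)

    def test_oracle_equivalence_on_file_kernel(self, geom, tmp_path, kernel_10nm):
        """The non-uniform-grid fallback path agrees with the oracle too."""
        from gnplem.dose_kernel import RadialDoseKernel, read_kernel_table, write_kernel_table

        edges = np.array([5.0, 100.0, 500.0, 2000.0, 5000.0])
        dose = np.array([4e-4, 1e-4, 2e-5, 4e-6])
        k = RadialDoseKernel(10.0, edges, dose)
        cfg = PlacementConfig(scenario="perinuclear", n_gnp=300, seed=9)
        placement = sample_gnp_positions(geom, cfg)
        irr = IrradiationConfig(n_integration_points=100, seed=9)
        fast = superpose_nucleus_dose(placement, k, geom, irr, method="indexed")
        slow = superpose_nucleus_dose(placement, k, geom, irr, method="bruteforce")
        np.testing.assert_allclose(fast.dose, slow.dose, rtol=1e-12)

    def test_diameter_mismatch_rejected(self, geom, kernel_10nm):
        cfg = PlacementConfig(scenario="uniform_cytoplasm", n_gnp=10, gnp_diameter_nm=2.0, seed=0)
        placement = sample_gnp_positions(geom, cfg)
        with pytest.raises(ValueError, match="diameter"):
            superpose_nucleus_dose(placement, kernel_10nm, geom, IrradiationConfig())

    def test_all_points_inside_nucleus_and_dose_floor(self, geom, kernel_10nm):
        cfg = PlacementConfig(scenario="perinuclear", n_gnp=2000, seed=2)
        placement = sample_gnp_positions(geom, cfg)
        irr = IrradiationConfig(n_integration_points=1000, seed=2)
        sample = superpose_nucleus_dose(placement, kernel_10nm, geom, irr)
        assert np.all(np.linalg.norm(sample.points, axis=1) <= geom.nucleus_radius)
        assert np.all(sample.dose >= irr.prescribed_dose)


class TestScenarioPipeline:
    def test_reduction_monotone_in_gnp_count(self):
        irr = IrradiationConfig(n_integration_points=2000, seed=0)
        reds = []
        for n in (2000, 10_000, 50_000):
            df = run_scenario("perinuclear", n, 10.0, seeds=(0, 1), irr_template=irr)
            reds.append(df["reduction_pct"].mean())
        assert reds[0] < reds[1] < reds[2]

    def test_reduction_monotone_in_eta(self):
        irr = IrradiationConfig(n_integration_points=2000, seed=0)
        reds = []
        for eta in (0.25, 0.5, 1.0):
            df = run_scenario(
                "perinuclear", 20_000, 10.0, seeds=(0, 1), irr_template=irr,
                calib=KernelCalibration(eta=eta),
            )
            reds.append(df["reduction_pct"].mean())
        assert reds[0] < reds[1] < reds[2]

    def test_run_scenario_columns_and_baseline(self, lq):
        irr = IrradiationConfig(n_integration_points=500, seed=0)
        df = run_scenario("uniform_cytoplasm", 1000, 10.0, seeds=(0,), irr_template=irr)
        assert set(df.columns) >= {"scenario", "diameter_nm", "n_gnp", "seed",
                                   "sf_bg", "sf_gnp", "reduction_pct"}
        assert df["sf_bg"].iloc[0] == pytest.approx(lq_survival(2.0, lq))
        assert (df["reduction_pct"] > 0).all()
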