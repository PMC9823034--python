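"""Standard-curve fitting, noise level, detection limits and inversion."""

import numpy as np
import pandas as pd
import pytest

from squidms.calibration import CalibrationError, fit_curve, limits
from squidms.isotope_quant import quantify_pairs
from squidms.peak_integration import integrate_run
from squidms.injection_windows import InjectionSchedule
from squidms.simulate import SimulationConfig, simulate_dilution_series


def exact_points(slope=0.004, intercept=0.0, levels=(50, 500, 5000, 50000), reps=2):
    rows = [
        {"nominal_nM": level, "ratio": slope * level + intercept}
        for level in levels
        for _ in range(reps)
    ]
    return pd.DataFrame(rows)


class TestFitCurve:
    def test_noiseless_fit_is_exact(self):
        curve = fit_curve(exact_points())
        assert curve.slope == pytest.approx(0.004, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.nrmse == pytest.approx(0.0, abs=1e-9)
        assert curve.valid

    def test_noiseless_round_trip_recovers_nominals_exactly(self):
        points = exact_points()
        curve = fit_curve(points)
        for _, row in points.iterrows():
            concentration, _, _ = curve.quantify(row["ratio"])
            assert concentration == pytest.approx(row["nominal_nM"], rel=1e-9)

    def test_blank_replicates_define_noise_level(self):
        rng = np.random.default_rng(4)
        points = exact_points()
        blank_ratios = rng.normal(0.0, 0.01, size=6)
        blanks = pd.DataFrame({"nominal_nM": 0.0, "ratio": blank_ratios})
        curve = fit_curve(pd.concat([points, blanks], ignore_index=True))
        assert curve.noise_level == pytest.approx(np.std(blank_ratios, ddof=1))
        assert curve.llod_nM == pytest.approx(3 * curve.noise_level / curve.slope)

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(CalibrationError):
            fit_curve(exact_points(levels=(50, 500)))

    def test_negative_slope_invalidates_curve(self):
        points = exact_points(slope=-0.001, intercept=100.0)
        curve = fit_curve(points)
        assert not curve.valid
        with pytest.raises(CalibrationError):
            curve.quantify(1.0)

    @pytest.mark.parametrize("weighting", ["none", "1/x", "1/x2"])
    def test_weighting_modes_exact_on_noiseless_data(self, weighting):
        curve = fit_curve(exact_points(), weighting_mode=weighting)
        assert curve.slope == pytest.approx(0.004, rel=1e-9)


class TestLimits:
    def test_arithmetic(self):
        assert limits(0.01, 0.004) == pytest.approx((7.5, 25.0))
        assert limits(0.02, 0.004) == pytest.approx((15.0, 50.0))

    def test_zero_noise_gives_zero_limits(self):
        assert limits(0.0, 0.004) == (0.0, 0.0)

    def test_lloq_to_llod_is_ten_thirds(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            llod, lloq = limits(rng.uniform(1e-4, 1.0), rng.uniform(1e-5, 1.0))
            assert lloq / llod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            limits(0.01, 0.0)


@pytest.fixture(scope="module")
def fitted(agmatine_targets):
    config = SimulationConfig(seed=17)
    run, truth, design = simulate_dilution_series(config=config)
    schedule = InjectionSchedule(
        t0=config.t0,
        cadence=config.cadence,
        n_injections=len(design),
        sample_labels=list(design["sample_label"]),
    )
    peaks = integrate_run(run, agmatine_targets, schedule)
    quant = quantify_pairs(peaks, agmatine_targets)
    points = quant.merge(design, on="sample_label")[["nominal_nM", "ratio"]]
    return fit_curve(points), design, quant.merge(design, on="sample_label")


class TestSimulatedDilutionSeries:
    def test_design_cardinality(self, fitted):
        _, design, _ = fitted
        assert len(design) == 32  # 8 levels x 4 replicates

    def test_slope_recovery_within_5pct(self, fitted):
        curve, _, _ = fitted
        # identical response of isotopologues: true slope is 1 / C_IS
        assert curve.slope == pytest.approx(1.0 / 250.0, rel=0.05)
        assert curve.lloq_nM / curve.llod_nM == pytest.approx(10.0 / 3.0, rel=1e-9)

    def test_concentration_recovery_within_10pct_above_lloq(self, fitted):
        curve, _, merged = fitted
        above = merged[merged["nominal_nM"] >= max(curve.lloq_nM, 50.0)]
        for _, row in above.iterrows():
            concentration, _, _ = curve.quantify(row["ratio"])
            assert concentration == pytest.approx(row["nominal_nM"], rel=0.10)

    def test_llod_scales_linearly_with_ratio_noise(self):
        """Doubling the blank-replicate ratio noise doubles the recovered LLOD
        (LLOD = 3 * noise / slope)."""
        rng = np.random.default_rng(23)
        llods = []
        for sd in (0.01, 0.02):
            points = exact_points(reps=4)
            blanks = pd.DataFrame(
                {"nominal_nM": 0.0, "ratio": rng.normal(0.0, sd, size=50)}
            )
            curve = fit_curve(pd.concat([points, blanks], ignore_index=True))
            assert curve.llod_nM == pytest.approx(3 * sd / 0.004, rel=0.35)
            llods.append(curve.llod_nM)
        assert llods[1] / llods[0] == pytest.approx(2.0, rel=0.35)

    def test_simulated_llod_increases_with_baseline_noise(self, agmatine_targets):
        """More instrument noise can only worsen the detection limit; checked
        on seed-averaged simulated dilution series."""
        mean_llods = []
        for noise in (5.0, 20.0):
            llods = []
            for seed in (23, 24, 25, 26, 27):
                config = SimulationConfig(seed=seed, baseline_noise_sd=noise)
                run, _, design = simulate_dilution_series(config=config)
                schedule = InjectionSchedule(
                    t0=config.t0,
                    cadence=config.cadence,
                    n_injections=len(design),
                    sample_labels=list(design["sample_label"]),
                )
                peaks = integrate_run(run, agmatine_targets, schedule)
                quant = quantify_pairs(peaks, agmatine_targets)
                points = quant.merge(design, on="sample_label")[["nominal_nM", "ratio"]]
                llods.append(fit_curve(points).llod_nM)
            mean_llods.append(np.mean(llods))
        assert mean_llods[1] > mean_llods[0]
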