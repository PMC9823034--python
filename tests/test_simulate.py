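"""Simulator ground truth, determinism, and the end-to-end contrast between
raw-area variability and isotope-ratio stability."""

import numpy as np
import pytest

from squidms.injection_windows import InjectionSchedule
from squidms.isotope_quant import mean_percent_error, nrmse, quantify_pairs
from squidms.peak_integration import integrate_run
from squidms.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_dilution_series,
    simulate_run,
)

SQRT_2PI = np.sqrt(2 * np.pi)


def run_signature(run):
    return [
        (s.retention_time, s.mz_values.tobytes(), s.intensities.tobytes())
        for s in run.spectra
    ]


class TestSimulateRun:
    def test_same_seed_identical_runs(self):
        config = SimulationConfig(n_injections=4, seed=99)
        run_a, truth_a = simulate_run(config)
        run_b, truth_b = simulate_run(SimulationConfig(n_injections=4, seed=99))
        assert run_signature(run_a) == run_signature(run_b)
        assert np.array_equal(truth_a.suppression, truth_b.suppression)

    def test_different_seed_differs(self):
        run_a, _ = simulate_run(SimulationConfig(n_injections=4, seed=1))
        run_b, _ = simulate_run(SimulationConfig(n_injections=4, seed=2))
        assert run_signature(run_a) != run_signature(run_b)

    def test_truth_areas_follow_suppression_and_concentration(self):
        config = SimulationConfig(n_injections=6, seed=5)
        _, truth = simulate_run(config)
        assert np.allclose(
            truth.light_areas,
            truth.suppression * config.response_factor * truth.concentrations_nM,
        )
        assert np.allclose(
            truth.heavy_areas,
            truth.suppression * config.response_factor * config.is_concentration_nM,
        )
        # true ratios are suppression-free by construction
        assert np.allclose(truth.ratios, truth.concentrations_nM / 250.0)

    def test_zero_noise_zero_suppression_recovery_within_1pct(
        self, agmatine_targets
    ):
        config = SimulationConfig(
            n_injections=3, suppression_sigma=0.0, baseline_noise_sd=0.0, seed=2
        )
        run, truth = simulate_run(config)
        schedule = InjectionSchedule(t0=config.t0, cadence=config.cadence, n_injections=3)
        results = integrate_run(run, agmatine_targets, schedule)
        light = results[results["target_name"] == "agmatine"].sort_values("window_index")
        expected = config.response_factor * np.asarray(config.light_concentrations_nM)
        assert np.allclose(light["area"], expected, rtol=0.01)

    def test_mass_centroids_stay_inside_10ppm_window(self):
        run, _ = simulate_run(SimulationConfig(n_injections=2, seed=13))
        light_mz, heavy_mz = 131.129122, 136.145897
        for spectrum in run.spectra:
            for mz in spectrum.mz_values:
                nearest = min((light_mz, heavy_mz), key=lambda m: abs(mz - m))
                assert abs(mz - nearest) / nearest < 10e-6

    def test_suppression_contrast_raw_vs_ratio(self, replicate_run, agmatine_targets):
        """With sigma_s = 0.10 and zero baseline noise the raw light-area NRMSE
        matches the population spread of the suppression factors while the
        ratio NRMSE collapses to machine precision."""
        run, truth, schedule, _ = replicate_run
        peaks = integrate_run(run, agmatine_targets, schedule)
        quant = quantify_pairs(peaks, agmatine_targets)
        light = peaks[peaks["target_name"] == "agmatine"]["area"].to_numpy()
        raw_nrmse = nrmse(light, float(light.mean()))
        spread = float(truth.suppression.std() / truth.suppression.mean())
        assert raw_nrmse > 0.05
        assert raw_nrmse == pytest.approx(spread, rel=0.05)
        ratio_nrmse = nrmse(quant["ratio"].to_numpy(), float(truth.ratios[0]))
        assert ratio_nrmse < 1e-9

    def test_corrected_beats_raw_over_replicate_seeds(self, agmatine_targets):
        """Across seeded replicates at sigma_s = 0.10 and high SNR, the
        concentration mean-percent-error stays small while the raw-area
        mean-percent-error reflects the suppression spread."""
        raw_errors, corrected_errors = [], []
        for seed in range(10):
            config = SimulationConfig(
                n_injections=12,
                suppression_sigma=0.10,
                baseline_noise_sd=5.0,
                seed=100 + seed,
            )
            run, truth = simulate_run(config)
            schedule = InjectionSchedule(
                t0=config.t0, cadence=config.cadence, n_injections=12
            )
            peaks = integrate_run(run, agmatine_targets, schedule)
            quant = quantify_pairs(peaks, agmatine_targets)
            light = peaks[peaks["target_name"] == "agmatine"]["area"].to_numpy()
            raw_errors.append(
                mean_percent_error(light, config.response_factor * 5000.0)
            )
            corrected_errors.append(
                mean_percent_error(quant["concentration_nM"].to_numpy(), 5000.0)
            )
        assert np.mean(corrected_errors) < 3.0
        assert np.mean(raw_errors) > 5.0
        assert np.mean(corrected_errors) < np.mean(raw_errors)


class TestSimulateCohort:
    def test_cohort_cardinality_and_labels(self):
        config = SimulationConfig(seed=31)
        run, truth, cohort = simulate_cohort(8, 9, config=config)
        assert len(cohort) == 17
        assert (cohort["culture_status"] == "positive").sum() == 8
        assert np.all(cohort.loc[cohort["culture_status"] == "negative",
                                 "true_concentration_nM"] == 0.0)

    def test_all_negative_cohort_every_light_missing(self, agmatine_targets):
        config = SimulationConfig(seed=37)
        run, _, cohort = simulate_cohort(0, 6, config=config)
        schedule = InjectionSchedule(
            t0=config.t0,
            cadence=config.cadence,
            n_injections=6,
            sample_labels=list(cohort["sample_label"]),
        )
        results = integrate_run(run, agmatine_targets, schedule)
        light = results[results["target_name"] == "agmatine"]
        assert light["flags"].str.contains("missing").all()


class TestSimulateDilutionSeries:
    def test_cardinality(self):
        _, _, design = simulate_dilution_series(config=SimulationConfig(seed=41))
        assert len(design) == 32
        assert design["nominal_nM"].min() == 50.0
        assert design["nominal_nM"].max() == 50000.0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series(levels_nM=[50.0, 500.0])
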