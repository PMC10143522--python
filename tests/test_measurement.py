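"""Tests for calibration fitting and fraction processing."""

import numpy as np
import pytest

from spikertd.compartment import CompartmentParams, SpikeSchedule, window_averaged_outlet
from spikertd.measurement import (
    CalibrationCurve,
    CalibrationError,
    FractionRecord,
    fit_calibration,
    process_fractions,
)
from spikertd.synthetic import ExperimentConfig, generate_experiment

PARAMS = CompartmentParams(4.3, (4.1, 1.0))


class TestCalibration:
    def test_exact_linear_data_recovered(self):
        conc = np.linspace(0, 4e-3, 6)
        cal = fit_calibration(list(zip(conc, 1.2e5 * conc + 0.49)))
        assert cal.slope == pytest.approx(1.2e5, rel=1e-12)
        assert cal.intercept == pytest.approx(0.49, rel=1e-9)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_blank_standard_pins_intercept(self):
        cal = fit_calibration([(0.0, 0.7), (1e-3, 0.7 + 120.0)])
        assert cal.intercept == pytest.approx(0.7, rel=1e-12)

    def test_rank_deficient_standards_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(1e-3, 120.0), (1e-3, 121.0)])

    def test_slope_recovered_within_sampling_error(self):
        """Monte-Carlo: the OLS slope lands within 3 fitted standard errors
        of the generating slope in almost all seeds."""
        true_slope, true_b, sd = 1.2e5, 0.49, 0.05
        conc = np.linspace(0, 4e-3, 8)
        failures = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            cond = true_slope * conc + true_b + rng.normal(0, sd, conc.size)
            cal = fit_calibration(list(zip(conc, np.maximum(cond, 0))))
            sxx = np.sum((conc - conc.mean()) ** 2)
            se = cal.residual_sd / np.sqrt(sxx) if cal.residual_sd > 0 else sd / np.sqrt(sxx)
            if abs(cal.slope - true_slope) > 3 * se:
                failures += 1
        assert failures <= 10  # ~0.3% expected rate per seed; allow slack


class TestProcessFractions:
    def test_completely_mixed_fraction_normalizes_to_one(self):
        s = SpikeSchedule()
        cal = CalibrationCurve(1.2e5, 0.49)
        volume, dilution = 0.82, 25.0
        c_diluted = s.c_mixed * volume / dilution
        rec = FractionRecord(0, 2, volume, (float(cal.to_conductivity(c_diluted)),) * 3)
        curve = process_fractions([rec], cal, dilution, s)
        assert curve.values[0] == pytest.approx(1.0, rel=1e-12)
        assert curve.times[0] == pytest.approx(1.0)  # window midpoint

    def test_blank_fraction_is_zero(self):
        s = SpikeSchedule()
        cal = CalibrationCurve(1.2e5, 0.49)
        rec = FractionRecord(0, 2, 0.82, (0.49, 0.49, 0.49))
        curve = process_fractions([rec], cal, 25.0, s)
        assert curve.values[0] == 0.0

    def test_collected_volume_matches_feed_rate(self):
        """A 2-min window at the 0.41 mL/min feed collects 0.82 mL."""
        cfg = ExperimentConfig(schedule=SpikeSchedule(), replicate_sd=0.0)
        exp = generate_experiment(cfg)
        assert exp.fractions[0].volume == pytest.approx(0.41 * 2.0)

    def test_dilution_invariance(self):
        s = SpikeSchedule()
        cal = CalibrationCurve(1.2e5, 0.49)
        c_sample = 0.5 * s.c_mixed
        curves = []
        for volume in (0.82, 0.41):
            cond = float(cal.to_conductivity(c_sample * volume / 25.0))
            rec = FractionRecord(0, 2, volume, (cond,))
            curves.append(process_fractions([rec], cal, 25.0, s))
        assert curves[0].values[0] == pytest.approx(curves[1].values[0], rel=1e-12)

    def test_overlapping_fractions_rejected(self):
        s = SpikeSchedule()
        cal = CalibrationCurve(1.2e5, 0.49)
        recs = [FractionRecord(0, 2, 0.8, (1.0,)), FractionRecord(1, 3, 0.8, (1.0,))]
        with pytest.raises(ValueError):
            process_fractions(recs, cal, 25.0, s)

    def test_negative_concentration_clipped(self, caplog):
        s = SpikeSchedule()
        cal = CalibrationCurve(1.2e5, 0.49, residual_sd=0.0)
        rec = FractionRecord(0, 2, 0.8, (0.1, 0.1, 0.1))  # below intercept
        with caplog.at_level("WARNING"):
            curve = process_fractions([rec], cal, 25.0, s)
        assert curve.values[0] == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_round_trip_reproduces_window_averaged_truth(self):
        """Noiseless generate -> process with the generating calibration
        reproduces the window-averaged model curve to float precision."""
        s = SpikeSchedule(t_spike=5.0)
        cfg = ExperimentConfig(schedule=s, true_params=PARAMS,
                               replicate_sd=0.0, standard_noise_sd=0.0)
        exp = generate_experiment(cfg)
        cal = CalibrationCurve(cfg.cal_slope, cfg.baseline_mean)
        curve = process_fractions(exp.fractions, cal, cfg.dilution_volume, s)
        truth = window_averaged_outlet(curve.windows, s, PARAMS)
        np.testing.assert_allclose(curve.values, truth, rtol=1e-10, atol=1e-14)
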