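"""Seeded generator of a full synthetic inline-spiking experiment.

Emulates the bench protocol: a 1 M NaCl spike fed at 1/10 of a 0.41 mL/min
feed for 1, 5 or 40 min, transport through the PFR-2CSTR train, fraction
collection every 2 min (~0.8 mL), dilution to 25 mL, and triplicate
conductivity reads on top of a 0.49 +/- 0.06 uS/cm deionized-water baseline.

The noiseless component is exact (analytic window averages of the
closed-form outlet) and seed-invariant; seeds only move the Gaussian
replicate noise, so generation is fully deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compartment import (
    CompartmentParams,
    RTDCurve,
    SpikeSchedule,
    closed_form_outlet,
    window_averaged_outlet,
)
from .measurement import FractionRecord

__all__ = ["ExperimentConfig", "SyntheticExperiment", "generate_experiment", "write_experiment"]

# Dilute-NaCl conductivity slope, uS/cm per mol/L (invented default in the
# literature regime for < ~3 mM samples; generation and processing share
# whatever value the config carries, so results do not hinge on it).
DEFAULT_CAL_SLOPE = 1.2e5


@dataclass(frozen=True)
class ExperimentConfig:
    """Ground truth plus measurement-noise description of one experiment."""

    schedule: SpikeSchedule = SpikeSchedule()
    true_params: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(4.3, (4.1, 1.0))
    )
    window: float = 2.0                 # fraction collection window, min
    horizon: float = 60.0               # simulated duration, min
    n_replicates: int = 3
    baseline_mean: float = 0.49         # uS/cm, deionized feed
    baseline_sd: float = 0.06           # uS/cm
    cal_slope: float = DEFAULT_CAL_SLOPE
    replicate_sd: float = 0.06          # uS/cm, per-replicate read noise
    recovery_fraction: float = 1.0      # <1 emulates dead-space losses
    dilution_volume: float = 25.0       # mL
    n_standards: int = 6
    standard_max_conc: float = 4e-3     # mol/L, spans the diluted-sample range
    standard_noise_sd: float = 0.0      # uS/cm on calibration standards
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.window > self.horizon:
            raise ValueError("collection window longer than the simulated horizon")
        if not 0 < self.recovery_fraction <= 1:
            raise ValueError("recovery_fraction must lie in (0, 1]")
        for name in ("baseline_sd", "replicate_sd", "standard_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SyntheticExperiment:
    """Generator output: raw data plus the ground truth that produced it."""

    fractions: list[FractionRecord]
    standards: pd.DataFrame              # columns: concentration_M, conductivity_uScm
    truth_curve: RTDCurve
    truth_params: CompartmentParams
    config: ExperimentConfig


def generate_experiment(cfg: ExperimentConfig) -> SyntheticExperiment:
    """Generate fractions, calibration standards and the ground-truth curve.

    Each fraction's true concentration is the exact time average of the
    closed-form outlet over its window (flow is constant, so the time
    average equals the flow-weighted average), scaled by
    ``recovery_fraction``, virtually diluted, mapped through the true
    calibration and perturbed with independent seeded Gaussian replicate
    noise.
    """
    rng = np.random.default_rng(cfg.seed)
    sched, params = cfg.schedule, cfg.true_params

    n_win = int(np.floor(cfg.horizon / cfg.window + 1e-9))
    starts = np.arange(n_win) * cfg.window
    windows = np.column_stack([starts, starts + cfg.window])
    norm_avg = window_averaged_outlet(windows, sched, params) * cfg.recovery_fraction

    volume = sched.q_feed * cfg.window  # mL collected per window
    fractions: list[FractionRecord] = []
    for (a, b), cnorm in zip(windows, norm_avg):
        c_sample = cnorm * sched.c_mixed                    # mol/L at the outlet
        c_diluted = c_sample * volume / cfg.dilution_volume
        true_cond = cfg.baseline_mean + cfg.cal_slope * c_diluted
        reads = true_cond + rng.normal(0.0, cfg.replicate_sd, size=cfg.n_replicates)
        reads = np.maximum(reads, 0.0)
        fractions.append(FractionRecord(float(a), float(b), volume, tuple(reads)))

    conc = np.linspace(0.0, cfg.standard_max_conc, cfg.n_standards)
    cond = cfg.baseline_mean + cfg.cal_slope * conc
    cond = cond + rng.normal(0.0, cfg.standard_noise_sd, size=conc.size)
    standards = pd.DataFrame(
        {"concentration_M": conc, "conductivity_uScm": np.maximum(cond, 0.0)}
    )

    t_fine = np.linspace(0.0, cfg.horizon, max(2001, 20 * n_win + 1))
    truth = RTDCurve(t_fine, closed_form_outlet(t_fine, sched, params), meta="model")
    return SyntheticExperiment(fractions, standards, truth, params, cfg)


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write fractions.csv, standards.csv and truth.json under ``outdir``.

    The CSV dialects are the ones :mod:`spikertd.io` reads back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = exp.config

    rows = []
    for rec in exp.fractions:
        row = {
            "t_start_min": rec.t_start,
            "t_end_min": rec.t_end,
            "volume_ml": rec.volume,
        }
        for k, c in enumerate(rec.conductivities, start=1):
            row[f"cond{k}_uScm"] = c
        rows.append(row)
    fractions_path = outdir / "fractions.csv"
    pd.DataFrame(rows).to_csv(fractions_path, index=False, float_format="%.10g")

    standards_path = outdir / "standards.csv"
    exp.standards.to_csv(standards_path, index=False, float_format="%.10g")

    truth_path = outdir / "truth.json"
    truth = {
        "tau_pfr_min": exp.truth_params.tau_pfr,
        "cstr_taus_min": list(exp.truth_params.cstr_taus),
        "gamma": cfg.schedule.gamma,
        "c_mixed_M": cfg.schedule.c_mixed,
        "seed": cfg.seed,
        "config": {
            "schedule": asdict(cfg.schedule),
            "true_params": {
                "tau_pfr": cfg.true_params.tau_pfr,
                "cstr_taus": list(cfg.true_params.cstr_taus),
            },
            **{
                k: getattr(cfg, k)
                for k in (
                    "window", "horizon", "n_replicates", "baseline_mean",
                    "baseline_sd", "cal_slope", "replicate_sd",
                    "recovery_fraction", "dilution_volume", "n_standards",
                    "standard_max_conc", "standard_noise_sd", "seed",
                )
            },
        },
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"fractions": fractions_path, "standards": standards_path, "truth": truth_path}
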