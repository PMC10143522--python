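#!/usr/bin/env python
"""Fit the PFR-2CSTR space times to the synthetic RTD curves.

Processes the fraction files written by 01_simulate_experiments.py through
the calibration-dilution-normalization chain, jointly fits one shared
(tau_pfr, tau1, tau2) to all three spiking durations, and compares the
estimates with the generator truth.  Writes results/fit/fit.json and an
overlay plot of data vs model.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from spikertd.compartment import SpikeSchedule, closed_form_outlet
from spikertd.fitting import fit_compartments
from spikertd.io import read_fractions, read_standards
from spikertd.measurement import fit_calibration, process_fractions

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "fit")
    parser.add_argument("--bootstrap", type=int, default=200)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    durations = (1.0, 5.0, 40.0)
    cal = fit_calibration(read_standards(args.data / "tspike_1" / "standards.csv"))
    print(f"Calibration: slope={cal.slope:.4g} uS/cm per M, "
          f"intercept={cal.intercept:.3f} uS/cm, residual sd={cal.residual_sd:.3g}")

    curves = []
    for ts in durations:
        schedule = SpikeSchedule(t_spike=ts)
        records = read_fractions(args.data / f"tspike_{ts:g}" / "fractions.csv")
        curves.append((process_fractions(records, cal, 25.0, schedule), schedule))

    fit = fit_compartments(curves, bootstrap=args.bootstrap, seed=args.seed)
    p = fit.params
    print(f"Joint fit: tau_pfr={p.tau_pfr:.3f} min, "
          f"tau1={p.cstr_taus[0]:.3f} min, tau2={p.cstr_taus[1]:.3f} min")
    print(f"Per-curve RMSE: "
          + ", ".join(f"t_spike={ts:g}: {r:.4f}" for ts, r in zip(durations, fit.per_curve_rmse)))
    if fit.bootstrap_intervals:
        for name, (lo, hi) in fit.bootstrap_intervals.items():
            print(f"  {name}: 95% bootstrap interval [{lo:.3f}, {hi:.3f}] min")

    args.out.mkdir(parents=True, exist_ok=True)
    report = fit.as_dict()
    report["calibration"] = {"slope": cal.slope, "intercept": cal.intercept,
                             "residual_sd": cal.residual_sd}
    (args.out / "fit.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = np.linspace(0, 60, 2000)
    for (curve, schedule), color in zip(curves, ("C0", "C1", "C2")):
        ax.plot(curve.times, curve.values, "o", ms=4, color=color,
                label=f"data, $t_{{spike}}$={schedule.t_spike:g} min")
        ax.plot(t, closed_form_outlet(t, schedule, p), "-", color=color, lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(r"$c_{out}/(\gamma c_{spike})$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(args.out / "rtd_fit.png", dpi=150)
    print(f"Wrote {args.out / 'fit.json'} and rtd_fit.png")


if __name__ == "__main__":
    main()
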