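# spikertd

Residence-time-distribution (RTD) analysis of a transient inline spiking
system for continuous biomanufacturing.

## The problem

To validate a virus-filtration step in continuous operation, a tracer or
virus spike is injected inline upstream of the filter for a finite duration
`t_spike`. The spike does not arrive at the filter as the clean rectangle
that was injected: tubing delays it, and the static mixer and filter holder
disperse it, so the outlet breakthrough curve spans far longer than
`t_spike` (band broadening). Interpreting such experiments requires a
quantitative model of the train's RTD.

This package analyzes a lab-scale train — syringe spike (1 M NaCl at 1/10
of a 0.41 mL/min feed) → static mixer → 25 mm filter holder with a single
nylon membrane — in which the outlet is characterized by collecting timed
effluent fractions and reading their conductivity.

## The model

The train is reduced to a plug-flow reactor (PFR) in series with two
continuous stirred tanks (CSTRs). The inlet is the rectangle
`c_in(t) = γ·c_spike` for `0 ≤ t ≤ t_spike` (spiking ratio
`γ = q_spike/(q_feed + q_spike) = 0.1/1.1`), the PFR is a pure delay
`τ_PFR`, and each CSTR obeys `τ_i dc_i/dt = c_{i-1} − c_i`. The normalized
outlet has the closed form

```
c_out/(γ c_spike) = S(t − τ_PFR) − S(t − τ_PFR − t_spike)
S(x) = [1 − (τ₁ e^{−x/τ₁} − τ₂ e^{−x/τ₂})/(τ₁ − τ₂)] · H(x),   H(0) = 0
```

with the repeated-root form `1 − (1 + x/τ)e^{−x/τ}` when `τ₁ = τ₂`.
With space times `(τ_PFR, τ₁, τ₂) = (4.3, 4.1, 1.0)` min this reproduces
the bench observations: onset at 4.3 min, a peak of ≈0.6 near 10 min for a
5-min spike, and a plateau of 1 for a 40-min spike.

Around the model the package provides:

- `spikertd.measurement` — calibration, dilution and normalization of
  fraction conductivities into RTD curves;
- `spikertd.synthetic` — a seeded generator of complete synthetic
  experiments (fractions, calibration standards, ground truth);
- `spikertd.fitting` — joint least-squares estimation of the space times
  across spiking durations;
- `spikertd.holdup` — bookkeeping of measured holdup times and their
  comparison with fitted space times;
- `spikertd.hydraulics` — Darcy transmembrane pressure and Reynolds
  numbers;
- `spikertd.holder` — a reduced axisymmetric Stokes–Brinkman simulation of
  flow, tracer transport and particle trajectories in the filter holder.

## Worked example

Generate synthetic experiments at the three spiking durations and recover
the space times:

```sh
python analysis/01_simulate_experiments.py
python analysis/02_fit_space_times.py
```

```
Joint fit: tau_pfr=4.301 min, tau1=4.100 min, tau2=0.999 min
Per-curve RMSE: t_spike=1: 0.0001, t_spike=5: 0.0001, t_spike=40: 0.0001
```

The fit recovers the generator truth (4.3, 4.1, 1.0 min) from conductivity
data with realistic replicate noise. The holdup audit and hydraulics:

```sh
python analysis/03_holdup_audit.py
python analysis/04_membrane_hydraulics.py
```

```
Tubing holdup total:        2.30 +/- 0.10 min (linear sd)
Mixer + holder holdup:      3.23 +/- 0.86 min (linear sd)
tubing < tau_pfr (4.30):   True (margin 2.00 min)
mixer+holder < tau1 (4.10): True (margin 0.87 min)
mixer+holder > tau2 (1.00): True (margin 2.23 min)
Darcy transmembrane pressure:        1366 Pa (measured on the bench: ~1380 Pa)
```

The reduced filter-holder simulation (64×64 grid):

```sh
python analysis/05_filter_holder_simulation.py
```

```
Flow (64x64): Q_in=6.227e-09 m^3/s, membrane dP=1363 Pa (Darcy at mean flux: 1363 Pa), downstream p=0.11 Pa
t_spike=   1 min: outlet peak 0.537, mass closure 9.23e-14
  PFR-2CSTR fit of the simulated curve: tau_pfr=2.78, tau1=1.25, tau2=0.04 min, RMSE=0.0029
t_spike=  40 min: outlet peak 0.999, mass closure 1.06e-12
Particles (5000, seed 11): 98% exited; median exit 0.36 min (inner membrane third) vs 2.04 min (outer third); flux-weighted mean 1.36 min vs V/Q 1.38 min
```

A short spike leaves the holder unsaturated (peak < 1); a long spike
saturates it (plateau ≈ 1); tracers crossing the membrane near the axis
exit much sooner than those crossing near the rim; and the simulated
breakthrough is captured by the PFR-2CSTR form (RMSE 0.003).

The same functionality is exposed as a CLI (`spikertd simulate|fit|metrics|
holdup|hydraulics|holder-sim|report`).

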