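# Methods

## Compartment model

The process train is reduced to one plug-flow reactor (PFR) followed by two
continuous stirred tanks (CSTRs) in series. The PFR is a pure transport
delay of space time `τ_PFR`; each CSTR obeys the mass balance
`τ_i dc_i/dt = c_{i-1} − c_i` with zero initial concentration. The input is
a rectangle of height `γ·c_spike` and duration `t_spike`, where
`γ = q_spike/(q_feed + q_spike)` is the spiking ratio (0.1/1.1 at the
default operating point: 0.41 mL/min feed, 0.041 mL/min spike).

The closed-form outlet is the superposition of the cascade step response
switched on at `τ_PFR` and off at `τ_PFR + t_spike`. A formulation choice
matters here: gating *un-shifted* exponentials `e^{−t/τ}` with
`H(t − τ_PFR)` produces a jump at `t = τ_PFR`, which is unphysical for a
transport delay. This implementation therefore runs the exponentials on the
shifted time `t − τ_PFR`, making the response continuous and exactly zero
through the delay. The shifted form reproduces every qualitative and
quantitative feature used for validation (onset at 4.3 min, peak ≈0.6 near
10 min for a 5-min spike, plateau 1 for a 40-min spike). When `τ₁ = τ₂`
(relative difference below 1e-9) the closed form switches to the
repeated-root expression `1 − (1 + x/τ)e^{−x/τ}` rather than failing on the
removable singularity. The Heaviside convention is `H(0) = 0`. The swap
symmetry `τ₁ ↔ τ₂` is resolved by reporting in non-increasing order.

`cascade_response` is the numeric companion for arbitrary bounded inputs
and any number of CSTRs: per substep it applies the exact exponential
update for a linear-in-time stage input (exact for piecewise-constant
inputs), with substeps ≤ 1e-3 min by default and endpoint samples nudged
into the substep interior so one-sided limits are taken at input
discontinuities. Closed form and numeric path agree to better than 1e-6 in
sup norm, and both are checked in the tests against an independent
piecewise-RK4 integration of the stage ODEs.

Exact window averages of the outlet use the analytic antiderivative of the
step response; this is what a collected fraction measures under constant
outlet flow, and it is what the fitter compares against window-tagged data.

Internal units for this layer are minutes and mol/L.

## Measurement chain

Fractions (default: 2-min windows, ≈0.82 mL at the 0.41 mL/min feed) are
diluted to 25 mL, read in triplicate, and averaged arithmetically. A linear
concentration–conductivity calibration (ordinary least squares over
standards) inverts the readings; diluted samples sit below ~3 mM NaCl,
where the response is near-linear, so no higher-order calibration is
offered. The recovered concentration is scaled by the dilution factor and
normalized by `γ·c_spike`. Fraction timestamps default to window midpoints
(unbiased for slowly varying curves); start/end conventions are selectable.
Negative inverted concentrations are clipped to zero with a logged warning,
and fractions whose replicates all fall more than 3 residual-sd below the
calibration intercept are flagged but not dropped.

## Synthetic experiments

The generator emulates the bench protocol: exact window-averaged model
concentrations (optionally scaled by a recovery fraction < 1 to mimic
dead-space losses; 0.97 reproduces the observed experimental plateau),
virtual dilution, mapping through the true calibration, and additive
Gaussian replicate noise on conductivity. Defaults are the bench
conditions: baseline 0.49 ± 0.06 μS/cm, triplicate reads, replicate sd
equal to the baseline sd (the only dispersion reported for the instrument),
calibration slope 1.2e5 μS/cm per mol/L (a dilute-NaCl literature-regime
value; generation and processing share whatever slope the config carries,
so no result depends on it). The noiseless component is seed-invariant;
seeds move only the noise draws, and outputs are byte-identical for a fixed
seed.

What the generator does *not* emulate: pump pulsation (far faster than the
2-min collection window), temperature drift of conductivity, solute
retention or adsorption, and flow-rate variation during the spike (the
collected volume uses the feed rate alone, matching the ≈0.8 mL/2 min
bookkeeping). Passing tests on synthetic data therefore demonstrate
correctness of the analysis chain under these idealizations, not robustness
to every bench artifact.

## Space-time fitting

The fit minimizes unweighted summed squared residuals between the
closed-form outlet (window-averaged where the data carry windows) and one
or more curves jointly, sharing a single parameter set across spiking
durations — the physical constraint that the train does not change between
runs. The solver is SciPy's bounded trust-region least squares, multi-started
from a deterministic grid (`τ_PFR ∈ {1..6}` min, CSTR taus from a series
first-moment heuristic split 2:1), with the best final cost kept and
canonical ordering applied afterwards. CSTR taus are bounded below by 1e-6
min to keep the closed form well posed. Optional residual-resampling
bootstrap intervals (percentile, seeded) are clearly artifact-derived —
they quantify noise propagation through this procedure, not any reported
experimental uncertainty.

On noiseless synthetic triplets the fit recovers the generator space times
to < 1e-4 min; at the default noise the median absolute error per space
time over 50 seeds is ~1e-3 min.

## Holdup audit

Holdup sums default to linear addition of standard deviations, which is the
bookkeeping convention consistent with the recorded totals
(2.30 ± 0.10 min for tubing, 3.23 ± 0.86 min for mixer + holder); quadrature
(0.07 min for tubing) is available as the statistically conventional
alternative. The audit checks three orderings against the fitted space
times: tubing < τ_PFR (part of the mixer/holder volume also acts as plug
flow), mixer+holder < τ₁, mixer+holder > τ₂.

## Hydraulics

SI units. Constant fluid properties (ρ = 997.5 kg/m³, μ = 0.898 mPa·s at
0.1 M and 25 °C, D = 1.68e-9 m²/s) — concentration-dependent corrections
are deliberately out of scope. Darcy slab law `ΔP = μ u h_m/κ` with
κ = 1.27e-15 m², h_m = 140 μm. Spreading the holder inlet flow
(ū = 4.3e-4 m/s through a 4.3 mm port) uniformly over the 24 mm membrane
gives ΔP ≈ 1366 Pa, within ~1% of the measured ≈1380 Pa. Reynolds numbers
computed from these constant properties are ≈2.0–2.05 at the mixer and
holder inlets; previously reported ranges of 1.84–1.94 require
concentration-dependent properties and are not forced.

## Filter-holder simulation

Geometry: a flat cylindrical cassette — inlet port (4.3 mm) → upstream
chamber → membrane disc (24 mm × 140 μm) → downstream chamber → outlet port
(2.3 mm) on the axis. Internal chamber contours are not published; the
default heights (0.5 mm each) are set so the modeled holder volume matches
the measured holdup volume (≈1.05 min × 0.41 mL/min ≈ 0.43 mL). Absolute
simulated time constants are therefore approximate by construction, and the
simulation is read for regimes and orderings, not exact times.

Flow: steady axisymmetric creeping flow with a unified Brinkman
formulation — one Stokes momentum equation with Darcy drag `μ u/κ` active
in the membrane band and zero elsewhere (drag omitted entirely in open
cells rather than using a large finite permeability). Inertia is dropped
(Re ≈ 2). Discretization is a staggered MAC finite-volume grid (default
64×64, uniform spacing); the membrane band is the run of cell rows covering
its thickness (≥2 rows), with the permeability rescaled by
(band thickness)/(true thickness) so the total Darcy resistance is exact on
any grid. Boundary conditions: parabolic inlet profile, p = 0 with
zero-gradient velocity on the outlet port, no slip elsewhere, symmetry on
the axis. The sparse system is row-equilibrated and solved directly; the
scaled residual must be < 1e-5 (it is ~1e-10 in practice). Discrete
continuity then holds to machine precision, so inlet, membrane and outlet
flows agree exactly, the membrane pressure jump reproduces the Darcy value
at the mean flux, and the downstream pressure is ≈0.1 Pa against a ≈1363 Pa
transmembrane drop.

Transport: explicit finite-volume first-order upwind advection plus central
diffusion on the same grid, time step from the cell-wise stability bound
(outflux + diffusive conductance) with a 0.5 safety factor; an explicit
over-large step raises before stepping. The inlet carries `γ·c_spike`
during the spike and clean feed otherwise; diffusive flux is zero on all
boundaries; the scheme is conservative by construction (mass closure
~1e-13 relative). Upwind monotonicity keeps concentrations within
[0, γ·c_spike]. First-order upwind introduces numerical diffusion; at
64×64 the RTD peak changes by < 0.3% against 32×32, which stands in for a
formal mesh-convergence study. The membrane band is advected at porosity 1
(its pore volume is ~12% of the modeled total; the RTD is dominated by the
chambers).

Particles: massless tracers, `dq/dt = u`, classical RK4 with clamped
bilinear interpolation of the staggered velocities (dt = 0.05 s, cap 1800
s). Release positions are uniform by inlet area; each particle also carries
a weight proportional to the local inlet velocity, because the
mean-residence-time identity `t̄ = V/Q` holds for flux-weighted injection
(flux-weighted mean exit 1.36 min vs V/Q = 1.38 min; the unweighted mean is
~2× larger since area-uniform release oversamples the slow near-wall
streamlines).

The arrival delay of the mixed stream at the holder inlet, `t0` (default
2.7 min), is a free alignment parameter for composing the simulated RTD
with the upstream train; no mechanistic account of its value is attempted.
Composed with that delay, the simulated breakthrough is fit by the
PFR-2CSTR model with RMSE ≈ 0.003, connecting the simulation back to the
compartment model.

Out of scope: the 3-D static-mixer flow (the holder inlet simply carries
the completely mixed concentration, which is the mixer's validated job),
membrane compression and fouling, and turbulence (meaningless at Re ≈ 2).

## Problem sizes and determinism

Default analysis sizes: 60-min horizons with 2-min windows (30 fractions
per curve); 50-seed Monte-Carlo recovery studies; 64×64 holder grid with
8–14 min simulated horizons; 5000 particles. All stochastic components
(replicate noise, standards noise, bootstrap, particle release) are driven
by explicit seeds through `numpy.random.default_rng`.

## Known limitations

- The compartment model treats an inert, fully recovered tracer; retention,
  adsorption and dead-space losses enter only through the generator's
  recovery fraction.
- Linear calibration is assumed; strongly concentrated samples would need a
  nonlinear conductivity model.
- The holder geometry's unpublished internals make simulated absolute time
  constants indicative only.
- τ_PFR trades off against CSTR taus on coarse grids; the multi-start grid
  and joint fitting across spiking durations mitigate but cannot eliminate
  this for single short-spike curves.
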