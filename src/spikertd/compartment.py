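"""PFR-2CSTR compartment model of a transient inline spiking system.

The process train (tubing -> static mixer -> filter holder -> tubing) is
reduced to a plug-flow reactor (pure transport delay, space time ``tau_pfr``)
followed by a cascade of continuous stirred-tank reactors (space times
``cstr_taus``).  A rectangular salt spike of duration ``t_spike`` enters at
the completely mixed concentration ``gamma * c_spike`` where the spiking
ratio ``gamma = q_spike / (q_feed + q_spike)``.

All concentrations handled here are normalized by ``gamma * c_spike`` unless
stated otherwise; internal units are minutes and mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpikeSchedule",
    "CompartmentParams",
    "RTDCurve",
    "RTDMetrics",
    "DegenerateCascadeError",
    "UndefinedMetricsError",
    "rect_input",
    "closed_form_outlet",
    "outlet_cumulative",
    "window_averaged_outlet",
    "cascade_response",
    "rtd_metrics",
]

# Relative tolerance below which two CSTR space times are treated as a
# repeated root of the cascade transfer function.
_REPEATED_ROOT_RTOL = 1e-9


class DegenerateCascadeError(ValueError):
    """Raised when a closed-form evaluation is requested for an unsupported
    cascade configuration (e.g. more than two CSTRs)."""


class UndefinedMetricsError(ValueError):
    """Raised when RTD summary metrics are requested for an all-zero curve."""


@dataclass(frozen=True)
class SpikeSchedule:
    """Rectangular spike input definition.

    Parameters
    ----------
    c_spike : float
        Concentration of the spiking solution (mol/L).
    q_feed : float
        Feed volumetric flow rate (mL/min).
    q_spike : float
        Spike volumetric flow rate (mL/min).
    t_spike : float
        Spiking duration (min).
    """

    c_spike: float = 1.0
    q_feed: float = 0.41
    q_spike: float = 0.041
    t_spike: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_spike", "q_feed", "q_spike", "t_spike"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def gamma(self) -> float:
        """Spiking ratio: spike flow over total flow, in (0, 1)."""
        return self.q_spike / (self.q_feed + self.q_spike)

    @property
    def c_mixed(self) -> float:
        """Concentration of the completely mixed stream, ``gamma * c_spike``."""
        return self.gamma * self.c_spike


@dataclass(frozen=True)
class CompartmentParams:
    """Space times of the reduced PFR + CSTR-cascade process model (min)."""

    tau_pfr: float
    cstr_taus: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cstr_taus", tuple(float(t) for t in self.cstr_taus))
        if self.tau_pfr < 0:
            raise ValueError("tau_pfr must be >= 0")
        if len(self.cstr_taus) < 1:
            raise ValueError("at least one CSTR space time is required")
        if any(t < 0 for t in self.cstr_taus):
            raise ValueError("CSTR space times must be >= 0")

    def canonical(self) -> "CompartmentParams":
        """Return params with CSTR taus sorted non-increasing.

        The cascade response is invariant under permutation of the CSTR
        space times; the non-increasing order is the reporting convention.
        """
        return CompartmentParams(self.tau_pfr, tuple(sorted(self.cstr_taus, reverse=True)))

    @property
    def total_time(self) -> float:
        """Sum of all space times: the mean residence time of the train."""
        return self.tau_pfr + float(sum(self.cstr_taus))


@dataclass
class RTDCurve:
    """Time-stamped normalized outlet concentrations ``cout / (gamma*c_spike)``.

    ``windows`` (optional, shape ``(n, 2)``) records the collection window of
    each point when the curve was reconstructed from collected fractions;
    downstream fitting then compares window-averaged model values.
    """

    times: np.ndarray
    values: np.ndarray
    meta: str = "model"
    windows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < -1e-9):
            raise ValueError("normalized concentrations must be >= 0")
        if self.windows is not None:
            self.windows = np.asarray(self.windows, dtype=float)
            if self.windows.shape != (self.times.size, 2):
                raise ValueError("windows must have shape (n, 2)")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RTDMetrics:
    """Summary descriptors of an RTD curve (times in min)."""

    onset_time: float
    peak_time: float
    peak_value: float
    area: float
    mean_time: float
    variance: float
    span: float


def rect_input(t, schedule: SpikeSchedule):
    """Rectangular inlet concentration (mol/L) of the spiked stream.

    Equals ``gamma * c_spike`` for ``0 <= t <= t_spike`` (closed interval)
    and 0 afterwards.  Negative times are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = np.where(t_arr <= schedule.t_spike, schedule.c_mixed, 0.0)
    return out if t_arr.ndim else float(out)


def _step_response(tp: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    """Normalized response of the CSTR cascade to a unit step at t=0.

    ``tp`` is time measured from the step (already PFR-shifted).  Uses the
    two-exponential form for distinct space times, the repeated-root form
    ``1 - (1 + t/tau) exp(-t/tau)`` when they coincide, and degenerates to
    the pure step / single-exponential when space times vanish.
    Heaviside convention H(0) = 0: the response is 0 for tp <= 0.
    """
    tp = np.asarray(tp, dtype=float)
    active = tp > 0
    x = np.where(active, tp, 0.0)
    if len(taus) == 1:
        (t1,) = taus
        resp = 1.0 - np.exp(-x / t1) if t1 > 0 else np.ones_like(x)
    elif len(taus) == 2:
        t1, t2 = taus
        if t1 == 0 and t2 == 0:
            resp = np.ones_like(x)
        elif min(t1, t2) == 0:
            tau = max(t1, t2)
            resp = 1.0 - np.exp(-x / tau)
        elif abs(t1 - t2) <= _REPEATED_ROOT_RTOL * max(t1, t2):
            tau = 0.5 * (t1 + t2)
            resp = 1.0 - (1.0 + x / tau) * np.exp(-x / tau)
        else:
            resp = 1.0 - (t1 * np.exp(-x / t1) - t2 * np.exp(-x / t2)) / (t1 - t2)
    else:
        raise DegenerateCascadeError(
            "closed form is implemented for 1 or 2 CSTRs; "
            "use cascade_response for longer cascades"
        )
    return np.where(active, resp, 0.0)


def _step_response_integral(tp: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    """Running integral of :func:`_step_response` from 0 to ``tp``."""
    tp = np.asarray(tp, dtype=float)
    active = tp > 0
    x = np.where(active, tp, 0.0)
    if len(taus) == 1:
        (t1,) = taus
        integ = x + t1 * np.exp(-x / t1) - t1 if t1 > 0 else x
    elif len(taus) == 2:
        t1, t2 = taus
        if t1 == 0 and t2 == 0:
            integ = x
        elif min(t1, t2) == 0:
            tau = max(t1, t2)
            integ = x + tau * np.exp(-x / tau) - tau
        elif abs(t1 - t2) <= _REPEATED_ROOT_RTOL * max(t1, t2):
            tau = 0.5 * (t1 + t2)
            integ = x + (x + 2.0 * tau) * np.exp(-x / tau) - 2.0 * tau
        else:
            integ = (
                x
                + (t1**2 * np.exp(-x / t1) - t2**2 * np.exp(-x / t2)) / (t1 - t2)
                - (t1 + t2)
            )
    else:
        raise DegenerateCascadeError("closed form is implemented for 1 or 2 CSTRs")
    return np.where(active, integ, 0.0)


def closed_form_outlet(t, schedule: SpikeSchedule, params: CompartmentParams):
    """Closed-form normalized outlet concentration ``cout / (gamma*c_spike)``.

    Superposition of the cascade step response switched on at ``tau_pfr``
    and off at ``tau_pfr + t_spike``; the PFR acts as a pure transport
    delay, so the exponentials run on the shifted time ``t - tau_pfr`` and
    the response is continuous and exactly 0 for ``t <= tau_pfr``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    taus = params.cstr_taus
    up = _step_response(t_arr - params.tau_pfr, taus)
    down = _step_response(t_arr - params.tau_pfr - schedule.t_spike, taus)
    out = up - down
    return out if t_arr.ndim else float(out)


def outlet_cumulative(t, schedule: SpikeSchedule, params: CompartmentParams):
    """Running integral of :func:`closed_form_outlet` from 0 to ``t`` (min)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    taus = params.cstr_taus
    up = _step_response_integral(t_arr - params.tau_pfr, taus)
    down = _step_response_integral(t_arr - params.tau_pfr - schedule.t_spike, taus)
    out = up - down
    return out if t_arr.ndim else float(out)


def window_averaged_outlet(
    windows: np.ndarray, schedule: SpikeSchedule, params: CompartmentParams
) -> np.ndarray:
    """Mean of the closed-form outlet over collection windows ``(start, end)``.

    Exact (analytic antiderivative); this is what a collected fraction
    measures for a constant outlet flow.
    """
    windows = np.asarray(windows, dtype=float)
    a, b = windows[:, 0], windows[:, 1]
    if np.any(b <= a):
        raise ValueError("window end must exceed window start")
    return (
        outlet_cumulative(b, schedule, params) - outlet_cumulative(a, schedule, params)
    ) / (b - a)


def cascade_response(
    input_fn: Callable[[float], float],
    params: CompartmentParams,
    t_grid: np.ndarray,
    dt_max: float = 1e-3,
    normalize_by: float = 1.0,
    meta: str = "model",
) -> RTDCurve:
    """Numerically propagate an arbitrary bounded input through the train.

    The PFR shifts the input by ``tau_pfr``; each CSTR obeys
    ``tau_i dc_i/dt = c_{i-1} - c_i`` with zero initial concentrations.
    Integration uses an exact exponential update per substep assuming the
    stage input is linear across the substep (exact for piecewise-constant
    inputs sampled inside smooth segments), with substeps no longer than
    ``dt_max`` minutes.

    Returns an :class:`RTDCurve` with values divided by ``normalize_by``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")

    def delayed(t: float) -> float:
        td = t - params.tau_pfr
        v = float(input_fn(td)) if td >= 0 else 0.0
        if not np.isfinite(v):
            raise ValueError(f"input function returned non-finite value at t={t:g}")
        return v

    taus = params.cstr_taus
    n_stage = len(taus)
    state = np.zeros(n_stage)
    out = np.empty_like(t_grid)
    out[0] = state[-1] if t_grid[0] > 0 else 0.0
    if t_grid[0] > 0:
        # integrate quietly from 0 to the first grid point
        _integrate_segment(delayed, taus, state, 0.0, t_grid[0], dt_max)
        out[0] = state[-1]
    for k in range(1, t_grid.size):
        _integrate_segment(delayed, taus, state, t_grid[k - 1], t_grid[k], dt_max)
        out[k] = state[-1]
    return RTDCurve(t_grid, np.maximum(out / normalize_by, 0.0), meta=meta)


def _integrate_segment(
    u_fn: Callable[[float], float],
    taus: tuple[float, ...],
    state: np.ndarray,
    a: float,
    b: float,
    dt_max: float,
) -> None:
    """Advance the cascade state from time a to b in place."""
    n_sub = max(1, int(np.ceil((b - a) / dt_max)))
    edges = np.linspace(a, b, n_sub + 1)
    # Nudge endpoint samples into the interior of each substep so one-sided
    # limits are used at input discontinuities (rectangular spike edges).
    eps = (b - a) / n_sub * 1e-9
    for s in range(n_sub):
        ta, tb = edges[s], edges[s + 1]
        h = tb - ta
        ua, ub = u_fn(ta + eps), u_fn(tb - eps)
        for i, tau in enumerate(taus):
            ca = state[i]
            if tau <= 0:
                state[i] = ub
            else:
                slope = (ub - ua) / h
                state[i] = ub - slope * tau + (ca - ua + slope * tau) * np.exp(-h / tau)
            # this stage's endpoint values feed the next stage
            ua, ub = ca, state[i]


def rtd_metrics(curve: RTDCurve, threshold: float = 0.01) -> RTDMetrics:
    """Summary metrics of an RTD curve.

    ``onset_time`` is the (interpolated) first crossing of
    ``threshold * max(value)``; ``peak_time``/``peak_value`` come from the
    grid argmax with local quadratic refinement; ``area``, ``mean_time`` and
    ``variance`` are trapezoidal moments; ``span`` is the total measure of
    ``{t : value > threshold}`` (absolute threshold on the normalized curve).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    t, v = curve.times, curve.values
    if t.size < 3:
        raise UndefinedMetricsError("curve too short for metrics")
    vmax = float(v.max())
    if vmax <= 0:
        raise UndefinedMetricsError("metrics are undefined for an all-zero curve")

    # onset: first upward crossing of threshold * max
    level = threshold * vmax
    above = v > level
    k = int(np.argmax(above))
    if k == 0:
        onset = float(t[0])
    else:
        t0, t1v, v0, v1 = t[k - 1], t[k], v[k - 1], v[k]
        onset = float(t0 + (level - v0) / (v1 - v0) * (t1v - t0))

    # peak: argmax with quadratic refinement through the three bracketing samples
    i = int(np.argmax(v))
    if 0 < i < t.size - 1 and (v[i - 1] - 2 * v[i] + v[i + 1]) < 0:
        denom = v[i - 1] - 2 * v[i] + v[i + 1]
        delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        dt_local = 0.5 * (t[min(i + 1, t.size - 1)] - t[max(i - 1, 0)])
        peak_time = float(t[i] + delta * dt_local)
        peak_value = float(v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta)
    else:
        peak_time, peak_value = float(t[i]), float(v[i])

    area = float(np.trapezoid(v, t))
    mean = float(np.trapezoid(t * v, t) / area)
    var = float(np.trapezoid((t - mean) ** 2 * v, t) / area)

    above_abs = v > threshold
    span = float(np.trapezoid(above_abs.astype(float), t))
    return RTDMetrics(onset, peak_time, peak_value, area, mean, var, span)
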