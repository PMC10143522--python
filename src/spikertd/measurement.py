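"""Reconstruction of normalized RTD curves from fraction-collection data.

Effluent is collected in timed fractions (~0.8 mL every 2 min at the 0.41
mL/min feed), each diluted to a fixed volume (25 mL) so a conductivity probe
fits, and read in replicate.  A linear NaCl concentration-conductivity
calibration inverts the readings; the dilution factor and the completely
mixed concentration ``gamma * c_spike`` then normalize each fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .compartment import RTDCurve, SpikeSchedule

__all__ = [
    "CalibrationCurve",
    "FractionRecord",
    "CalibrationError",
    "fit_calibration",
    "process_fractions",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the calibration standards cannot support a line fit."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear concentration -> conductivity map.

    conductivity [uS/cm] = slope [uS/cm per mol/L] * concentration [mol/L]
                           + intercept [uS/cm]
    """

    slope: float
    intercept: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.intercept < 0:
            raise ValueError("calibration intercept must be >= 0")

    def to_conductivity(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def to_concentration(self, conductivity):
        return (np.asarray(conductivity, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class FractionRecord:
    """One collected effluent fraction.

    ``conductivities`` are replicate readings (uS/cm) of the sample after
    dilution; the collection window is ``[t_start, t_end]`` minutes and
    ``volume`` (mL) is the undiluted collected volume.
    """

    t_start: float
    t_end: float
    volume: float
    conductivities: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conductivities", tuple(float(c) for c in self.conductivities)
        )
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if len(self.conductivities) < 1:
            raise ValueError("at least one conductivity replicate is required")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    @property
    def mean_conductivity(self) -> float:
        return float(np.mean(self.conductivities))


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, conductivity) pairs.

    Requires at least two distinct concentrations.  ``residual_sd`` is the
    root-mean-square residual with n-2 degrees of freedom (0 for two points
    or an exact fit).
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need at least two (concentration, conductivity) pairs")
    conc, cond = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise CalibrationError("standards are rank deficient: one distinct concentration")
    res = stats.linregress(conc, cond)
    n = conc.size
    resid = cond - (res.intercept + res.slope * conc)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(float(res.slope), float(max(res.intercept, 0.0)), residual_sd)


def process_fractions(
    records: Sequence[FractionRecord],
    cal: CalibrationCurve,
    dilution_volume: float,
    schedule: SpikeSchedule,
    timestamp: str = "midpoint",
) -> RTDCurve:
    """Convert collected fractions into a normalized RTD curve.

    Per fraction: average the replicates, invert the calibration to the
    diluted concentration, multiply by the dilution factor
    ``dilution_volume / volume``, and divide by ``gamma * c_spike``.
    Fractions whose replicates all read more than ``3 * residual_sd`` below
    the calibration intercept are flagged (logged), not fatal; negative
    inverted concentrations are clipped to zero with a warning.

    ``timestamp`` selects the reported time per fraction: "midpoint"
    (default), "start" or "end".
    """
    if timestamp not in ("midpoint", "start", "end"):
        raise ValueError("timestamp must be 'midpoint', 'start' or 'end'")
    if not records:
        raise ValueError("no fraction records given")
    recs = sorted(records, key=lambda r: r.t_start)
    for prev, cur in zip(recs, recs[1:]):
        if cur.t_start < prev.t_end - 1e-9:
            raise ValueError(
                f"fractions overlap: [{prev.t_start}, {prev.t_end}] and "
                f"[{cur.t_start}, {cur.t_end}]"
            )
    if dilution_volume < max(r.volume for r in recs):
        raise ValueError("dilution_volume must be >= every fraction volume")

    times, values, windows = [], [], []
    for rec in recs:
        reads = np.asarray(rec.conductivities)
        if np.all(reads < cal.intercept - 3.0 * cal.residual_sd):
            logger.warning(
                "fraction [%g, %g] min: all replicates more than 3 sd below the "
                "calibration intercept", rec.t_start, rec.t_end,
            )
        c_diluted = float(cal.to_concentration(rec.mean_conductivity))
        c_sample = c_diluted * dilution_volume / rec.volume
        norm = c_sample / schedule.c_mixed
        if norm < 0:
            logger.warning(
                "fraction [%g, %g] min: negative inverted concentration %.3g "
                "clipped to 0", rec.t_start, rec.t_end, norm,
            )
            norm = 0.0
        t = {"midpoint": rec.midpoint, "start": rec.t_start, "end": rec.t_end}[timestamp]
        times.append(t)
        values.append(norm)
        windows.append((rec.t_start, rec.t_end))
    return RTDCurve(
        np.asarray(times), np.asarray(values), meta="measured",
        windows=np.asarray(windows),
    )
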