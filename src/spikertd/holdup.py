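"""Holdup-time bookkeeping for the inline spiking train.

Holdup times are measured transit times of fluid through physical intervals
of the process (tubing runs, the static mixer, the filter holder), obtained
by emptying the train and timing the front at a constant 0.41 mL/min feed.
Summed per category they are compared against the fitted space times: the
tubing total should fall below the plug-flow space time (part of the mixer
and holder volume also acts as plug flow), while the mixer+holder total
should land between the two stirred-tank space times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .compartment import CompartmentParams

__all__ = [
    "HoldupInterval",
    "HoldupAudit",
    "MEASURED_HOLDUP",
    "sum_holdup",
    "compare_spacetimes",
]


@dataclass(frozen=True)
class HoldupInterval:
    """Measured holdup of one physical interval (minutes, mean +/- sd)."""

    label: str
    mean: float
    sd: float
    category: str  # "tubing" | "mixer" | "holder"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("holdup mean must be > 0")
        if self.sd < 0:
            raise ValueError("holdup sd must be >= 0")
        if self.category not in ("tubing", "mixer", "holder"):
            raise ValueError(f"unknown category {self.category!r}")


# Bench measurements for the lab-scale train (five intervals along the flow
# path: three tubing runs, the static mixer, and the filter holder).
MEASURED_HOLDUP: tuple[HoldupInterval, ...] = (
    HoldupInterval("spiking station -> static mixer", 0.98, 0.02, "tubing"),
    HoldupInterval("static mixer", 2.18, 0.29, "mixer"),
    HoldupInterval("static mixer -> filter holder", 0.98, 0.07, "tubing"),
    HoldupInterval("filter holder", 1.05, 0.57, "holder"),
    HoldupInterval("filter holder -> collection tube", 0.34, 0.01, "tubing"),
)


def sum_holdup(
    intervals: Sequence[HoldupInterval], mode: str = "linear"
) -> tuple[float, float]:
    """Total (mean, sd) over intervals.

    ``mode="linear"`` adds standard deviations arithmetically (the bench
    bookkeeping convention used with these tables); ``mode="quadrature"``
    adds them in quadrature, the convention for independent errors.
    """
    if not intervals:
        raise ValueError("no holdup intervals given")
    means = np.array([iv.mean for iv in intervals])
    sds = np.array([iv.sd for iv in intervals])
    if mode == "linear":
        sd = float(sds.sum())
    elif mode == "quadrature":
        sd = float(np.sqrt(np.sum(sds**2)))
    else:
        raise ValueError("mode must be 'linear' or 'quadrature'")
    return float(means.sum()), sd


@dataclass(frozen=True)
class HoldupAudit:
    """Comparison of summed holdups against fitted space times (minutes).

    The three findings mirror the physical reading of the compartment model:
    tubing alone underfills the plug-flow space time, and the mixer+holder
    holdup sits between the two stirred-tank space times.
    """

    tubing_total: float
    tubing_sd: float
    mixer_holder_total: float
    mixer_holder_sd: float
    tau_pfr: float
    tau_cstr1: float
    tau_cstr2: float
    tubing_below_tau_pfr: bool
    mixer_holder_below_tau1: bool
    mixer_holder_above_tau2: bool
    margin_tau_pfr: float
    margin_tau1: float
    margin_tau2: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_spacetimes(
    params: CompartmentParams, intervals: Iterable[HoldupInterval] = MEASURED_HOLDUP
) -> HoldupAudit:
    """Audit fitted space times against summed measured holdups.

    Requires a 2-CSTR model (canonical ordering tau1 >= tau2).
    """
    params = params.canonical()
    if len(params.cstr_taus) != 2:
        raise ValueError("holdup audit requires a 2-CSTR compartment model")
    intervals = list(intervals)
    tubing = [iv for iv in intervals if iv.category == "tubing"]
    mixer_holder = [iv for iv in intervals if iv.category in ("mixer", "holder")]
    if not tubing or not mixer_holder:
        raise ValueError("holdup table must contain tubing and mixer/holder intervals")
    t_mean, t_sd = sum_holdup(tubing)
    mh_mean, mh_sd = sum_holdup(mixer_holder)
    tau1, tau2 = params.cstr_taus
    return HoldupAudit(
        tubing_total=t_mean,
        tubing_sd=t_sd,
        mixer_holder_total=mh_mean,
        mixer_holder_sd=mh_sd,
        tau_pfr=params.tau_pfr,
        tau_cstr1=tau1,
        tau_cstr2=tau2,
        tubing_below_tau_pfr=t_mean < params.tau_pfr,
        mixer_holder_below_tau1=mh_mean < tau1,
        mixer_holder_above_tau2=mh_mean > tau2,
        margin_tau_pfr=params.tau_pfr - t_mean,
        margin_tau1=tau1 - mh_mean,
        margin_tau2=mh_mean - tau2,
    )
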