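"""CSV/JSON readers and writers for the shared exchange formats.

Dialects:

* RTD curve: 2-column CSV ``time_min, c_norm`` with an optional JSON sidecar
  (``<name>.json``) carrying provenance and parameters.
* Fractions: ``t_start_min, t_end_min, volume_ml, cond1_uScm, cond2_uScm, ...``
* Calibration standards: ``concentration_M, conductivity_uScm``
* Holdup table: ``label, mean_min, sd_min, category``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compartment import RTDCurve
from .holdup import HoldupInterval
from .measurement import FractionRecord

__all__ = [
    "write_rtd_curve",
    "read_rtd_curve",
    "read_fractions",
    "read_standards",
    "read_holdup_table",
    "write_holdup_table",
]


def write_rtd_curve(curve: RTDCurve, path: str | Path, sidecar: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": curve.times, "c_norm": curve.values}).to_csv(
        path, index=False, float_format="%.10g"
    )
    meta = {"meta": curve.meta}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_rtd_curve(path: str | Path) -> RTDCurve:
    path = Path(path)
    df = _read_csv(path, required=("time_min", "c_norm"))
    meta = "measured"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", meta)
    return RTDCurve(df["time_min"].to_numpy(), df["c_norm"].to_numpy(), meta=meta)


def read_fractions(path: str | Path) -> list[FractionRecord]:
    df = _read_csv(path, required=("t_start_min", "t_end_min", "volume_ml"))
    cond_cols = sorted(c for c in df.columns if c.startswith("cond") and c.endswith("_uScm"))
    if not cond_cols:
        raise ValueError(f"{path}: no cond<i>_uScm replicate columns found")
    records = []
    for _, row in df.iterrows():
        reads = tuple(float(row[c]) for c in cond_cols if np.isfinite(row[c]))
        records.append(
            FractionRecord(float(row.t_start_min), float(row.t_end_min),
                           float(row.volume_ml), reads)
        )
    return records


def read_standards(path: str | Path) -> list[tuple[float, float]]:
    df = _read_csv(path, required=("concentration_M", "conductivity_uScm"))
    return list(zip(df["concentration_M"].astype(float), df["conductivity_uScm"].astype(float)))


def read_holdup_table(path: str | Path) -> list[HoldupInterval]:
    df = _read_csv(path, required=("label", "mean_min", "sd_min", "category"))
    return [
        HoldupInterval(str(r.label), float(r.mean_min), float(r.sd_min), str(r.category))
        for r in df.itertuples()
    ]


def write_holdup_table(intervals, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"label": iv.label, "mean_min": iv.mean, "sd_min": iv.sd, "category": iv.category}
            for iv in intervals
        ]
    ).to_csv(path, index=False)
    return path


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df
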