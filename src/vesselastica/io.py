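"""Plain-CSV interchange formats for every pipeline artifact.

All stages exchange data as small, independently inspectable CSV files:

* contours:   frame_index, t_seconds, vertex_index, x_mm, y_mm
* pressure:   t_seconds, p_mmHg
* strain:     t_seconds, L_mm, epsilon
* P–S loop:   t_seconds, epsilon, p_mmHg
* cohort:     animal_id, timepoint_months, tissue {native|itev}, modulus
* decay:      time_weeks, value, quantity {strength_N|mw_da}

Floats are written with repr-level precision so a write/read round trip is
lossless and a re-run is byte-identical under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .degradation import DecaySeries
from .errors import ValidationError
from .kinematics import ContourSeries, StrainSeries
from .psloop import PressureTrace, PSLoop

__all__ = [
    "read_contours", "write_contours",
    "read_pressure", "write_pressure",
    "read_strain", "write_strain",
    "read_ps_loop", "write_ps_loop",
    "read_cohort", "write_cohort",
    "read_decay", "write_decay",
]

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def write_contours(contours: ContourSeries, path: str | Path) -> Path:
    rows = []
    for i, (t, verts) in enumerate(zip(contours.timestamps, contours.contours)):
        for j, (x, y) in enumerate(verts):
            rows.append((i, t, j, x, y))
    df = pd.DataFrame(rows, columns=["frame_index", "t_seconds", "vertex_index",
                                     "x_mm", "y_mm"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_contours(path: str | Path) -> ContourSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["frame_index", "t_seconds", "vertex_index", "x_mm", "y_mm"],
                     "contours csv")
    timestamps, contours = [], []
    for idx, g in df.groupby("frame_index", sort=True):
        g = g.sort_values("vertex_index")
        t = g["t_seconds"].unique()
        if len(t) != 1:
            raise ValidationError(f"contours csv: frame {idx} has mixed timestamps")
        timestamps.append(float(t[0]))
        contours.append(g[["x_mm", "y_mm"]].to_numpy(dtype=float))
    return ContourSeries(timestamps=np.asarray(timestamps), contours=contours)


def write_pressure(pressure: PressureTrace, path: str | Path) -> Path:
    pd.DataFrame({"t_seconds": pressure.timestamps, "p_mmHg": pressure.pressures}) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_pressure(path: str | Path) -> PressureTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_seconds", "p_mmHg"], "pressure csv")
    return PressureTrace(timestamps=df["t_seconds"].to_numpy(dtype=float),
                         pressures=df["p_mmHg"].to_numpy(dtype=float))


def write_strain(strain: StrainSeries, path: str | Path) -> Path:
    pd.DataFrame({
        "t_seconds": strain.timestamps,
        "L_mm": strain.lengths,
        "epsilon": strain.strains,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_strain(path: str | Path) -> StrainSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_seconds", "L_mm", "epsilon"], "strain csv")
    strains = df["epsilon"].to_numpy(dtype=float)
    ref = int(np.argmin(np.abs(strains)))
    return StrainSeries(timestamps=df["t_seconds"].to_numpy(dtype=float),
                        lengths=df["L_mm"].to_numpy(dtype=float),
                        strains=strains, reference_index=ref)


def write_ps_loop(loop: PSLoop, path: str | Path) -> Path:
    pd.DataFrame({
        "t_seconds": loop.timestamps,
        "epsilon": loop.strains,
        "p_mmHg": loop.pressures,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_ps_loop(path: str | Path) -> PSLoop:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_seconds", "epsilon", "p_mmHg"], "ps loop csv")
    return PSLoop(timestamps=df["t_seconds"].to_numpy(dtype=float),
                  strains=df["epsilon"].to_numpy(dtype=float),
                  pressures=df["p_mmHg"].to_numpy(dtype=float))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    _require_columns(cohort, ["animal_id", "timepoint_months", "tissue", "modulus"],
                     "cohort table")
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["animal_id", "timepoint_months", "tissue", "modulus"],
                     "cohort csv")
    bad = set(df["tissue"].unique()) - {"native", "itev"}
    if bad:
        raise ValidationError(f"cohort csv: unknown tissue labels {sorted(bad)}")
    return df


def write_decay(series: DecaySeries, path: str | Path) -> Path:
    pd.DataFrame({
        "time_weeks": series.times,
        "value": series.values,
        "quantity": series.quantity,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_decay(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_weeks", "value"], "decay csv")
    quantity = ""
    if "quantity" in df.columns:
        q = df["quantity"].unique()
        if len(q) > 1:
            raise ValidationError("decay csv: mixed quantity labels in one file")
        quantity = str(q[0])
    return DecaySeries(times=df["time_weeks"].to_numpy(dtype=float),
                       values=df["value"].to_numpy(dtype=float),
                       quantity=quantity)
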