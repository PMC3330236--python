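"""Regeneration score (RS): stiffness-matching of a graft to native tissue.

The score compares the elastic-modulus gap between the engineered vessel
(E_T) and the native vessel (E_N) at a follow-up time with the gap at
implantation (E_T0, E_N0):

    RS = (1 - |E_T - E_N| / |E_T0 - E_N0|) * 100   [percent]

RS = 100% means the graft's modulus exactly matches native tissue; RS = 0%
means the gap is unchanged from implantation. The score is a ratio of
differences, so it is invariant under a common rescaling of all four moduli
— calibration of the modulus scale cancels out. Negative values (the gap
grew beyond baseline) are reported as-is, not clamped.

By default the gaps enter as absolute values, making the score symmetric in
over- vs under-stiffness; ``signed=True`` keeps the raw signed differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingBaselineError, ValidationError, ZeroBaselineError

__all__ = ["regeneration_score", "cohort_rs"]

_BASELINE_EPS = 0.0  # exact-zero check; moduli are O(1)-O(100) in practice


def regeneration_score(
    e_t: float,
    e_n: float,
    e_t0: float,
    e_n0: float,
    signed: bool = False,
) -> float:
    """RS in percent from current (E_T, E_N) and baseline (E_T0, E_N0) moduli.

    All moduli must be positive and the baseline difference nonzero
    (otherwise the normalization is undefined and ZeroBaselineError is
    raised).
    """
    for name, v in (("e_t", e_t), ("e_n", e_n), ("e_t0", e_t0), ("e_n0", e_n0)):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name}: modulus must be positive and finite")
    num = (e_t - e_n) if signed else abs(e_t - e_n)
    den = (e_t0 - e_n0) if signed else abs(e_t0 - e_n0)
    if den == _BASELINE_EPS:
        raise ZeroBaselineError("baseline modulus difference is zero; RS undefined")
    return (1.0 - num / den) * 100.0


def cohort_rs(cohort: pd.DataFrame, signed: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal RS trajectories and per-timepoint mean ± SEM summaries.

    ``cohort`` is the long-format cohort table with columns ``animal_id``,
    ``timepoint_months``, ``tissue`` ('native' | 'itev') and ``modulus``.
    Each animal's own month-0 records provide its baseline (E_T0, E_N0);
    an animal with no month-0 row for either tissue raises
    MissingBaselineError naming it.

    Returns ``(records, summary)``: records with columns animal_id,
    timepoint_months, rs_percent; summary with timepoint_months, mean, sem, n
    (SEM uses the n-1 sample standard deviation).
    """
    required = {"animal_id", "timepoint_months", "tissue", "modulus"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table: missing columns {sorted(missing)}")

    wide = cohort.pivot_table(
        index=["animal_id", "timepoint_months"],
        columns="tissue",
        values="modulus",
        aggfunc="mean",
    )
    for tissue in ("native", "itev"):
        if tissue not in wide.columns:
            raise ValidationError(f"cohort table: no '{tissue}' rows")

    rows = []
    for animal, traj in wide.groupby(level="animal_id"):
        traj = traj.droplevel("animal_id")
        if 0 not in traj.index or traj.loc[0].isna().any():
            raise MissingBaselineError(
                f"animal '{animal}' has no month-0 baseline records", animal_id=str(animal)
            )
        e_t0 = float(traj.loc[0, "itev"])
        e_n0 = float(traj.loc[0, "native"])
        for tp, row in traj.iterrows():
            rs = regeneration_score(float(row["itev"]), float(row["native"]),
                                    e_t0, e_n0, signed=signed)
            rows.append({"animal_id": animal, "timepoint_months": tp, "rs_percent": rs})

    records = pd.DataFrame(rows).sort_values(
        ["timepoint_months", "animal_id"], ignore_index=True
    )
    grouped = records.groupby("timepoint_months")["rs_percent"]
    summary = pd.DataFrame({
        "timepoint_months": grouped.mean().index,
        "mean": grouped.mean().to_numpy(),
        "sem": grouped.sem().to_numpy(),
        "n": grouped.size().to_numpy(),
    }).reset_index(drop=True)
    return records, summary
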