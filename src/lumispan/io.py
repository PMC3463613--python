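"""CSV and JSON interchange for survival series and plate readings.

Survival CSV dialect: header exactly ``timepoint_days,n_scored,n_alive,treatment``.
Plate CSV dialect: header
``plate_id,well,row,col,treatment,timepoint_h,worm_count,luminescence,fluorescence``
with ``well`` in letter-number form (A1-H12).  Plain UTF-8, dot decimal.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import WellRecord
from .survival import FittedSurvivalModel, SurvivalSeries

SURVIVAL_HEADER = ["timepoint_days", "n_scored", "n_alive", "treatment"]
PLATE_HEADER = [
    "plate_id",
    "well",
    "row",
    "col",
    "treatment",
    "timepoint_h",
    "worm_count",
    "luminescence",
    "fluorescence",
]

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "read_plate_csv",
    "write_plate_csv",
    "fit_report",
    "write_json",
]


def write_survival_csv(series_list, path) -> None:
    """Write one or more SurvivalSeries to the survival CSV dialect."""
    if isinstance(series_list, SurvivalSeries):
        series_list = [series_list]
    frames = [
        pd.DataFrame(
            {
                "timepoint_days": s.timepoints,
                "n_scored": s.n_scored,
                "n_alive": s.n_alive,
                "treatment": s.treatment,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_survival_csv(path) -> dict[str, SurvivalSeries]:
    """Read a survival CSV into one SurvivalSeries per treatment.

    Rows are sorted by timepoint within each treatment.  Rows with
    n_alive > n_scored or non-numeric fields are rejected with the
    offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != SURVIVAL_HEADER:
        raise ValueError(
            f"bad survival CSV header in {path}: expected "
            f"{','.join(SURVIVAL_HEADER)}, got {','.join(df.columns)}"
        )
    lines = df.index + 2  # header occupies line 1
    try:
        t = df["timepoint_days"].astype(float)
        n = df["n_scored"].astype(int)
        y = df["n_alive"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-numeric field in {path}: {exc}") from exc
    bad = y > n
    if bad.any():
        line = int(lines[bad][0])
        raise ValueError(
            f"{path} line {line}: n_alive ({int(y[bad].iloc[0])}) exceeds "
            f"n_scored ({int(n[bad].iloc[0])})"
        )
    parsed = pd.DataFrame(
        {"t": t, "n": n, "y": y, "treatment": df["treatment"]}
    )
    out: dict[str, SurvivalSeries] = {}
    for treatment, grp in parsed.groupby("treatment", sort=False):
        grp = grp.sort_values("t")
        out[str(treatment)] = SurvivalSeries(
            timepoints=grp["t"].to_numpy(),
            n_scored=grp["n"].to_numpy(),
            n_alive=grp["y"].to_numpy(),
            treatment=str(treatment),
        )
    return out


def write_plate_csv(records: list[WellRecord], path) -> None:
    """Write well records to the plate CSV dialect."""
    pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in records],
            "well": [r.well for r in records],
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "treatment": [r.treatment for r in records],
            "timepoint_h": [r.timepoint_h for r in records],
            "worm_count": [
                "" if r.worm_count is None else r.worm_count for r in records
            ],
            "luminescence": [r.luminescence for r in records],
            "fluorescence": [r.fluorescence for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_plate_csv(path) -> list[WellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != PLATE_HEADER:
        raise ValueError(
            f"bad plate CSV header in {path}: expected "
            f"{','.join(PLATE_HEADER)}, got {','.join(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        count = row["worm_count"]
        records.append(
            WellRecord(
                plate_id=str(row["plate_id"]),
                row=str(row["row"]),
                col=int(row["col"]),
                treatment=str(row["treatment"]),
                timepoint_h=float(row["timepoint_h"]),
                luminescence=float(row["luminescence"]),
                fluorescence=float(row["fluorescence"]),
                worm_count=None if pd.isna(count) else int(count),
            )
        )
    return records


def fit_report(model: FittedSurvivalModel, series: SurvivalSeries) -> dict:
    """JSON-ready summary of a fitted survival model."""
    return {
        "treatment": series.treatment,
        "degree": model.degree,
        "coefficients": [float(b) for b in model.coefficients],
        "standard_errors": [float(s) for s in model.standard_errors()],
        "dispersion": float(model.dispersion),
        "pearson_chi2": float(model.pearson_chi2),
        "deviance": float(model.deviance),
        "df_residual": int(model.df_residual),
        "converged": bool(model.converged),
        "data_window": list(model.data_window),
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload, path) -> None:
    """Write a JSON document (dataclasses and numpy types handled)."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
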