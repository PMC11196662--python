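"""CSV and JSON I/O for herd data, fits and reports.

The herd CSV schema has one row per animal per measurement period:

    animal_id,eye_temp,ambient_temp,humidity,age,days_in_milk,parity,body_weight,milk_yield

Units: deg C (eye_temp, ambient_temp), % (humidity), months (age), days
(days_in_milk), count (parity), kg (body_weight), litres (milk_yield).
Numeric fields round-trip at full double precision (written with repr
precision).  Unknown extra columns are preserved in metadata with a
warning; missing required columns and out-of-range values are reported
with the offending rows.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .herd import HERD_COLUMNS, CowRecord, frame_to_herd, herd_to_frame
from .models import ModelFit, invert_ttq, logistic_gamma50

__all__ = ["read_herd_csv", "write_herd_csv", "fit_to_dict", "dump_json"]


def write_herd_csv(records: Sequence[CowRecord], path) -> None:
    """Write herd records with the documented header, full precision."""
    frame = herd_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_herd_csv(path) -> tuple[list[CowRecord], dict]:
    """Read a herd CSV; returns ``(records, metadata)``.

    Errors name missing columns; unparseable numerics and humidity
    outside [0, 100] are reported with their row numbers.  Extra columns
    are kept under ``metadata["extra_columns"]``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in HERD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    extra = [c for c in frame.columns if c not in HERD_COLUMNS]
    metadata: dict = {"source": str(path)}
    if extra:
        warnings.warn(f"{path}: preserving unknown column(s) {extra} in metadata")
        metadata["extra_columns"] = frame[extra]
        frame = frame[list(HERD_COLUMNS)]

    numeric_cols = [c for c in HERD_COLUMNS if c != "animal_id"]
    parsed = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & frame[numeric_cols].notna() | frame[numeric_cols].isna()
    if bad.any().any():
        rows = sorted(set(np.flatnonzero(bad.any(axis=1)) + 2))  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable or missing numeric values at file row(s) {rows}")
    frame[numeric_cols] = parsed

    out_of_range = (frame["humidity"] < 0) | (frame["humidity"] > 100)
    if out_of_range.any():
        rows = sorted(np.flatnonzero(out_of_range.to_numpy()) + 2)
        raise ValueError(f"{path}: humidity outside [0, 100] at file row(s) {rows}")

    return frame_to_herd(frame), metadata


def fit_to_dict(fit: ModelFit) -> dict:
    """JSON-ready summary of one fitted ABTP model (incl. TT50/TT20)."""
    params = fit.params
    out = {
        "family": params.family,
        "tn50": params.tn50,
        "shape": params.shape,
        "log_likelihood": fit.log_likelihood,
        "n_parameters": fit.n_parameters,
        "n_observations": fit.n_observations,
        "converged": fit.converged,
        "aic": fit.aic,
        "tt50": invert_ttq(fit, 0.5),
    }
    try:
        out["tt20"] = invert_ttq(fit, 0.2)
    except ValueError:
        out["tt20"] = None
    if params.family == "Logistic":
        out["beta0"] = params.beta0
        out["beta1"] = params.beta1
        out["gamma50"] = logistic_gamma50(fit)
    return out


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def dump_json(obj, path) -> None:
    """Deterministic JSON dump: sorted keys, 17-significant-digit floats."""
    text = json.dumps(obj, indent=2, sort_keys=True, default=_default)
    Path(path).write_text(text + "\n")
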