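"""Temperature-humidity index (THI), abnormality labelling and triage bands.

The THI combines air temperature T (deg C) and relative humidity RH (%)
into a single heat-stress index:

    THI = (1.8*T + 32) - (0.55 - 0.0055*RH) * (1.8*T - 26)

A cow is labelled "abnormal" when its eye-socket temperature deviates
above a reference (by default the dataset mean, mirroring an annual-mean
screening rule).  Body temperatures are additionally sorted into triage
bands — normal / observe / abnormal — whose default boundaries are the
critical temperature 38.32 deg C and that value inflated by the thermal
imager's 2% accuracy margin (39.09 deg C), with an environmental alert
whenever THI exceeds 75.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "LabelRule",
    "TriageBands",
    "LabeledDataset",
    "compute_thi",
    "label_abnormal",
    "classify_temperature",
    "thi_alert",
]

#: feature columns of a LabeledDataset, in canonical order
FEATURE_COLUMNS = (
    "thi",
    "ambient_temp",
    "humidity",
    "age",
    "days_in_milk",
    "parity",
    "body_weight",
    "milk_yield",
)


def compute_thi(T, RH):
    """Temperature-humidity index from air temperature (deg C) and RH (%).

    Vectorised; scalar inputs return a float.  RH outside [0, 100] or
    non-finite T is rejected.
    """
    T_arr = np.asarray(T, dtype=float)
    RH_arr = np.asarray(RH, dtype=float)
    if not np.all(np.isfinite(T_arr)):
        raise ValueError("temperature must be finite")
    if not np.all(np.isfinite(RH_arr)) or np.any(RH_arr < 0) or np.any(RH_arr > 100):
        raise ValueError("relative humidity must lie in [0, 100]")
    thi = (1.8 * T_arr + 32.0) - (0.55 - 0.0055 * RH_arr) * (1.8 * T_arr - 26.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


@dataclass(frozen=True)
class LabelRule:
    """How the binary abnormal-temperature outcome is derived.

    reference="annual_mean": abnormal iff eye_temp > mean(eye_temp) + offset.
    reference="fixed_threshold": abnormal iff eye_temp > fixed_value.
    Both comparisons are strict, one-sided upward: heat stress elevates
    body temperature, so only positive deviations are flagged.
    """

    reference: str = "annual_mean"
    offset: float = 0.0
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.reference not in ("annual_mean", "fixed_threshold"):
            raise ValueError(f"unknown label reference {self.reference!r}")
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")
        if self.reference == "fixed_threshold":
            if self.fixed_value is None or self.fixed_value <= 0:
                raise ValueError("fixed_threshold rule needs fixed_value > 0")


@dataclass(frozen=True)
class TriageBands:
    """Body-temperature triage bands and the environmental THI alert level.

    ``observe_upper`` defaults to ``round(normal_below * (1 + instrument_margin), 2)``
    — the critical temperature inflated by the imager's accuracy margin.
    With the defaults 38.32 deg C and 2% this gives 39.09 deg C.
    """

    normal_below: float = 38.32
    instrument_margin: float = 0.02
    observe_upper: float | None = None
    thi_alert: float = 75.0

    def __post_init__(self) -> None:
        if self.observe_upper is None:
            object.__setattr__(
                self, "observe_upper",
                round(self.normal_below * (1.0 + self.instrument_margin), 2))
        if not self.normal_below < self.observe_upper:
            raise ValueError("normal_below must be strictly below observe_upper")
        if self.thi_alert <= 0:
            raise ValueError("thi_alert must be positive")


@dataclass
class LabeledDataset:
    """Feature matrix (8 canonical columns) plus the binary outcome."""

    X: pd.DataFrame
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if list(self.X.columns) != list(FEATURE_COLUMNS):
            raise ValueError(
                f"feature columns must be {list(FEATURE_COLUMNS)}, got {list(self.X.columns)}")
        if len(self.X) != self.y.size:
            raise ValueError("feature matrix and outcome disagree on row count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("outcome must be binary")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


def label_abnormal(records: Sequence | pd.DataFrame, rule: LabelRule | None = None) -> LabeledDataset:
    """Build a LabeledDataset from herd records.

    Accepts a sequence of CowRecord or a herd DataFrame.  Computes the THI
    column from ambient temperature and humidity and derives the outcome
    according to ``rule`` (default: strictly above the dataset mean
    eye-socket temperature).
    """
    from .herd import herd_to_frame  # local import to avoid a cycle

    rule = rule or LabelRule()
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = herd_to_frame(records)
    if len(frame) == 0:
        raise ValueError("cannot label an empty herd")
    eye = frame["eye_temp"].to_numpy(dtype=float)
    if not np.all(np.isfinite(eye)):
        raise ValueError("non-finite eye-socket temperature")

    if rule.reference == "annual_mean":
        threshold = float(eye.mean()) + rule.offset
    else:
        threshold = float(rule.fixed_value)
    y = (eye > threshold).astype(int)

    thi = compute_thi(frame["ambient_temp"].to_numpy(), frame["humidity"].to_numpy())
    X = pd.DataFrame({
        "thi": thi,
        "ambient_temp": frame["ambient_temp"].to_numpy(dtype=float),
        "humidity": frame["humidity"].to_numpy(dtype=float),
        "age": frame["age"].to_numpy(dtype=float),
        "days_in_milk": frame["days_in_milk"].to_numpy(dtype=float),
        "parity": frame["parity"].to_numpy(dtype=float),
        "body_weight": frame["body_weight"].to_numpy(dtype=float),
        "milk_yield": frame["milk_yield"].to_numpy(dtype=float),
    })
    meta = {"label_rule": rule, "label_threshold": threshold,
            "eye_temp": eye, "n_abnormal": int(y.sum())}
    return LabeledDataset(X=X, y=y, metadata=meta)


def classify_temperature(temp, bands: TriageBands | None = None):
    """Sort body temperature(s) into 'normal' / 'observe' / 'abnormal'.

    normal: temp < normal_below; observe: normal_below <= temp < observe_upper;
    abnormal: temp >= observe_upper.  Both band floors are inclusive.
    """
    bands = bands or TriageBands()
    temp_arr = np.asarray(temp, dtype=float)
    if not np.all(np.isfinite(temp_arr)):
        raise ValueError("temperature must be finite")
    labels = np.where(
        temp_arr < bands.normal_below, "normal",
        np.where(temp_arr < bands.observe_upper, "observe", "abnormal"))
    if labels.ndim == 0:
        return str(labels)
    return labels


def thi_alert(thi, bands: TriageBands | None = None):
    """Environmental alert: true iff THI strictly exceeds the alert level."""
    bands = bands or TriageBands()
    thi_arr = np.asarray(thi, dtype=float)
    if not np.all(np.isfinite(thi_arr)):
        raise ValueError("THI must be finite")
    out = thi_arr > bands.thi_alert
    if out.ndim == 0:
        return bool(out)
    return out
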