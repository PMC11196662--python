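"""Synthetic herd generation.

The study population this package targets — lactating Holstein-Friesian
cattle monitored by infrared eye-socket thermography together with farm
and weather records — is emulated by a configurable generator whose
default marginal moments are (mean +/- SD):

* eye-socket temperature 38.3 +/- 1.40 deg C
* ambient temperature 25.13 +/- 4.55 deg C, relative humidity 83.79 +/- 7.90 %
* age 49 +/- 27 months, days in milk 194 +/- 132, parity 2 +/- 1
* body weight 599.76 +/- 81.07 kg, milk yield 22.27 +/- 6.87 l

Marginals are Gaussian; ambient temperature and humidity share one
configurable correlation (default -0.3, the typical diurnal
anticorrelation) and all other variables are independent.  Humidity is
truncated to [0, 100]; age, days in milk and parity are truncated at 0
and rounded to integers.

Two ground-truth mechanisms couple heat stress to the outcome:

* ``temperature_generative`` — eye temperature follows a piecewise-linear
  "knee" response to THI (flat below the knee, linear above, Gaussian
  noise); abnormality labels are then derived downstream from the
  temperatures themselves.
* ``bernoulli_direct`` — eye temperature is drawn from its marginal and
  binary labels are drawn directly from a configured ABTP curve evaluated
  at each animal's THI, which makes dose-response parameter recovery
  exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .models import ABTPParams, predict
from .thi import compute_thi

__all__ = [
    "Moment",
    "HerdConfig",
    "CowRecord",
    "generate_herd",
    "generate_labels_direct",
    "herd_to_frame",
    "frame_to_herd",
]


class Moment(NamedTuple):
    """Mean and standard deviation of one herd variable."""

    mean: float
    sd: float


@dataclass(frozen=True)
class CowRecord:
    """One animal's physiological and environmental measurements."""

    animal_id: str
    eye_temp: float        # deg C, eye-socket (orbital) temperature
    ambient_temp: float    # deg C
    humidity: float        # %, in [0, 100]
    age: int               # months
    days_in_milk: int      # days since last calving
    parity: int            # number of calvings
    body_weight: float     # kg
    milk_yield: float      # litres

    def __post_init__(self) -> None:
        for name in ("eye_temp", "ambient_temp", "humidity", "body_weight", "milk_yield"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.humidity <= 100.0:
            raise ValueError(f"humidity {self.humidity} outside [0, 100]")
        if self.parity < 0:
            raise ValueError("parity must be a non-negative integer")


@dataclass(frozen=True)
class HerdConfig:
    """Configuration of the synthetic herd generator."""

    n_animals: int = 320
    eye_temp: Moment = Moment(38.3, 1.40)
    ambient_temp: Moment = Moment(25.13, 4.55)
    humidity: Moment = Moment(83.79, 7.90)
    age: Moment = Moment(49.0, 27.0)
    days_in_milk: Moment = Moment(194.0, 132.0)
    parity: Moment = Moment(2.0, 1.0)
    body_weight: Moment = Moment(599.76, 81.07)
    milk_yield: Moment = Moment(22.27, 6.87)
    temp_rh_correlation: float = -0.3
    label_mechanism: str = "temperature_generative"
    ground_truth: ABTPParams | None = None
    #: THI value at which eye temperature starts responding to heat load
    response_knee: float = 70.0
    #: deg C of eye-temperature rise per THI unit above the knee
    response_slope: float = 0.032
    #: baseline eye-socket temperature below the knee, deg C
    baseline_eye_temp: float = 38.1
    #: residual SD of the generative eye-temperature response, deg C
    noise_sd: float = 1.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not -1.0 <= self.temp_rh_correlation <= 1.0:
            raise ValueError("temp_rh_correlation must lie in [-1, 1]")
        for name in ("eye_temp", "ambient_temp", "humidity", "age",
                     "days_in_milk", "parity", "body_weight", "milk_yield"):
            if getattr(self, name).sd < 0:
                raise ValueError(f"{name} standard deviation must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.label_mechanism not in ("temperature_generative", "bernoulli_direct"):
            raise ValueError(f"unknown label mechanism {self.label_mechanism!r}")
        if self.label_mechanism == "bernoulli_direct" and self.ground_truth is None:
            raise ValueError("bernoulli_direct requires ground_truth ABTP parameters")

    def with_seed(self, seed: int) -> "HerdConfig":
        return replace(self, seed=seed)


HERD_COLUMNS = (
    "animal_id", "eye_temp", "ambient_temp", "humidity", "age",
    "days_in_milk", "parity", "body_weight", "milk_yield",
)


def generate_herd(config: HerdConfig) -> list[CowRecord]:
    """Draw a synthetic herd; identical config (incl. seed) gives identical data."""
    rng = np.random.default_rng(config.seed)
    n = config.n_animals

    # ambient temperature and humidity: bivariate Gaussian, then truncation
    t_m, t_s = config.ambient_temp
    h_m, h_s = config.humidity
    rho = config.temp_rh_correlation
    cov = np.array([[t_s**2, rho * t_s * h_s],
                    [rho * t_s * h_s, h_s**2]])
    env = rng.multivariate_normal([t_m, h_m], cov, size=n, method="svd")
    ambient = env[:, 0]
    humidity = np.clip(env[:, 1], 0.0, 100.0)

    age = np.rint(np.clip(rng.normal(*config.age, size=n), 0, None)).astype(int)
    dim = np.rint(np.clip(rng.normal(*config.days_in_milk, size=n), 0, None)).astype(int)
    parity = np.rint(np.clip(rng.normal(*config.parity, size=n), 0, None)).astype(int)
    weight = rng.normal(*config.body_weight, size=n)
    milk = rng.normal(*config.milk_yield, size=n)

    if config.label_mechanism == "temperature_generative":
        thi = compute_thi(ambient, humidity)
        excess = np.maximum(0.0, np.asarray(thi) - config.response_knee)
        eye = (config.baseline_eye_temp
               + config.response_slope * excess
               + rng.normal(0.0, config.noise_sd, size=n))
    else:
        eye = rng.normal(*config.eye_temp, size=n)

    return [
        CowRecord(
            animal_id=f"cow{i:04d}",
            eye_temp=float(eye[i]),
            ambient_temp=float(ambient[i]),
            humidity=float(humidity[i]),
            age=int(age[i]),
            days_in_milk=int(dim[i]),
            parity=int(parity[i]),
            body_weight=float(weight[i]),
            milk_yield=float(milk[i]),
        )
        for i in range(n)
    ]


def generate_labels_direct(thi_values, params: ABTPParams, seed: int) -> np.ndarray:
    """Draw Bernoulli abnormality labels from an ABTP curve at each THI.

    Element i is 1 with probability ``predict(params, thi_values[i])``.
    """
    thi_values = np.asarray(thi_values, dtype=float)
    p = np.asarray(predict(params, thi_values), dtype=float)
    rng = np.random.default_rng(seed)
    return (rng.random(thi_values.shape) < p).astype(int)


def herd_to_frame(records: Sequence[CowRecord]) -> pd.DataFrame:
    """Herd records as a DataFrame with the canonical column order."""
    return pd.DataFrame([
        {col: getattr(r, col) for col in HERD_COLUMNS} for r in records
    ], columns=list(HERD_COLUMNS))


def frame_to_herd(frame: pd.DataFrame) -> list[CowRecord]:
    """Inverse of :func:`herd_to_frame`; validates each row."""
    return [
        CowRecord(
            animal_id=str(row.animal_id),
            eye_temp=float(row.eye_temp),
            ambient_temp=float(row.ambient_temp),
            humidity=float(row.humidity),
            age=int(row.age),
            days_in_milk=int(row.days_in_milk),
            parity=int(row.parity),
            body_weight=float(row.body_weight),
            milk_yield=float(row.milk_yield),
        )
        for row in frame.itertuples(index=False)
    ]
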