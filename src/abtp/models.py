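"""Sigmoid dose-response models for abnormal body temperature probability (ABTP).

Four two-parameter families map a quantitative risk factor ``n`` (in this
package usually the temperature-humidity index, THI) onto the probability
that a cow's body temperature is classified abnormal:

* **LKB** — the Lyman-Kutcher-Burman probit model from the radiotherapy
  NTCP literature, ``P = Phi((n - Tn50) / (m * Tn50))``.
* **Logistic** — ``P = 1 / (1 + exp(-(b0 + b1 * n)))``.
* **Schultheiss** — the log-logistic model ``P = 1 / (1 + (Tn50 / n)^k)``.
* **Poisson** — the Poisson tolerance model
  ``P = 2^(-exp(e * gamma * (1 - n / Tn50)))``.

All families share the location parameter ``Tn50``, the factor value at
which the predicted probability is exactly 0.5, plus one shape (slope)
parameter.  Fitting is by maximum Bernoulli likelihood: a coarse grid
search over (Tn50, shape) followed by Nelder-Mead refinement, which is
deterministic for a given dataset.  Fitted curves invert to ``TTq``
thresholds (e.g. TT50, TT20), the factor values at probability ``q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, special

__all__ = [
    "FAMILIES",
    "ABTPParams",
    "ModelFit",
    "prob_lkb",
    "prob_logistic",
    "prob_schultheiss",
    "prob_poisson",
    "predict",
    "log_likelihood",
    "fit_abtp",
    "invert_ttq",
    "logistic_gamma50",
]

Family = Literal["LKB", "Logistic", "Schultheiss", "Poisson"]
FAMILIES: tuple[str, ...] = ("LKB", "Logistic", "Schultheiss", "Poisson")

#: probability floor/ceiling applied before taking logs in the likelihood
CLIP_EPS = 1e-12

# search bounds for the shape parameter of each family
SHAPE_BOUNDS: dict[str, tuple[float, float]] = {
    "LKB": (0.005, 2.0),
    "Logistic": (0.01, 5.0),
    "Schultheiss": (0.1, 200.0),
    "Poisson": (0.05, 20.0),
}


@dataclass(frozen=True)
class ABTPParams:
    """Parameters of one ABTP family.

    Every family is stored as (tn50, shape):

    ======== ======================= =====================================
    family   shape meaning           relation to the published form
    ======== ======================= =====================================
    LKB      m (relative slope)      u = (n - tn50) / (m * tn50)
    Logistic b1 (slope per n-unit)   b0 = -b1 * tn50, s = b0 + b1 * n
    Schultheiss k (log-logistic)     P = 1 / (1 + (tn50 / n)^k)
    Poisson  gamma                   P = 2^(-exp(e * gamma * (1 - n/tn50)))
    ======== ======================= =====================================
    """

    family: str
    tn50: float
    shape: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not np.isfinite(self.tn50) or self.tn50 <= 0:
            raise ValueError(f"tn50 must be positive and finite, got {self.tn50}")
        if not np.isfinite(self.shape):
            raise ValueError(f"shape must be finite, got {self.shape}")
        if self.family == "Logistic":
            if self.shape == 0:
                raise ValueError("Logistic slope b1 must be nonzero")
        elif self.shape <= 0:
            raise ValueError(f"{self.family} shape must be positive, got {self.shape}")

    # -- logistic convenience accessors -------------------------------------
    @property
    def beta1(self) -> float:
        if self.family != "Logistic":
            raise AttributeError("beta1 is defined for the Logistic family only")
        return self.shape

    @property
    def beta0(self) -> float:
        if self.family != "Logistic":
            raise AttributeError("beta0 is defined for the Logistic family only")
        return -self.shape * self.tn50

    @classmethod
    def from_logistic_coefficients(cls, beta0: float, beta1: float) -> "ABTPParams":
        """Build Logistic params from (b0, b1); tn50 is the derived -b0/b1."""
        if beta1 == 0:
            raise ValueError("beta1 must be nonzero")
        return cls("Logistic", tn50=-beta0 / beta1, shape=beta1)


@dataclass(frozen=True)
class ModelFit:
    """A maximum-likelihood fit of one ABTP family to binary outcome data."""

    params: ABTPParams
    log_likelihood: float
    n_observations: int
    converged: bool
    n_parameters: int = 2
    #: optimizer trace: best grid point, refinement iterations, etc.
    trace: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood

    @property
    def tt50(self) -> float:
        return self.params.tn50


# ---------------------------------------------------------------------------
# probability curves
# ---------------------------------------------------------------------------

def prob_lkb(n, tn50: float, m: float):
    """LKB probit curve: standard normal CDF of (n - tn50) / (m * tn50)."""
    if tn50 <= 0 or m <= 0:
        raise ValueError("tn50 and m must be positive")
    n = np.asarray(n, dtype=float)
    u = (n - tn50) / (m * tn50)
    return special.ndtr(u)


def prob_logistic(n, beta0: float, beta1: float):
    """Logistic curve 1 / (1 + exp(-(beta0 + beta1 * n))), overflow-safe."""
    n = np.asarray(n, dtype=float)
    return special.expit(beta0 + beta1 * n)


def prob_schultheiss(n, tn50: float, k: float):
    """Log-logistic (Schultheiss) curve 1 / (1 + (tn50 / n)^k); requires n > 0."""
    if tn50 <= 0 or k <= 0:
        raise ValueError("tn50 and k must be positive")
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("Schultheiss curve is defined for positive n only")
    # 1/(1+(tn50/n)^k) == expit(k*(ln n - ln tn50)) — stable for extreme k
    return special.expit(k * (np.log(n) - math.log(tn50)))


def prob_poisson(n, tn50: float, gamma: float):
    """Poisson tolerance curve 2^(-exp(e * gamma * (1 - n / tn50))).

    The constant multiplying gamma is Euler's number at full precision.
    At ``n = tn50`` the inner exponent vanishes and the value is exactly
    2^(-1) = 0.5.
    """
    if tn50 <= 0 or gamma <= 0:
        raise ValueError("tn50 and gamma must be positive")
    n = np.asarray(n, dtype=float)
    inner = math.e * gamma * (1.0 - n / tn50)
    with np.errstate(over="ignore"):
        # exp overflow -> inf -> exp(-inf * ln2) -> 0, the correct limit
        return np.exp(-math.log(2.0) * np.exp(inner))


def predict(params: ABTPParams, n):
    """Evaluate a family's ABTP curve at factor value(s) ``n``."""
    if params.family == "LKB":
        return prob_lkb(n, params.tn50, params.shape)
    if params.family == "Logistic":
        return prob_logistic(n, params.beta0, params.beta1)
    if params.family == "Schultheiss":
        return prob_schultheiss(n, params.tn50, params.shape)
    return prob_poisson(n, params.tn50, params.shape)


def log_likelihood(y, p, eps: float = CLIP_EPS) -> float:
    """Bernoulli log-likelihood sum(y*ln p + (1-y)*ln(1-p)), in nats.

    Probabilities are clipped to [eps, 1-eps] before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: y has shape {y.shape}, p has {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _curve_ll_grid(family: str, thi: np.ndarray, y: np.ndarray,
                   tn50_grid: np.ndarray, shape_grid: np.ndarray) -> np.ndarray:
    """Log-likelihood on the (tn50, shape) grid, vectorised over shape and data."""
    ll = np.empty((tn50_grid.size, shape_grid.size))
    for i, t50 in enumerate(tn50_grid):
        if family == "LKB":
            u = (thi[None, :] - t50) / (shape_grid[:, None] * t50)
            p = special.ndtr(u)
        elif family == "Logistic":
            p = special.expit(shape_grid[:, None] * (thi[None, :] - t50))
        elif family == "Schultheiss":
            p = special.expit(shape_grid[:, None] * (np.log(thi)[None, :] - math.log(t50)))
        else:  # Poisson
            inner = math.e * shape_grid[:, None] * (1.0 - thi[None, :] / t50)
            with np.errstate(over="ignore"):
                p = np.exp(-math.log(2.0) * np.exp(inner))
        p = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
        ll[i] = np.sum(y[None, :] * np.log(p) + (1.0 - y[None, :]) * np.log1p(-p), axis=1)
    return ll


def fit_abtp(family: str, thi, y, seed: int | None = None,
             grid_size: int = 50) -> ModelFit:
    """Fit one ABTP family to binary outcomes by maximum likelihood.

    Coarse grid search — tn50 over the observed factor range, shape
    log-spaced over the family's documented bounds — followed by
    Nelder-Mead refinement from the best grid point.  Deterministic for a
    given dataset; ``seed`` is accepted for interface symmetry and unused.

    Parameters
    ----------
    family : one of "LKB", "Logistic", "Schultheiss", "Poisson"
    thi : array of factor values (must be positive for Schultheiss/Poisson)
    y : binary outcome array, both classes present
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    thi = np.asarray(thi, dtype=float)
    y = np.asarray(y, dtype=float)
    if thi.shape != y.shape:
        raise ValueError("thi and y must have the same length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to fit")
    if family in ("Schultheiss", "Poisson") and np.any(thi <= 0):
        raise ValueError(f"{family} requires positive factor values")

    lo, hi = SHAPE_BOUNDS[family]
    t_lo, t_hi = float(thi.min()), float(thi.max())
    if t_lo <= 0:
        t_lo = min(1e-3, t_hi / 2)
    tn50_grid = np.linspace(t_lo, t_hi, grid_size)
    tn50_grid = tn50_grid[tn50_grid > 0]
    shape_grid = np.geomspace(lo, hi, grid_size)

    ll = _curve_ll_grid(family, thi, y, tn50_grid, shape_grid)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    best_grid_ll = float(ll[i, j])
    x0 = np.array([tn50_grid[i], math.log(shape_grid[j])])

    def nll(x: np.ndarray) -> float:
        t50, log_s = x
        s = math.exp(log_s)
        if not (t_lo / 2 <= t50 <= t_hi * 2) or not (lo <= s <= hi):
            return np.inf
        pars = ABTPParams(family, t50, s)
        return -log_likelihood(y, predict(pars, thi))

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 2000})
    refined_ll = -float(res.fun)
    if refined_ll >= best_grid_ll:
        tn50_hat, shape_hat = float(res.x[0]), math.exp(float(res.x[1]))
        final_ll = refined_ll
        converged = bool(res.success)
    else:  # refinement must never lose to the grid; keep the grid optimum
        tn50_hat, shape_hat = float(tn50_grid[i]), float(shape_grid[j])
        final_ll = best_grid_ll
        converged = False

    params = ABTPParams(family, tn50_hat, shape_hat)
    return ModelFit(
        params=params,
        log_likelihood=final_ll,
        n_observations=int(y.size),
        converged=converged,
        trace={
            "grid_best_tn50": float(tn50_grid[i]),
            "grid_best_shape": float(shape_grid[j]),
            "grid_best_ll": best_grid_ll,
            "nm_iterations": int(res.nit),
            "nm_success": bool(res.success),
        },
    )


# ---------------------------------------------------------------------------
# quantile inversion
# ---------------------------------------------------------------------------

def invert_ttq(fit: ModelFit | ABTPParams, q: float) -> float:
    """Invert a fitted curve: the factor value where predicted ABTP equals q.

    Closed form for LKB, Logistic and Schultheiss; bracketed Brent root
    finding for the Poisson family.  ``q = 0.5`` returns tn50 exactly for
    every family.
    """
    params = fit.params if isinstance(fit, ModelFit) else fit
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    t50, s = params.tn50, params.shape
    if params.family == "LKB":
        z = special.ndtri(q)
        scale = 1.0 + s * z
        if scale <= 0:
            raise ValueError(
                f"q={q} is below the LKB curve's support (1 + m*z = {scale:.4g} <= 0)")
        return t50 * scale
    if params.family == "Logistic":
        return (special.logit(q) - params.beta0) / params.beta1
    if params.family == "Schultheiss":
        return t50 * (q / (1.0 - q)) ** (1.0 / s)
    # Poisson: bracketed root finding on a monotone curve.  The curve is
    # bounded below by its n -> 0 limit 2^(-exp(e*gamma)), so small q can
    # be unreachable on the positive axis.
    p_floor = float(prob_poisson(1e-12, t50, s))
    if q <= p_floor:
        raise ValueError(
            f"q={q} is at or below the Poisson curve's n->0 limit {p_floor:.4g}")
    f = lambda n: float(prob_poisson(n, t50, s)) - q
    lo, hi = t50, t50
    step = 0.5 * t50
    while f(lo) > 0 and lo > 1e-9:
        lo = max(lo - step, 1e-9)
    while f(hi) < 0 and hi < 1e9 * t50:
        hi += step
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def logistic_gamma50(fit: ModelFit | ABTPParams) -> float:
    """Normalised logistic slope at the 50% point, gamma50 = b1 * TT50 / 4.

    Display-only convenience; the stored shape parameter remains b1.
    """
    params = fit.params if isinstance(fit, ModelFit) else fit
    if params.family != "Logistic":
        raise ValueError("gamma50 is defined for the Logistic family")
    return params.beta1 * params.tn50 / 4.0
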