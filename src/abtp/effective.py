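"""LKB effective-index model coupling body temperature and the risk factor.

The plain LKB curve treats the risk factor (THI) alone.  The effective
index extends it with the animal's body temperature through a power law
for the 50%-probability level,

    Tn50(temp) = Tn50(1) * temp^(-c),        c > 0,

and an effective temperature that renormalises an observation made at
factor value ``n_i`` to the reference level ``n_ref``:

    Temp_eff_i = Temp_i * (n_i / n_ref)^(-c).

The combined abnormality probability is the probit

    P = Phi(u),   u = (dose - Tn50(1) * Temp_eff^(-c)) / (m * Tn50(1) * Temp_eff^(-c)),

where ``dose`` is ``n_ref`` in the published form (``dose="reference"``,
the default) or the observed factor value ``n_i`` (``dose="observed"``).
The two readings differ materially: with ``dose="reference"`` the factor
enters only through ``Temp_eff^(-c) ~ n_i^(c^2)``, a very weak and
direction-reversed dependence, whereas ``dose="observed"`` is the usual
dose-response reading in which probability rises steeply with the factor
and iso-probability contours in the (temperature, factor) plane are
ordered by probability level.  Both are provided; see docs/methods.md.

All three parameters (Tn50(1), c, m) are estimated jointly by maximum
likelihood with the same grid-then-Nelder-Mead strategy as the
univariate ABTP fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .models import CLIP_EPS, log_likelihood

__all__ = [
    "EffectiveIndexModel",
    "tn50_power_law",
    "effective_temperature",
    "lkb_eff_prob",
    "abtp_eff",
    "fit_effective_index",
    "iso_probability_contour",
]


@dataclass(frozen=True)
class EffectiveIndexModel:
    """Power-law Tn50(temp) relationship plus the LKB slope.

    Fields
    ------
    tn50_at_unit : Tn50(1), the 50% factor level at unit body temperature
    c : power-law exponent (> 0) linking body temperature to Tn50
    m : LKB relative slope
    n_ref : reference factor value used to normalise observations
    temp_ref : reference (critical) body temperature, for reporting
    dose : "reference" (published u with n_ref in the numerator) or
        "observed" (the observed factor value in the numerator)
    """

    tn50_at_unit: float
    c: float
    m: float
    n_ref: float
    temp_ref: float = 38.32
    dose: str = "reference"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.tn50_at_unit <= 0:
            raise ValueError("tn50_at_unit must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.n_ref <= 0:
            raise ValueError("n_ref must be positive")
        if self.dose not in ("reference", "observed"):
            raise ValueError(f"dose must be 'reference' or 'observed', got {self.dose!r}")


def tn50_power_law(temp, model: EffectiveIndexModel):
    """Tn50 at body temperature ``temp``: tn50_at_unit * temp^(-c)."""
    temp = np.asarray(temp, dtype=float)
    if np.any(temp <= 0):
        raise ValueError("temp must be positive")
    out = model.tn50_at_unit * temp ** (-model.c)
    return float(out) if out.ndim == 0 else out


def effective_temperature(temp_i, n_i, model: EffectiveIndexModel):
    """Effective temperature Temp_i * (n_i / n_ref)^(-c).

    Equals ``temp_i`` exactly when the observed factor sits at the
    reference value.
    """
    temp_i = np.asarray(temp_i, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    if np.any(temp_i <= 0):
        raise ValueError("temp_i must be positive")
    if np.any(n_i <= 0):
        raise ValueError("n_i must be positive")
    out = temp_i * (n_i / model.n_ref) ** (-model.c)
    return float(out) if out.ndim == 0 else out


def lkb_eff_prob(temp_eff, model: EffectiveIndexModel, n=None):
    """Probit abnormality probability at an effective temperature.

    With ``model.dose == "reference"`` the numerator dose is ``n_ref``;
    with ``"observed"`` it is the supplied factor value ``n`` (required
    in that mode).
    """
    temp_eff = np.asarray(temp_eff, dtype=float)
    if np.any(temp_eff <= 0):
        raise ValueError("temp_eff must be positive")
    tn50_eff = model.tn50_at_unit * temp_eff ** (-model.c)
    if model.dose == "reference":
        dose = model.n_ref
    else:
        if n is None:
            raise ValueError("dose='observed' requires the observed factor value n")
        dose = np.asarray(n, dtype=float)
    u = (dose - tn50_eff) / (model.m * tn50_eff)
    out = special.ndtr(u)
    return float(out) if np.ndim(out) == 0 else out


def abtp_eff(thi, eye_temp, model: EffectiveIndexModel):
    """Full chain: effective temperature from (eye_temp, thi), then Phi(u)."""
    te = effective_temperature(eye_temp, thi, model)
    return lkb_eff_prob(te, model, n=thi)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _eff_nll(params_vec, thi, temp, y, n_ref, dose):
    log_t50u, log_c, log_m = params_vec
    model = EffectiveIndexModel(
        tn50_at_unit=math.exp(log_t50u), c=math.exp(log_c), m=math.exp(log_m),
        n_ref=n_ref, dose=dose)
    p = abtp_eff(thi, temp, model)
    return -log_likelihood(y, p)


def fit_effective_index(thi, eye_temp, y, n_ref: float | None = None,
                        dose: str = "reference", seed: int | None = None,
                        grid_size: int = 12) -> EffectiveIndexModel:
    """Joint MLE of (tn50_at_unit, c, m) from (THI, eye_temp, abnormal) triples.

    ``n_ref`` defaults to the mean observed THI (the herd-mean condition).
    Coarse log-spaced grid over the three parameters, then Nelder-Mead in
    log space; deterministic given the data.
    """
    thi = np.asarray(thi, dtype=float)
    temp = np.asarray(eye_temp, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (thi.shape == temp.shape == y.shape):
        raise ValueError("thi, eye_temp and y must have equal length")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to fit")
    if n_ref is None:
        n_ref = float(thi.mean())

    # Tn50(1) must be able to place Tn50(temp) inside the observed THI range
    # for body temperatures near the data, across the c grid.
    c_grid = np.geomspace(1e-3, 1.0, grid_size)
    m_grid = np.geomspace(0.005, 2.0, grid_size)
    mean_temp = float(np.mean(temp))
    t50u_grid = np.geomspace(0.3 * n_ref, n_ref * mean_temp ** 1.0, 2 * grid_size)

    best = (np.inf, None)
    dose_vec = n_ref if dose == "reference" else thi
    for c in c_grid:
        a = temp ** (-c) * (thi / n_ref) ** (c * c)  # Temp_eff^(-c)
        for t50u in t50u_grid:
            tn50_eff = t50u * a
            u = (dose_vec - tn50_eff)[None, :] / (m_grid[:, None] * tn50_eff[None, :])
            p = np.clip(special.ndtr(u), CLIP_EPS, 1 - CLIP_EPS)
            nll_m = -np.sum(y[None, :] * np.log(p)
                            + (1 - y[None, :]) * np.log1p(-p), axis=1)
            j = int(np.argmin(nll_m))
            if nll_m[j] < best[0]:
                best = (float(nll_m[j]), (t50u, c, float(m_grid[j])))
    nll0, (t50u0, c0, m0) = best

    x0 = np.log([t50u0, c0, m0])
    res = optimize.minimize(
        _eff_nll, x0, args=(thi, temp, y, n_ref, dose), method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 4000})
    if -res.fun >= -nll0:
        t50u, c, m = np.exp(res.x)
        ll = -float(res.fun)
        converged = bool(res.success)
    else:
        t50u, c, m = t50u0, c0, m0
        ll = -nll0
        converged = False

    return EffectiveIndexModel(
        tn50_at_unit=float(t50u), c=float(c), m=float(m), n_ref=n_ref, dose=dose,
        metadata={"log_likelihood": ll, "converged": converged,
                  "n_observations": int(y.size), "grid_best_nll": float(nll0),
                  "nm_success": bool(res.success)},
    )


# ---------------------------------------------------------------------------
# iso-probability contours
# ---------------------------------------------------------------------------

def iso_probability_contour(model: EffectiveIndexModel, q: float, temp_grid,
                            thi_bracket: tuple[float, float] = (30.0, 120.0),
                            tol: float = 1e-10):
    """THI solving ABTP(thi, temp) = q at each body temperature in the grid.

    Returns ``(temp, thi, reachable)`` arrays; ``thi`` is NaN (and
    ``reachable`` False) where ``q`` is not bracketed within
    ``thi_bracket`` at that temperature.  Root finding is bisection-grade
    Brent to ``tol`` THI units.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly in (0, 1)")
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    lo, hi = thi_bracket
    thi_out = np.full(temp_grid.shape, np.nan)
    ok = np.zeros(temp_grid.shape, dtype=bool)
    for i, t in enumerate(temp_grid):
        f = lambda n: float(abtp_eff(n, t, model)) - q
        flo, fhi = f(lo), f(hi)
        if flo == 0.0:
            thi_out[i], ok[i] = lo, True
            continue
        if fhi == 0.0:
            thi_out[i], ok[i] = hi, True
            continue
        if flo * fhi > 0:
            continue  # q unreachable at this temperature, reported via mask
        thi_out[i] = optimize.brentq(f, lo, hi, xtol=tol)
        ok[i] = True
    return temp_grid, thi_out, ok
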