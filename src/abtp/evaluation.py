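"""Model-comparison battery for fitted ABTP models.

For each fitted model the report carries: AUC with a 95% DeLong
confidence interval, classification accuracy at the 50% probability
cutoff, AIC and delta-AIC against a designated baseline (LKB by
convention), the Brier score, the Hosmer-Lemeshow goodness-of-fit
p-value, and a calibration summary (weighted slope/intercept of observed
vs predicted event rates across probability bins, plus their weighted
correlation).  Evaluation is in-sample, matching how such univariate
dose-response fits are normally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelFit

__all__ = [
    "EvaluationReport",
    "auc_with_ci",
    "accuracy_at",
    "aic",
    "delta_aic",
    "brier",
    "hosmer_lemeshow",
    "calibration_curve",
    "evaluate_models",
]


def _check_binary(y: np.ndarray) -> None:
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_with_ci(y, p, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC (Mann-Whitney concordance, ties at half credit) with DeLong CI.

    Returns ``(auc, ci_low, ci_high)``; the interval is the normal
    approximation with the DeLong structural-component variance, clipped
    to [0, 1].
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    _check_binary(y)
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = pos.size, neg.size

    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), float(lo), float(hi)


def accuracy_at(y, p, threshold: float = 0.5) -> float:
    """Fraction of records where (p > threshold) matches the outcome.

    The comparison is strict, so probabilities exactly at the cutoff
    predict the negative class.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    return float(np.mean((p > threshold).astype(float) == y))


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aic(fit: ModelFit) -> float:
    """Akaike information criterion, 2k - 2*log_likelihood."""
    return 2.0 * fit.n_parameters - 2.0 * fit.log_likelihood


def delta_aic(aics: dict[str, float], baseline: str = "LKB") -> dict[str, float | None]:
    """AIC_i - AIC_baseline per model; the baseline's own entry is None.

    ``None`` renders as a dash in the tabular report, matching the usual
    presentation where the reference row is left blank.
    """
    if baseline not in aics:
        raise ValueError(f"baseline {baseline!r} not among models {sorted(aics)}")
    ref = aics[baseline]
    return {name: (None if name == baseline else value - ref)
            for name, value in aics.items()}


def brier(y, p) -> float:
    """Brier score: mean squared error of the probabilistic forecasts."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _equal_frequency_bins(p: np.ndarray, bins: int) -> list[np.ndarray]:
    """Indices per bin after a stable sort of p; sizes differ by at most 1."""
    order = np.argsort(p, kind="stable")
    return [idx for idx in np.array_split(order, bins) if idx.size > 0]


def hosmer_lemeshow(y, p, bins: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square test over equal-frequency probability bins.

    Statistic: sum over bins of (O - E)^2 / (E * (1 - E / n_g)) with O the
    observed and E the expected event count in a bin of size n_g; p-value
    from chi-square with bins - 2 degrees of freedom.  Bins with zero
    expected count are merged with their neighbour (and noted via a
    warning); fewer than 3 effective bins leaves no degrees of freedom
    and raises.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    _check_binary(y)
    if y.size < bins:
        raise ValueError("need at least as many observations as bins")

    groups = _equal_frequency_bins(p, bins)
    # merge bins whose expected count is 0 into the following bin
    merged: list[np.ndarray] = []
    carry = np.array([], dtype=int)
    for g in groups:
        g = np.concatenate([carry, g])
        if p[g].sum() <= 0.0:
            carry = g
            continue
        merged.append(g)
        carry = np.array([], dtype=int)
    if carry.size:
        if merged:
            merged[-1] = np.concatenate([merged[-1], carry])
            warnings.warn("merged a zero-expectation probability bin with its neighbour")
        else:
            raise ValueError("all predicted probabilities are zero")
    if len(merged) < len(groups):
        warnings.warn(
            f"{len(groups) - len(merged)} zero-expectation bin(s) merged")

    df = len(merged) - 2
    if df < 1:
        raise ValueError(f"{len(merged)} bins leave {df} degrees of freedom; need >= 1")
    stat = 0.0
    for g in merged:
        n_g = g.size
        obs = y[g].sum()
        exp = p[g].sum()
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:  # all-one expected bin: fall back to plain chi-square term
            denom = max(exp, 1e-12)
        stat += (obs - exp) ** 2 / denom
    p_value = float(stats.chi2.sf(stat, df))
    return float(stat), p_value


def calibration_curve(y, p, bins: int = 10):
    """Per-bin observed vs predicted event rates plus a weighted linear fit.

    Returns ``(table, slope, intercept)``: the table has one row per
    equal-frequency bin (count, mean predicted, observed rate); slope and
    intercept come from least squares on the bin points weighted by bin
    count.  With a single distinct bin abscissa the regression is
    degenerate and slope/intercept are NaN, flagged in the table attrs.
    The weighted correlation between the bin rates is stored in
    ``table.attrs["weighted_correlation"]``.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if y.size < bins:
        raise ValueError("need at least as many observations as bins")
    groups = _equal_frequency_bins(p, bins)
    counts = np.array([g.size for g in groups], dtype=float)
    pred = np.array([p[g].mean() for g in groups])
    obs = np.array([y[g].mean() for g in groups])
    table = pd.DataFrame({"count": counts.astype(int),
                          "mean_predicted": pred, "observed_rate": obs})

    w = counts / counts.sum()
    xbar = np.sum(w * pred)
    ybar = np.sum(w * obs)
    sxx = np.sum(w * (pred - xbar) ** 2)
    if sxx <= 1e-16:
        table.attrs["degenerate"] = True
        table.attrs["weighted_correlation"] = float("nan")
        return table, float("nan"), float("nan")
    sxy = np.sum(w * (pred - xbar) * (obs - ybar))
    syy = np.sum(w * (obs - ybar) ** 2)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    corr = sxy / np.sqrt(sxx * syy) if syy > 1e-16 else float("nan")
    table.attrs["degenerate"] = False
    table.attrs["weighted_correlation"] = float(corr)
    return table, float(slope), float(intercept)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-model metric rows with a designated delta-AIC baseline."""

    table: pd.DataFrame
    baseline_model: str
    calibration_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def evaluate_models(y, predictions: dict[str, np.ndarray],
                    fits: dict[str, ModelFit] | None = None,
                    baseline: str = "LKB", bins: int = 10) -> EvaluationReport:
    """Run the full battery for each model's predicted probabilities.

    ``fits`` supplies log-likelihoods for AIC; models without a fit get
    NaN AIC entries.  If the requested baseline is absent, the first
    model is used instead (with a warning) so single-model reports still
    render.
    """
    y = np.asarray(y, dtype=float)
    names = list(predictions)
    if baseline not in names:
        warnings.warn(f"baseline {baseline!r} not evaluated; using {names[0]!r}")
        baseline = names[0]
    fits = fits or {}

    rows = []
    cal_tables: dict[str, pd.DataFrame] = {}
    aics: dict[str, float] = {}
    for name in names:
        p = np.asarray(predictions[name], dtype=float)
        auc, lo, hi = auc_with_ci(y, p)
        hl_stat, hl_p = hosmer_lemeshow(y, p, bins=bins)
        cal, slope, intercept = calibration_curve(y, p, bins=bins)
        cal_tables[name] = cal
        model_aic = aic(fits[name]) if name in fits else float("nan")
        aics[name] = model_aic
        rows.append({
            "model": name,
            "auc": auc, "auc_ci_low": lo, "auc_ci_high": hi,
            "accuracy": accuracy_at(y, p),
            "aic": model_aic,
            "brier": brier(y, p),
            "hl_stat": hl_stat, "hl_p": hl_p,
            "calibration_slope": slope,
            "calibration_intercept": intercept,
            "calibration_correlation": cal.attrs["weighted_correlation"],
        })
    table = pd.DataFrame(rows).set_index("model")
    if np.isfinite(list(aics.values())).all():
        deltas = delta_aic(aics, baseline=baseline)
        table["delta_aic"] = [deltas[name] for name in table.index]
    else:
        table["delta_aic"] = float("nan")
    return EvaluationReport(table=table, baseline_model=baseline,
                            calibration_tables=cal_tables)
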