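"""LASSO coefficient paths and risk-factor ranking.

L1-penalised regression shrinks coefficients toward zero along a
decreasing penalty grid; the order in which factors enter the path
(acquire a nonzero coefficient) ranks their importance.  For the herd
analysis the outcome is binary, so the working family is binomial
(penalised logistic regression); a squared-error family is also exposed
because on orthonormal designs its path has the exact soft-thresholding
solution, which serves as an analytic correctness check.

Solvers are scikit-learn's (liblinear logistic regression per penalty,
coordinate-descent Lasso for the linear family); the grid follows the
glmnet convention of 100 log-spaced penalties from lambda_max, the
smallest penalty with an all-zero path, down to lambda_max / 1e4.
Features are standardised to zero mean and unit variance before
penalisation, so the ranking is invariant to the units the factors are
recorded in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .models import log_likelihood
from .thi import LabeledDataset

__all__ = ["LassoPath", "fit_lasso_path", "rank_factors", "select_lambda_cv"]

#: coefficients with absolute value below this are treated as zero
ZERO_TOL = 1e-8


@dataclass
class LassoPath:
    """A fitted L1 path: penalties, standardized coefficients, ranking."""

    lambdas: np.ndarray          # decreasing penalty grid
    coefs: np.ndarray            # (n_features, n_lambdas), standardized scale
    feature_names: list[str]
    family: str
    selected_lambda: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def entry_order(self) -> list[str]:
        return rank_factors(self)

    def coefs_at(self, lam: float) -> np.ndarray:
        """Coefficients at the grid point nearest to ``lam``."""
        return self.coefs[:, int(np.argmin(np.abs(self.lambdas - lam)))]


def _as_xy(data, standardize: bool):
    if isinstance(data, LabeledDataset):
        X = data.X.to_numpy(dtype=float)
        y = np.asarray(data.y, dtype=float)
        names = list(data.feature_names)
    else:
        X, y = data
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd <= 1e-12
    if constant.any():
        dropped = [names[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"dropping constant feature column(s): {dropped}")
        keep = ~constant
        X, mu, sd = X[:, keep], mu[keep], sd[keep]
        names = [n for n, k in zip(names, keep) if k]
    else:
        dropped = []
    if standardize:
        X = (X - mu) / sd
    return X, y, names, dropped


def _l1_logistic(C: float) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                              max_iter=10_000, tol=1e-8, random_state=0)


def _duplicate_groups(X: np.ndarray) -> list[list[int]]:
    """Groups of exactly identical columns (first index is the representative)."""
    groups: list[list[int]] = []
    for j in range(X.shape[1]):
        for g in groups:
            if np.array_equal(X[:, j], X[:, g[0]]):
                g.append(j)
                break
        else:
            groups.append([j])
    return groups


def _lambda_grid(X: np.ndarray, y: np.ndarray, family: str,
                 n_lambdas: int, lambda_min_ratio: float) -> np.ndarray:
    n = X.shape[0]
    if family == "binomial":
        resid = y - y.mean()
    else:
        resid = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid)) / n)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def fit_lasso_path(data, n_lambdas: int = 100, seed: int = 0,
                   family: str = "binomial", standardize: bool = True,
                   lambda_min_ratio: float = 1e-4,
                   lambdas: np.ndarray | None = None) -> LassoPath:
    """Solve the L1 path over a log-spaced penalty grid.

    ``data`` is a LabeledDataset or an (X, y) pair.  The binomial family
    minimises mean log-loss + lambda * ||beta||_1; the gaussian family
    minimises (1/2n)||y - X beta||^2 + lambda * ||beta||_1.  At the
    largest grid penalty the support is empty by construction.
    Deterministic given the data; ``seed`` is stored for provenance.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    X, y, names, dropped = _as_xy(data, standardize)
    n = X.shape[0]
    if family == "binomial":
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("outcome has a single class; cannot fit a binomial path")
    if lambdas is None:
        lambdas = _lambda_grid(X, y, family, n_lambdas, lambda_min_ratio)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambda grid must be decreasing")

    # exactly duplicated columns make the L1 solution non-unique and the
    # solver's pick arbitrary; fit each group once and split the coefficient
    # evenly (the symmetric representative), so entry order stays well-defined
    groups = _duplicate_groups(X)
    reps = [g[0] for g in groups]
    X_fit = X[:, reps]

    rep_coefs = np.zeros((len(reps), lambdas.size))
    if family == "gaussian":
        yc = y - y.mean()
        for j, lam in enumerate(lambdas):
            est = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-10)
            est.fit(X_fit, yc)
            rep_coefs[:, j] = est.coef_
    else:
        for j, lam in enumerate(lambdas):
            est = _l1_logistic(C=1.0 / (n * lam))
            est.fit(X_fit, y)
            rep_coefs[:, j] = est.coef_[0]

    coefs = np.zeros((X.shape[1], lambdas.size))
    for gi, g in enumerate(groups):
        for member in g:
            coefs[member] = rep_coefs[gi] / len(g)

    return LassoPath(
        lambdas=lambdas, coefs=coefs, feature_names=names, family=family,
        metadata={"dropped_constant_columns": dropped, "seed": seed,
                  "standardized": standardize, "n_observations": n,
                  "duplicate_groups": [g for g in groups if len(g) > 1]},
    )


def rank_factors(path: LassoPath) -> list[str]:
    """Factors ordered by path entry: earlier entry (larger penalty) first.

    Ties — identical entry penalty — break by absolute coefficient at the
    selected penalty (largest first; the smallest grid penalty is used if
    none was selected by cross-validation), then by column order.
    """
    nz = np.abs(path.coefs) > ZERO_TOL
    # entry index = first (largest-lambda) grid position with a nonzero coef
    entry_idx = np.where(nz.any(axis=1), nz.argmax(axis=1), path.lambdas.size)
    ref_lam = path.selected_lambda if path.selected_lambda is not None else path.lambdas[-1]
    ref_coefs = np.abs(path.coefs_at(ref_lam))
    order = sorted(range(len(path.feature_names)),
                   key=lambda j: (entry_idx[j], -ref_coefs[j], j))
    return [path.feature_names[j] for j in order]


def select_lambda_cv(data, folds: int = 10, seed: int = 0,
                     n_lambdas: int = 100, lambda_min_ratio: float = 1e-4) -> float:
    """Pick the penalty minimising mean cross-validated binomial deviance.

    Stratified K-fold with a seeded shuffle, so the choice is
    deterministic for a given seed.  Errors if a class has fewer members
    than there are folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y, names, _ = _as_xy(data, standardize=True)
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ValueError(
            f"folds={folds} exceeds the smallest class count {counts.min()}")
    lambdas = _lambda_grid(X, y, "binomial", n_lambdas, lambda_min_ratio)
    n = X.shape[0]
    deviance = np.zeros(lambdas.size)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        for j, lam in enumerate(lambdas):
            est = _l1_logistic(C=1.0 / (len(train) * lam))
            est.fit(X[train], y[train])
            p = est.predict_proba(X[test])[:, 1]
            deviance[j] += -2.0 * log_likelihood(y[test], p)
    deviance /= n
    return float(lambdas[int(np.argmin(deviance))])
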