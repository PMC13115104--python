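"""Training-fold preprocessing: capping, imputation, Box-Cox, min-max.

All statistics are learned with ``fit_*`` on the training split only and
replayed deterministically on validation data with ``apply_*`` — the fitted
state never sees validation rows or outcome labels.

Steps, in pipeline order:

1. cap laboratory values at their clinical upper reference limit;
2. chained-equations imputation (each incomplete feature regressed on all
   others, ridge-penalized, iterated to convergence);
3. Box-Cox power transform with per-feature maximum-likelihood lambda,
   shifted to positivity;
4. min-max scaling to [0, 1], with out-of-range validation values clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort_io import CohortTable, ReferenceRangeMap, log_stage

_EPS_POSITIVE = 1e-6      # positivity margin before Box-Cox
_RIDGE_ALPHA = 1e-3       # penalty of the chained-equation regressions
_IMPUTE_TOL = 1e-3        # convergence: max cell change < tol * feature sd


# ---------------------------------------------------------------- capping

def cap_values(table: CohortTable, ranges: ReferenceRangeMap) -> CohortTable:
    """Cap each mapped feature at its upper reference limit.

    Pure elementwise ``min(value, upper)``; unmapped features and missing
    cells are untouched.
    """
    X = table.X.copy()
    for j, name in enumerate(table.feature_names):
        upper = ranges.get(name)
        if upper is not None:
            col = X[:, j]
            X[:, j] = np.where(np.isnan(col), col, np.minimum(col, upper))
    return table.with_X(X)


def cap_matrix(X: np.ndarray, feature_names: list[str],
               ranges: ReferenceRangeMap) -> np.ndarray:
    X = np.array(X, dtype=float)
    for j, name in enumerate(feature_names):
        upper = ranges.get(name)
        if upper is not None:
            col = X[:, j]
            X[:, j] = np.where(np.isnan(col), col, np.minimum(col, upper))
    return X


# ------------------------------------------------------------- imputation

@dataclass
class ImputerState:
    """Fitted chained-equations imputer.

    ``coefs[j]`` holds the intercept followed by one coefficient per other
    feature for each column that had missing values at fit time; complete
    columns carry no model and are passed through.
    """

    means: np.ndarray
    coefs: dict[int, np.ndarray]
    max_iter: int = 30

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Fill missing cells of ``X`` using the fitted regressions.

        Initial fill is the training mean; columns with a fitted model are
        then refined by iterating the chained regressions (with the frozen
        training coefficients) to a fixed point.
        """
        X = np.array(X, dtype=float)
        mask = np.isnan(X)
        if not mask.any():
            return X
        for j in range(X.shape[1]):
            X[mask[:, j], j] = self.means[j]
        if not self.coefs:
            return X
        for _ in range(self.max_iter):
            delta = 0.0
            for j, beta in self.coefs.items():
                rows = mask[:, j]
                if not rows.any():
                    continue
                others = np.delete(X[rows], j, axis=1)
                pred = beta[0] + others @ beta[1:]
                delta = max(delta, float(np.max(np.abs(pred - X[rows, j]))))
                X[rows, j] = pred
            if delta < 1e-8:
                break
        return X


def _ridge_fit(A: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form ridge regression with unpenalized intercept.

    Returns [intercept, coef...].
    """
    mu_a = A.mean(axis=0)
    mu_b = b.mean()
    Ac = A - mu_a
    bc = b - mu_b
    G = Ac.T @ Ac + alpha * np.eye(A.shape[1])
    coef = np.linalg.solve(G, Ac.T @ bc)
    intercept = mu_b - mu_a @ coef
    return np.concatenate([[intercept], coef])


def fit_imputer(X: np.ndarray, max_iter: int = 30,
                alpha: float = _RIDGE_ALPHA) -> ImputerState:
    """Fit the chained-equations imputer on training data.

    Each feature with missing values is regressed (ridge, closed form) on
    all other features; the sweep over incomplete columns repeats until the
    largest imputed-cell change falls below ``_IMPUTE_TOL`` times the
    feature's observed standard deviation, or ``max_iter`` sweeps.
    """
    X = np.array(X, dtype=float)
    mask = np.isnan(X)
    if mask.all(axis=0).any():
        bad = int(np.where(mask.all(axis=0))[0][0])
        raise ValueError(f"feature column {bad} is entirely missing")
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    incomplete = [j for j in range(X.shape[1]) if mask[:, j].any()]
    for j in range(X.shape[1]):
        X[mask[:, j], j] = means[j]

    coefs: dict[int, np.ndarray] = {}
    for sweep in range(max_iter):
        delta_rel = 0.0
        for j in incomplete:
            obs = ~mask[:, j]
            A_obs = np.delete(X[obs], j, axis=1)
            beta = _ridge_fit(A_obs, X[obs, j], alpha)
            coefs[j] = beta
            rows = mask[:, j]
            others = np.delete(X[rows], j, axis=1)
            pred = beta[0] + others @ beta[1:]
            if rows.any():
                delta_rel = max(delta_rel,
                                float(np.max(np.abs(pred - X[rows, j]))) / sds[j])
            X[rows, j] = pred
        if delta_rel < _IMPUTE_TOL:
            break
    return ImputerState(means=means, coefs=coefs, max_iter=max_iter)


# ---------------------------------------------------------------- Box-Cox

def fit_boxcox(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature positivity shift and maximum-likelihood Box-Cox lambda.

    shift = max(0, eps - min) so all shifted training values are >= eps;
    constant features get lambda = 1 (identity up to an affine map).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("Box-Cox requires complete data; impute first")
    p = X.shape[1]
    shifts = np.zeros(p)
    lambdas = np.ones(p)
    for j in range(p):
        col = X[:, j]
        shifts[j] = max(0.0, _EPS_POSITIVE - float(col.min()))
        shifted = col + shifts[j]
        if np.ptp(shifted) == 0.0:
            log_stage("boxcox_constant_feature", feature=j)
            lambdas[j] = 1.0
            continue
        _, lam = stats.boxcox(shifted)
        lambdas[j] = float(lam)
    return shifts, lambdas


def apply_boxcox(X: np.ndarray, shifts: np.ndarray,
                 lambdas: np.ndarray) -> np.ndarray:
    """((x+shift)^lambda - 1)/lambda, or log(x+shift) at lambda = 0.

    Validation values whose shifted value is non-positive (below the
    training minimum) are clamped to a tiny positive number first.
    """
    X = np.asarray(X, dtype=float) + shifts[np.newaxis, :]
    X = np.maximum(X, 1e-12)
    out = np.empty_like(X)
    for j, lam in enumerate(lambdas):
        if lam == 0.0:
            out[:, j] = np.log(X[:, j])
        else:
            out[:, j] = (np.power(X[:, j], lam) - 1.0) / lam
    return out


# ---------------------------------------------------------------- min-max

def fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def apply_minmax(X: np.ndarray, mins: np.ndarray,
                 maxs: np.ndarray) -> np.ndarray:
    """Scale to [0,1] by the training min/max; unseen values are clipped.

    Constant training columns map to all-zero.
    """
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    out = (X - mins) / safe
    out[:, span == 0] = 0.0
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------- pipeline

@dataclass
class PreprocessModel:
    """Frozen preprocessing state fitted on one training split."""

    feature_names: list[str]
    caps: dict[str, float] = field(default_factory=dict)
    imputer: ImputerState | None = None
    shifts: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Deterministically replay cap -> impute -> Box-Cox -> min-max."""
        X = cap_matrix(X, self.feature_names, ReferenceRangeMap(dict(self.caps)))
        X = self.imputer.apply(X)
        X = apply_boxcox(X, self.shifts, self.lambdas)
        return apply_minmax(X, self.mins, self.maxs)

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "caps": self.caps,
            "imputer": {
                "means": self.imputer.means.tolist(),
                "coefs": {str(k): v.tolist() for k, v in self.imputer.coefs.items()},
                "max_iter": self.imputer.max_iter,
            },
            "shifts": self.shifts.tolist(),
            "lambdas": self.lambdas.tolist(),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PreprocessModel":
        d = json.loads(text)
        imp = ImputerState(
            means=np.array(d["imputer"]["means"]),
            coefs={int(k): np.array(v) for k, v in d["imputer"]["coefs"].items()},
            max_iter=d["imputer"]["max_iter"],
        )
        return cls(
            feature_names=d["feature_names"],
            caps={k: float(v) for k, v in d["caps"].items()},
            imputer=imp,
            shifts=np.array(d["shifts"]),
            lambdas=np.array(d["lambdas"]),
            mins=np.array(d["mins"]),
            maxs=np.array(d["maxs"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessModel":
        return cls.from_json(Path(path).read_text())


def fit_transform_pipeline(
    X_train: np.ndarray,
    feature_names: list[str],
    ranges: ReferenceRangeMap | None = None,
    max_impute_iter: int = 30,
) -> tuple[PreprocessModel, np.ndarray]:
    """Fit the full pipeline on training rows and return transformed rows.

    Outcome labels are never consulted; the returned model replays the
    identical transform on any other matrix via ``apply_pipeline``.
    """
    ranges = ranges or ReferenceRangeMap({})
    caps = {n: ranges.get(n) for n in feature_names if ranges.get(n) is not None}
    X = cap_matrix(X_train, feature_names, ranges)
    imputer = fit_imputer(X, max_iter=max_impute_iter)
    X = imputer.apply(X)
    shifts, lambdas = fit_boxcox(X)
    X = apply_boxcox(X, shifts, lambdas)
    mins, maxs = fit_minmax(X)
    model = PreprocessModel(feature_names=list(feature_names), caps=caps,
                            imputer=imputer, shifts=shifts, lambdas=lambdas,
                            mins=mins, maxs=maxs)
    return model, apply_minmax(X, mins, maxs)


def apply_pipeline(model: PreprocessModel, X: np.ndarray) -> np.ndarray:
    return model.apply(X)
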