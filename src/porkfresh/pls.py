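"""Partial least squares regression (NIPALS), latent-variable selection,
VIP scores and performance metrics.

PLS1/PLS2 is implemented with the classical NIPALS deflation so that the
per-component weights, loadings and scores needed for Wold's VIP statistic
are available exactly as defined.  Coefficients for every truncation
1..A are recoverable from the stored rotation, which makes the RMSECV
curve over latent-variable counts a single fit per cross-validation fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .preprocess import PreprocessingTag

__all__ = [
    "MetricSet",
    "PLSRFit",
    "VIPResult",
    "fit_plsr",
    "predict_plsr",
    "venetian_blinds_folds",
    "select_lvs",
    "rmse",
    "r_squared",
    "compute_metrics",
    "vip_scores",
    "plsda_vip",
    "pearson_pattern",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class MetricSet:
    """RMSE and R^2 on the calibration, cross-validation and prediction
    sets (NaN where a set was not evaluated)."""

    rmsec: float = float("nan")
    rmsecv: float = float("nan")
    rmsep: float = float("nan")
    r2c: float = float("nan")
    r2cv: float = float("nan")
    r2p: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "RMSEC": self.rmsec,
            "RMSECV": self.rmsecv,
            "RMSEP": self.rmsep,
            "R2C": self.r2c,
            "R2CV": self.r2cv,
            "R2P": self.r2p,
        }


@dataclass(frozen=True)
class VIPResult:
    """Variable importance in projection; mean squared score is 1, so
    scores above 1 mark above-average contributors."""

    variables: tuple[str, ...]
    scores: np.ndarray

    def selected(self, threshold: float = 1.0) -> list[str]:
        """Variables with VIP strictly greater than ``threshold``,
        input order preserved."""
        return [
            v for v, s in zip(self.variables, self.scores) if s > threshold
        ]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.variables), name="VIP")


@dataclass(frozen=True)
class PLSRFit:
    """A fitted PLS regression.

    Weights/loadings are stored per latent variable on the centered (and
    optionally autoscaled) data; ``coefficients``/``intercept`` map raw X
    to raw Y directly.
    """

    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    weights: np.ndarray        # (p, A), unit norm columns
    x_loadings: np.ndarray     # (p, A)
    y_loadings: np.ndarray     # (m, A)
    rotation: np.ndarray       # (p, A) = W (P'W)^-1
    ssy: np.ndarray            # (A,) Y-variance captured per component
    coefficients: np.ndarray   # (p, m) on original variable scale
    intercept: np.ndarray      # (m,)
    fitted_values: np.ndarray  # (n_cal, m)
    scaling: str = "center"
    variable_names: tuple[str, ...] = ()
    response_names: tuple[str, ...] = ()
    univariate: bool = True
    preprocessing: PreprocessingTag | None = None
    metrics: MetricSet | None = None

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    def coefficients_for(self, n_lv: int) -> tuple[np.ndarray, np.ndarray]:
        """Raw-scale (coefficients, intercept) using the first ``n_lv``
        latent variables."""
        if not (1 <= n_lv <= self.n_lv):
            raise DomainError(f"n_lv must be in [1, {self.n_lv}]")
        b_scaled = self.rotation[:, :n_lv] @ self.y_loadings[:, :n_lv].T
        b = (b_scaled / self.x_scale[:, None]) * self.y_scale[None, :]
        b0 = self.y_mean - self.x_mean @ b
        return b, b0

    def with_metrics(self, metrics: MetricSet) -> "PLSRFit":
        return replace(self, metrics=metrics)


def _as_2d_y(Y: np.ndarray) -> tuple[np.ndarray, bool]:
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        return Y[:, None], True
    return Y, False


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    scaling: str = "center",
    variable_names: Sequence[str] | None = None,
    response_names: Sequence[str] | None = None,
    preprocessing: PreprocessingTag | None = None,
) -> PLSRFit:
    """NIPALS PLS regression with ``n_lv`` latent variables.

    ``scaling`` is ``"center"`` (mean-centering, the spectral convention)
    or ``"autoscale"`` (unit-variance scaling of X and Y columns, the
    metabolite convention).  Deflation stops early, with a warning, if the
    residual X has no variance left.
    """
    X = np.asarray(X, float)
    Y2, univariate = _as_2d_y(Y)
    n, p = X.shape
    m = Y2.shape[1]
    if Y2.shape[0] != n:
        raise DomainError(f"X has {n} rows but Y has {Y2.shape[0]}")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise DomainError(
            f"n_lv={n_lv} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if scaling not in ("center", "autoscale"):
        raise DomainError(f"unknown scaling {scaling!r}")

    x_mean = X.mean(axis=0)
    y_mean = Y2.mean(axis=0)
    if scaling == "autoscale":
        x_scale = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(x_scale == 0)
        if dead.size:
            names = (
                [variable_names[i] for i in dead[:10]]
                if variable_names is not None
                else dead[:10].tolist()
            )
            raise DomainError(
                f"zero-variance columns under autoscaling: {names}"
            )
        y_scale = Y2.std(axis=0, ddof=1)
        y_scale = np.where(y_scale == 0, 1.0, y_scale)
    else:
        x_scale = np.ones(p)
        y_scale = np.ones(m)

    Xc = (X - x_mean) / x_scale
    Yc = (Y2 - y_mean) / y_scale
    x_sst = float((Xc**2).sum())

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    ssy = np.zeros(n_lv)
    a_done = 0
    for a in range(n_lv):
        if (Xc**2).sum() <= _NIPALS_TOL * max(x_sst, 1.0):
            warnings.warn(
                f"X residual exhausted after {a} latent variables "
                f"(requested {n_lv}); truncating",
                stacklevel=2,
            )
            break
        if m == 1:
            w = Xc.T @ Yc[:, 0]
        else:
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
            w = np.zeros(p)
            for _ in range(_NIPALS_MAX_ITER):
                w_new = Xc.T @ u
                nw = np.linalg.norm(w_new)
                if nw == 0:
                    break
                w_new /= nw
                t = Xc @ w_new
                q = Yc.T @ t / (t @ t)
                nq = np.linalg.norm(q)
                u_new = Yc @ q / (q @ q) if nq > 0 else u
                if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                    w = w_new
                    u = u_new
                    break
                w, u = w_new, u_new
        nw = np.linalg.norm(w)
        if nw <= _NIPALS_TOL:
            warnings.warn(
                f"no covariance left after {a} latent variables; truncating",
                stacklevel=2,
            )
            break
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _NIPALS_TOL:
            break
        pa = Xc.T @ t / tt
        qa = Yc.T @ t / tt
        Xc -= np.outer(t, pa)
        Yc -= np.outer(t, qa)
        W[:, a], P[:, a], Q[:, a] = w, pa, qa
        ssy[a] = tt * float(qa @ qa)
        a_done = a + 1

    if a_done == 0:
        raise DomainError("PLSR fit failed: X or Y has no usable variance")
    W, P, Q, ssy = W[:, :a_done], P[:, :a_done], Q[:, :a_done], ssy[:a_done]

    # rotation R = W (P'W)^{-1}; P'W is unit upper triangular
    R = np.zeros_like(W)
    for a in range(a_done):
        R[:, a] = W[:, a] - R[:, :a] @ (P[:, :a].T @ W[:, a])

    b_scaled = R @ Q.T
    coefficients = (b_scaled / x_scale[:, None]) * y_scale[None, :]
    intercept = y_mean - x_mean @ coefficients
    fitted = X @ coefficients + intercept

    return PLSRFit(
        n_lv=a_done,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        rotation=R,
        ssy=ssy,
        coefficients=coefficients,
        intercept=intercept,
        fitted_values=fitted,
        scaling=scaling,
        variable_names=tuple(variable_names or ()),
        response_names=tuple(response_names or ()),
        univariate=univariate,
        preprocessing=preprocessing,
    )


def predict_plsr(
    fit: PLSRFit, X_new: np.ndarray, n_lv: int | None = None
) -> np.ndarray:
    """Apply the stored centering/scaling and coefficients; never refits."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != fit.n_variables:
        raise DomainError(
            f"X has {X_new.shape[1]} columns; fit expects {fit.n_variables}"
        )
    if n_lv is None:
        b, b0 = fit.coefficients, fit.intercept
    else:
        b, b0 = fit.coefficients_for(n_lv)
    pred = X_new @ b + b0
    return pred[:, 0] if fit.univariate else pred


def venetian_blinds_folds(n: int, n_splits: int = 10) -> np.ndarray:
    """Interleaved fold assignment with blind thickness 1: sample i goes
    to fold i mod n_splits."""
    if n_splits < 2:
        raise DomainError(f"n_splits must be >= 2, got {n_splits}")
    if n < n_splits:
        raise DomainError(f"need n >= n_splits, got n={n}, splits={n_splits}")
    return np.arange(n) % n_splits


def select_lvs(
    X: np.ndarray,
    Y: np.ndarray,
    max_lv: int,
    n_splits: int = 10,
    scaling: str = "center",
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by venetian-blinds cross-validation.

    Fits each fold once at ``max_lv`` components, evaluates every
    truncation 1..max_lv, and returns the count with the lowest RMSECV
    (ties toward fewer LVs) together with the full RMSECV curve.
    """
    if max_lv < 1:
        raise DomainError("max_lv must be >= 1")
    X = np.asarray(X, float)
    Y2, _ = _as_2d_y(Y)
    n, p = X.shape
    folds = venetian_blinds_folds(n, n_splits)
    min_train = min(int(n - (folds == k).sum()) for k in range(n_splits))
    feasible = min(min_train - 1, p)
    if max_lv > feasible:
        warnings.warn(
            f"max_lv={max_lv} exceeds feasible rank {feasible}; capped",
            stacklevel=2,
        )
        max_lv = feasible

    cv_pred = np.empty((n, max_lv, Y2.shape[1]))
    for k in range(n_splits):
        val = folds == k
        fit = fit_plsr(X[~val], Y2[~val], max_lv, scaling=scaling)
        for a in range(1, max_lv + 1):
            b, b0 = fit.coefficients_for(min(a, fit.n_lv))
            cv_pred[val, a - 1] = X[val] @ b + b0

    curve = np.sqrt(((cv_pred - Y2[:, None, :]) ** 2).mean(axis=(0, 2)))
    best = int(np.argmin(curve)) + 1  # argmin takes the first (fewest LVs)
    return best, curve


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - SSE/SST with SST about the evaluated set's own mean.

    Distinct from squared correlation on prediction sets; NaN (with a
    warning) when the truth is constant.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn("R^2 undefined for constant truth vector", stacklevel=2)
        return float("nan")
    sse = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - sse / sst


def compute_metrics(
    cal: tuple[np.ndarray, np.ndarray] | None = None,
    cv: tuple[np.ndarray, np.ndarray] | None = None,
    pred: tuple[np.ndarray, np.ndarray] | None = None,
) -> MetricSet:
    """Bundle RMSE/R^2 for whichever of the calibration, cross-validation
    and prediction (truth, prediction) pairs are supplied."""
    out: dict[str, float] = {}
    for name, pair in (("c", cal), ("cv", cv), ("p", pred)):
        if pair is None:
            continue
        y, yhat = pair
        out[f"rmse{name}"] = rmse(y, yhat)
        out[f"r2{name}"] = r_squared(y, yhat)
    return MetricSet(**out)


def vip_scores(fit: PLSRFit) -> VIPResult:
    """Wold's VIP: VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a)
    with unit-norm weight vectors; mean squared VIP is 1 by construction.
    """
    total = float(fit.ssy.sum())
    if total <= 0:
        raise DomainError("VIP undefined: model explains no Y variance")
    p = fit.n_variables
    contrib = (fit.weights**2) @ fit.ssy
    scores = np.sqrt(p * contrib / total)
    names = fit.variable_names or tuple(f"x{j}" for j in range(p))
    return VIPResult(tuple(names), scores)


def plsda_vip(
    X: np.ndarray,
    class_labels: Sequence,
    n_lv: int | None = None,
    variable_names: Sequence[str] | None = None,
) -> VIPResult:
    """Discriminant-analysis VIP: classes dummy-coded as indicator
    responses, multi-response PLSR on autoscaled X, VIP over the summed
    per-class explained variance."""
    labels = pd.Series(list(class_labels))
    classes = sorted(labels.unique().tolist())
    if len(classes) < 2:
        raise DomainError("PLS-DA needs at least two classes")
    counts = labels.value_counts()
    if (counts == 1).any():
        warnings.warn(
            f"classes with a single sample: "
            f"{counts[counts == 1].index.tolist()}",
            stacklevel=2,
        )
    Y = np.column_stack(
        [(labels == c).to_numpy(float) for c in classes]
    )
    X = np.asarray(X, float)
    n, p = X.shape
    if n_lv is None:
        n_lv = min(10, n - 1, p)
    fit = fit_plsr(
        X, Y, n_lv, scaling="autoscale", variable_names=variable_names
    )
    return vip_scores(fit)


def pearson_pattern(
    metabolites: pd.DataFrame, trait: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each metabolite with one quality trait,
    sorted by |r| descending (the pattern-hunter view).

    Zero-variance metabolites yield NaN.  Design columns (day/replicate/
    observation) are excluded automatically.
    """
    cols = [
        c
        for c in metabolites.columns
        if c not in ("day", "replicate", "observation", "chem_id")
    ]
    data = metabolites[cols]
    trait = pd.Series(np.asarray(trait, float), index=metabolites.index)
    if len(data) < 3:
        raise DomainError("need at least 3 paired observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = data.corrwith(trait)
    out = pd.DataFrame({"variable": r.index, "r": r.to_numpy()})
    out["abs_r"] = out["r"].abs()
    out = (
        out.sort_values(["abs_r", "variable"], ascending=[False, True])
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    return out
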