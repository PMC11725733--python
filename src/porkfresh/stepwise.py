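"""Stepwise ordinary least squares with a collinearity gate.

Classic forward/backward stepwise selection on partial-F p-values
(enter at p <= 0.05, remove at p >= 0.10 by default), followed by a
collinearity gate: the accepted model must have every variance inflation
factor strictly below 10 and every condition index strictly below 15.
If the converged model violates the gate, the most recently entered
violating term is dropped and selection resumes; every step is logged.

Condition indices follow the convention of scaling each design column
(intercept included) to unit Euclidean length before taking eigenvalues
of the cross-product matrix, so the leading index is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .equations import LinearEquation
from .errors import DomainError

__all__ = [
    "OLSFit",
    "StepwiseResult",
    "ols_fit",
    "vif",
    "condition_indices",
    "stepwise_select",
]


@dataclass(frozen=True)
class OLSFit:
    """Least-squares fit summary (intercept always included)."""

    intercept: float
    coefficients: pd.Series
    r2: float
    resid_var: float
    pvalues: pd.Series  # per non-intercept term (t-test == partial F)
    fvalue: float


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of stepwise selection plus the collinearity diagnostics."""

    terms: tuple[str, ...]  # in entry order
    intercept: float
    coefficients: dict[str, float]
    r2: float
    vif: dict[str, float]
    condition_indices: np.ndarray
    accepted: bool
    trace: tuple[dict, ...] = field(default_factory=tuple)

    def equation(self, name: str) -> LinearEquation:
        return LinearEquation(name, self.intercept, dict(self.coefficients))


def _design(X: pd.DataFrame) -> np.ndarray:
    return sm.add_constant(np.asarray(X, float), has_constant="add")


def ols_fit(X: pd.DataFrame | np.ndarray, y) -> OLSFit:
    """OLS with intercept via statsmodels; errors on singular designs."""
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    A = _design(X)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise DomainError("singular design matrix")
    if A.shape[0] <= A.shape[1]:
        raise DomainError(
            f"need n > predictors + 1 (n={A.shape[0]}, p={A.shape[1] - 1})"
        )
    res = sm.OLS(y, A).fit()
    names = [str(c) for c in X.columns]
    return OLSFit(
        intercept=float(res.params[0]),
        coefficients=pd.Series(res.params[1:], index=names),
        r2=float(res.rsquared),
        resid_var=float(res.mse_resid),
        pvalues=pd.Series(res.pvalues[1:], index=names),
        fvalue=float(res.fvalue) if res.df_model > 0 else float("nan"),
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) from regressing
    predictor j on the others (with intercept).  Perfect collinearity is
    reported as ``inf``."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise DomainError("VIF needs at least 2 predictors")
    values = np.asarray(X, float)
    if np.any(values.std(axis=0) == 0):
        raise DomainError("VIF undefined for constant predictors")
    out = {}
    for j, name in enumerate(X.columns):
        others = np.delete(values, j, axis=1)
        A = sm.add_constant(others, has_constant="add")
        yj = values[:, j]
        resid = yj - A @ np.linalg.lstsq(A, yj, rcond=None)[0]
        sst = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst
        out[str(name)] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def condition_indices(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Condition indices of the intercept-augmented design.

    Columns (intercept included) are scaled to unit Euclidean length;
    CI_k = sqrt(lambda_max / lambda_k) of the scaled cross-product,
    sorted ascending so the first index is exactly 1.
    """
    A = _design(pd.DataFrame(X))
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise DomainError("design has a zero column")
    A = A / norms
    lam = np.linalg.eigvalsh(A.T @ A)
    if lam[0] <= 1e-12 * lam[-1]:
        raise DomainError("design is rank deficient")
    ci = np.sqrt(lam[-1] / lam)
    return np.sort(ci)


def _gate(
    X: pd.DataFrame, terms: list[str], vif_max: float, ci_max: float
) -> tuple[bool, dict[str, float], np.ndarray, list[str]]:
    """Evaluate the collinearity gate; returns (passed, vifs, cis,
    violating terms in entry order)."""
    if not terms:
        return False, {}, np.array([1.0]), []
    sub = X[terms]
    vifs = (
        vif(sub).to_dict()
        if len(terms) >= 2
        else {terms[0]: 1.0}
    )
    cis = condition_indices(sub)
    violating = [t for t in terms if vifs[t] >= vif_max]
    passed = (
        max(vifs.values()) < vif_max and float(cis.max()) < ci_max
    )
    if not passed and not violating:
        violating = list(terms)  # CI violation: no single-term attribution
    return passed, vifs, cis, violating


def stepwise_select(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    vif_max: float = 10.0,
    ci_max: float = 15.0,
) -> StepwiseResult:
    """Forward/backward stepwise OLS with a post-convergence
    collinearity gate.

    Entry: the candidate with the smallest partial-F p-value joins if
    p <= ``p_enter``.  Removal: any included term with p >= ``p_remove``
    leaves (largest first).  After convergence the VIF/CI gate is applied;
    on failure the most recently entered violating term is removed and
    selection resumes (re-entry of removed terms stays possible through
    the normal entry rule, but a gate-removed term is barred).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if X.shape[1] == 0:
        raise DomainError("candidate set is empty")
    if not (0 < p_enter < p_remove):
        raise DomainError("need 0 < p_enter < p_remove")

    selected: list[str] = []
    barred: set[str] = set()
    trace: list[dict] = []

    def try_fit(terms: list[str]) -> OLSFit:
        return ols_fit(X[terms], y)

    max_steps = 4 * X.shape[1] + 8
    for _ in range(max_steps):
        changed = False
        # entry
        best_p, best_term = None, None
        for cand in X.columns:
            if cand in selected or cand in barred:
                continue
            try:
                fit = try_fit(selected + [cand])
            except DomainError:
                continue  # singular with this candidate
            pval = float(fit.pvalues[cand])
            if best_p is None or pval < best_p:
                best_p, best_term = pval, cand
        if best_term is not None and best_p <= p_enter:
            selected.append(best_term)
            trace.append(
                {"action": "enter", "term": best_term, "p": best_p}
            )
            changed = True
        # removal
        while len(selected) > 0:
            fit = try_fit(selected)
            worst = fit.pvalues.idxmax()
            worst_p = float(fit.pvalues[worst])
            if worst_p >= p_remove:
                selected.remove(worst)
                trace.append(
                    {"action": "remove", "term": worst, "p": worst_p}
                )
                changed = True
            else:
                break
        if changed:
            continue
        # converged: collinearity gate
        passed, vifs, cis, violating = _gate(X, selected, vif_max, ci_max)
        if passed or not selected:
            break
        drop = violating[-1] if violating else selected[-1]
        # most recently entered violating term
        for term in reversed(selected):
            if term in violating:
                drop = term
                break
        selected.remove(drop)
        barred.add(drop)
        trace.append(
            {
                "action": "gate-remove",
                "term": drop,
                "max_vif": max(vifs.values()) if vifs else float("nan"),
                "max_ci": float(cis.max()),
            }
        )

    if selected:
        fit = try_fit(selected)
        passed, vifs, cis, _ = _gate(X, selected, vif_max, ci_max)
        return StepwiseResult(
            terms=tuple(selected),
            intercept=fit.intercept,
            coefficients={t: float(fit.coefficients[t]) for t in selected},
            r2=fit.r2,
            vif=vifs,
            condition_indices=cis,
            accepted=passed,
            trace=tuple(trace),
        )
    return StepwiseResult(
        terms=(),
        intercept=float(np.mean(y)),
        coefficients={},
        r2=0.0,
        vif={},
        condition_indices=np.array([1.0]),
        accepted=False,
        trace=tuple(trace),
    )
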