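"""Non-nested model comparison: does one outcome's tract model transfer?

Given the tract sets selected separately for the two learning outcomes, the
transfer analysis asks whether the predictors selected for one outcome can
explain variance in the other outcome beyond what that outcome's own
("original") model already explains.  Two complementary tests are provided:

* The Cox test (Pesaran's linear-model formulation).  Step one fits the
  original model and takes its fitted values; step two regresses those
  fitted values on the competing predictors.  The statistic compares the
  competing model's residual variance with what it should be if the
  original model were correct; under the null "the original model Z is
  correct / X adds nothing beyond Z" it is asymptotically standard normal.
  The z is negative when the competing predictors explain leftover
  variance.
* The Davidson-MacKinnon J-test: augment the original model with the
  competing model's fitted values and t-test that coefficient.

Both follow the convention: ``cox_test(y, X, Z)`` asks "do X's predictors
add beyond Z's model of y"; rejection means they do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model_selection import SelectionResult

__all__ = [
    "OlsFit",
    "NonNestedResult",
    "ols_fit",
    "cox_test",
    "j_test",
    "transfer_r2",
    "run_transfer_analysis",
]


@dataclass
class OlsFit:
    predictor_labels: list[str]
    coefficients: np.ndarray      # includes the intercept first
    fitted_values: np.ndarray
    residuals: np.ndarray
    ssr: float
    sigma2: float                 # ssr / n (ML scale, as the Cox statistic uses)
    n: int
    hat_basis: np.ndarray         # orthonormal basis of the design column space


def _design(X: Optional[np.ndarray], n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if X is None or X.size == 0:
        return ones
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        X = X.T
    return np.hstack([ones, X])


def ols_fit(y: np.ndarray, X: Optional[np.ndarray], labels: Optional[list[str]] = None) -> OlsFit:
    """OLS with an intercept; projections via an orthonormal design basis."""
    y = np.asarray(y, float)
    n = y.shape[0]
    D = _design(X, n)
    Q, R = np.linalg.qr(D)
    coef = np.linalg.lstsq(D, y, rcond=None)[0]
    fitted = Q @ (Q.T @ y)
    resid = y - fitted
    ssr = float(resid @ resid)
    return OlsFit(
        predictor_labels=list(labels or []),
        coefficients=coef,
        fitted_values=fitted,
        residuals=resid,
        ssr=ssr,
        sigma2=ssr / n,
        n=n,
        hat_basis=Q,
    )


@dataclass
class NonNestedResult:
    method: str                   # "cox" | "jtest"
    direction: str                # human-readable "does B add beyond A"
    statistic: float              # z (cox) or t (jtest)
    p: float                      # two-sided
    n: int
    model_a_labels: list[str]     # the original model's predictors (Z)
    model_b_labels: list[str]     # the competing predictors (X)
    small_sample: bool = False    # n < 100: asymptotic z is a caveat


def _check_non_nested(X: np.ndarray, Z: np.ndarray, n: int) -> None:
    dx, dz = _design(X, n), _design(Z, n)
    both = np.hstack([dx, dz])
    rank_x = np.linalg.matrix_rank(dx)
    rank_z = np.linalg.matrix_rank(dz)
    rank_both = np.linalg.matrix_rank(both)
    if rank_both == rank_z or rank_both == rank_x:
        raise ValueError("designs are nested (one column space contains the other)")


def cox_test(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    labels_x: Optional[list[str]] = None,
    labels_z: Optional[list[str]] = None,
) -> NonNestedResult:
    """Cox test of whether X's predictors add beyond the original model Z.

    Null hypothesis: the original model (y ~ Z) is correct and X explains
    nothing beyond it.  The original model's fitted values are regressed on
    X; the statistic compares sigma2_X with its value implied by the
    original model.  Asymptotically N(0,1) under the null; z < 0 when X
    explains leftover variance.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if Z.shape[0] != y.shape[0]:
        Z = Z.T
    n = y.shape[0]
    if n <= X.shape[1] + Z.shape[1]:
        raise ValueError("too few observations for the two designs")
    _check_non_nested(X, Z, n)
    fit_z = ols_fit(y, Z)       # the original model
    fit_x = ols_fit(y, X)       # the competing model
    yhat_z = fit_z.fitted_values
    Qx = fit_x.hat_basis
    Qz = fit_z.hat_basis
    # step two: regress the original model's fitted values on X
    w = yhat_z - Qx @ (Qx.T @ yhat_z)            # M_X yhat_Z
    sigma2_xz = fit_z.sigma2 + float(w @ w) / n  # residual variance of the X
    # model implied by "Z correct"
    c = (n / 2.0) * np.log(fit_x.sigma2 / sigma2_xz)
    mzw = w - Qz @ (Qz.T @ w)                    # M_Z M_X yhat_Z
    v = fit_z.sigma2 * float(w @ mzw) / sigma2_xz**2
    if v <= 0:
        raise ValueError("numerically degenerate Cox variance (v <= 0)")
    z = float(c / np.sqrt(v))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return NonNestedResult(
        method="cox",
        direction="do X's predictors add beyond Z",
        statistic=z,
        p=p,
        n=n,
        model_a_labels=list(labels_z or []),
        model_b_labels=list(labels_x or []),
        small_sample=n < 100,
    )


def j_test(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    labels_x: Optional[list[str]] = None,
    labels_z: Optional[list[str]] = None,
    condition_threshold: float = 1e8,
) -> NonNestedResult:
    """Davidson-MacKinnon J-test: t-test on X's fitted values added to Z's model."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if Z.shape[0] != y.shape[0]:
        Z = Z.T
    n = y.shape[0]
    _check_non_nested(X, Z, n)
    yhat_x = ols_fit(y, X).fitted_values
    D = np.hstack([_design(Z, n), yhat_x[:, None]])
    if np.linalg.cond(D) > condition_threshold:
        raise ValueError("X's fitted values are collinear with Z's columns")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = n - Z.shape[1] - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(D.T @ D)
    t = float(coef[-1] / np.sqrt(cov[-1, -1]))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return NonNestedResult(
        method="jtest",
        direction="do X's predictors add beyond Z",
        statistic=t,
        p=p,
        n=n,
        model_a_labels=list(labels_z or []),
        model_b_labels=list(labels_x or []),
        small_sample=n < 100,
    )


def transfer_r2(y_other: np.ndarray, predictors: Optional[np.ndarray]) -> float:
    """OLS R^2 of one outcome on the tracts selected for the other outcome."""
    y = np.asarray(y_other, float)
    if predictors is None or np.size(predictors) == 0:
        return 0.0
    fit = ols_fit(y, predictors)
    sst = float(np.sum((y - y.mean()) ** 2))
    return float(1.0 - fit.ssr / sst) if sst > 0 else 0.0


def _standardized_columns(feature_table: pd.DataFrame, tracts: list[str]) -> np.ndarray:
    X = feature_table[tracts].to_numpy(float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def run_transfer_analysis(
    outcomes: pd.DataFrame,
    selection_drawing: SelectionResult,
    selection_recognition: SelectionResult,
    feature_table: pd.DataFrame,
) -> dict:
    """Both-direction transfer report: Cox + J tests and transfer R^2 values.

    ``outcomes`` must have columns ``drawing`` and ``recognition`` indexed by
    participant, aligned with ``feature_table``.  Directions:

    * "drawing_to_recognition": do the drawing-selected tracts add beyond
      the original recognition model (response: recognition learning)?
    * "recognition_to_drawing": the converse.
    """
    report: dict = {"tests": [], "transfer_r2": {}, "original_r2": {}, "status": {}}
    sels = {"drawing": selection_drawing, "recognition": selection_recognition}
    for direction, (other, own) in {
        "drawing_to_recognition": ("drawing", "recognition"),
        "recognition_to_drawing": ("recognition", "drawing"),
    }.items():
        y = outcomes[own].reindex(feature_table.index).to_numpy(float)
        own_sel, other_sel = sels[own], sels[other]
        report["original_r2"][own] = own_sel.r2
        if not other_sel.selected_tracts:
            report["transfer_r2"][direction] = 0.0
            report["status"][direction] = "skipped: empty transfer predictor set"
            continue
        Xcols = _standardized_columns(feature_table, other_sel.selected_tracts)
        report["transfer_r2"][direction] = transfer_r2(y, Xcols)
        if not own_sel.selected_tracts:
            report["status"][direction] = "skipped: empty original predictor set"
            continue
        Zcols = _standardized_columns(feature_table, own_sel.selected_tracts)
        label = f"{direction}: do the {other}-selected tracts add beyond the original {own} model"
        try:
            for res in (
                cox_test(y, Xcols, Zcols, other_sel.selected_tracts, own_sel.selected_tracts),
                j_test(y, Xcols, Zcols, other_sel.selected_tracts, own_sel.selected_tracts),
            ):
                res.direction = label
                report["tests"].append(res)
            report["status"][direction] = "ok"
        except ValueError as exc:
            report["status"][direction] = f"skipped: {exc}"
    return report
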