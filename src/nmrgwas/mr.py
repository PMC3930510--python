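"""Mendelian randomization follow-up: 2SLS, Wald ratio, Durbin-Hausman, power.

A SNP that robustly shifts a metabolite level can serve as an instrumental
variable to probe whether the metabolite causally affects a clinical trait
(e.g. urinary lysine and kidney function). This module implements the
single-instrument toolkit: first-stage strength (F-statistic), the one-sample
two-stage least-squares estimator and its two-sample Wald-ratio analogue, the
regression-based Durbin-Hausman comparison of OLS and 2SLS, and analytic
power / required sample size for the 2SLS test.

Exposure and outcome preprocessing (e.g. log transformation, age/sex
correction of eGFR) is the caller's responsibility; functions take ready
numeric vectors, and units of the causal effect follow the units supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MRResult",
    "first_stage",
    "tsls",
    "wald_ratio",
    "durbin_hausman",
    "mr_power",
    "required_n",
    "instrument_confounder_check",
    "WeakInstrumentError",
]


class WeakInstrumentError(ValueError):
    """Raised when the instrument-exposure effect is too small to invert."""


@dataclass
class MRResult:
    """Instrumental-variable estimate with its OLS counterpart."""

    beta_ols: float | None
    se_ols: float | None
    beta_iv: float
    se_iv: float
    p_iv: float
    f_stat: float | None = None
    dh_stat: float | None = None
    dh_p: float | None = None
    mode: str = "one_sample"
    n: int | None = None


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])


def _ols(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, cov, resid, dof


def first_stage(g, x, covariates=None) -> dict:
    """First-stage regression of the exposure on the instrument.

    Returns the instrument's coefficient, its F-statistic (t² for a single
    instrument), and the fitted exposure used by 2SLS. A monomorphic
    instrument is an error; a perfect fit is flagged degenerate with
    infinite F.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    n = g.size
    if np.var(g) <= 1e-12:
        raise ValueError("monomorphic instrument: no dosage variance")
    C = _design(n, covariates)
    X = np.column_stack([C, g])
    if n <= X.shape[1] + 1:
        raise ValueError("not enough samples for the first-stage model")
    coef, cov, resid, dof = _ols(X, x)
    b = float(coef[-1])
    se = float(np.sqrt(cov[-1, -1]))
    degenerate = float(resid @ resid) <= 1e-12 * float(x @ x)
    f = np.inf if degenerate or se == 0 else (b / se) ** 2
    return {
        "beta_gx": b,
        "se_gx": se,
        "f_stat": float(f),
        "fitted": X @ coef,
        "residual": resid,
        "degenerate": bool(degenerate),
    }


def tsls(g, x, y, covariates=None, weak_tol: float = 1e-10) -> MRResult:
    """One-sample two-stage least squares with a single instrument.

    The exposure is replaced by its first-stage fit; the second-stage
    standard error uses the standard 2SLS correction (residuals formed with
    the observed exposure, not the fitted one). The plain OLS estimate of y
    on x is reported alongside for comparison.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.size
    fs = first_stage(g, x, covariates)
    if abs(fs["beta_gx"]) < weak_tol:
        raise WeakInstrumentError("instrument-exposure effect indistinguishable from zero")
    C = _design(n, covariates)
    # second stage on fitted exposure
    X2 = np.column_stack([C, fs["fitted"]])
    coef2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    beta_iv = float(coef2[-1])
    # 2SLS SE correction: sigma^2 from residuals with the *observed* exposure
    Xs = np.column_stack([C, x])
    resid_struct = y - Xs @ np.append(coef2[:-1], beta_iv)
    dof = n - X2.shape[1]
    sigma2 = float(resid_struct @ resid_struct) / dof
    cov_iv = sigma2 * np.linalg.pinv(X2.T @ X2)
    se_iv = float(np.sqrt(cov_iv[-1, -1]))
    p_iv = float(2 * stats.t.sf(abs(beta_iv) / se_iv, dof)) if se_iv > 0 else 0.0
    # OLS comparison fit
    coef_o, cov_o, _, _ = _ols(Xs, y)
    return MRResult(
        beta_ols=float(coef_o[-1]),
        se_ols=float(np.sqrt(cov_o[-1, -1])),
        beta_iv=beta_iv,
        se_iv=se_iv,
        p_iv=max(p_iv, 1e-320),
        f_stat=fs["f_stat"],
        mode="one_sample",
        n=n,
    )


def wald_ratio(b_gx: float, se_gx: float, b_gy: float, se_gy: float) -> MRResult:
    """Two-sample MR from harmonized summary statistics.

    beta_iv = b_GY / b_GX; the standard error follows from the first-order
    delta method for a ratio of independent estimates.
    """
    if abs(b_gx) < 1e-12:
        raise WeakInstrumentError("instrument-exposure effect is zero")
    beta_iv = b_gy / b_gx
    var = (se_gy**2) / b_gx**2 + (b_gy**2) * (se_gx**2) / b_gx**4
    se_iv = float(np.sqrt(var))
    if se_iv > 0:
        p_iv = float(2 * stats.norm.sf(abs(beta_iv) / se_iv))
    else:
        p_iv = 0.0 if beta_iv != 0 else 1.0
    return MRResult(
        beta_ols=None, se_ols=None,
        beta_iv=float(beta_iv), se_iv=se_iv, p_iv=max(p_iv, 1e-320),
        mode="two_sample",
    )


def durbin_hausman(g, x, y, covariates=None) -> tuple[float, float]:
    """Durbin-Hausman exogeneity test (control-function form).

    Augments the y-on-x regression with the first-stage residual and t-tests
    its coefficient: a significant coefficient means OLS and 2SLS disagree,
    i.e. the exposure is endogenous. Returns (dh_stat, two-sided p).
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.size
    fs = first_stage(g, x, covariates)
    C = _design(n, covariates)
    X = np.column_stack([C, x, fs["residual"]])
    coef, cov, _, dof = _ols(X, y)
    se = float(np.sqrt(cov[-1, -1]))
    t = coef[-1] / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), dof))
    return float(t), p


def mr_power(
    n: int,
    r2_gx: float,
    beta_causal: float,
    var_x: float = 1.0,
    var_y: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Analytic power of the single-instrument 2SLS test.

    The Wald statistic is asymptotically non-central chi-squared with one
    degree of freedom and non-centrality
    lambda = n * r2_gx * beta² * var_x / var_y.
    """
    if not (0 < r2_gx < 1):
        raise ValueError("r2_gx must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    lam = n * r2_gx * beta_causal**2 * var_x / var_y
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else float(alpha)


def required_n(
    target_power: float = 0.8,
    r2_gx: float = 0.01,
    beta_causal: float = 0.1,
    var_x: float = 1.0,
    var_y: float = 1.0,
    alpha: float = 0.05,
    n_max: int = 10**9,
) -> int:
    """Smallest sample size achieving ``target_power`` (monotone bisection)."""
    if beta_causal == 0:
        raise ValueError("zero causal effect: target power unattainable")
    if not (alpha < target_power < 1):
        raise ValueError("target power must lie in (alpha, 1)")
    lo, hi = 1, 2
    while mr_power(hi, r2_gx, beta_causal, var_x, var_y, alpha) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError("required sample size exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if mr_power(mid, r2_gx, beta_causal, var_x, var_y, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def instrument_confounder_check(g, confounders, names=None, alpha: float = 0.05):
    """Association tests of the instrument against candidate confounders.

    The one implementable piece of the qualitative MR assumption audit: a
    valid instrument should not associate with known confounders of the
    exposure-outcome relation. Reported for inspection; not a gate.
    """
    import pandas as pd

    g = np.asarray(g, dtype=float)
    Cf = np.asarray(confounders, dtype=float)
    if Cf.ndim == 1:
        Cf = Cf[:, None]
    if names is None:
        names = [f"confounder{i}" for i in range(Cf.shape[1])]
    rows = []
    for j, name in enumerate(names):
        c = Cf[:, j]
        r = np.corrcoef(g, c)[0, 1]
        n = g.size
        t = r * np.sqrt((n - 2) / max(1 - r * r, 1e-12))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        rows.append({"confounder": name, "r": float(r), "p": p, "flag": p < alpha})
    return pd.DataFrame(rows)
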