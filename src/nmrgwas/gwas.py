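"""Per-feature association scans, covariate selection and multiple-testing tools.

Each metabolome feature is regressed on SNP dosage (expected allele count in
[0, 2]) plus an intercept and the feature's selected covariates, by ordinary
least squares. Association across many SNPs (or many features) is computed by
the Frisch–Waugh–Lovell decomposition: covariates are projected out of both
the phenotype and the dosages once, after which every SNP reduces to a simple
regression — algebraically identical to the full OLS fit, including the
residual degrees of freedom.

The multiple-testing burden across correlated features uses the eigenvalue
(simpleM) estimate of the effective number of tests: the number of principal
components needed to capture a fixed fraction (default 99.5%) of the
feature-correlation variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import FeatureMatrix

__all__ = [
    "CandidateFactor",
    "select_covariates",
    "associate",
    "associate_matrix",
    "effective_tests",
    "thresholds",
    "SUGGESTIVE_P",
]

#: conventional genome-wide suggestive threshold
SUGGESTIVE_P = 5e-8

_MONO_TOL = 1e-12


@dataclass
class CandidateFactor:
    """One candidate confounding factor (age, sex, diet PC, creatinine, ...)."""

    name: str
    values: np.ndarray
    kind: str = "continuous"  # continuous | binary | categorical

    def design(self) -> pd.DataFrame:
        v = np.asarray(self.values)
        if self.kind == "categorical":
            d = pd.get_dummies(pd.Series(v), prefix=self.name, drop_first=True)
            return d.astype(float)
        return pd.DataFrame({self.name: v.astype(float)})


def _as_design(factors) -> pd.DataFrame:
    if isinstance(factors, pd.DataFrame):
        return factors.astype(float)
    return pd.concat([f.design() for f in factors], axis=1)


def select_covariates(y, factors, alpha: float | None = None) -> list[str]:
    """Forward stepwise covariate selection for one feature.

    Repeatedly add the candidate factor with the smallest conditional P-value
    (t-test in the model containing the already-selected factors) while that
    P-value is below ``alpha`` (default the Bonferroni level 0.05/#factors).
    Ties break by factor name; factors collinear with the current selection
    are skipped with a warning.
    """
    X = _as_design(factors)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate factor")
    if alpha is None:
        alpha = 0.05 / X.shape[1]
    y = np.asarray(y, dtype=float)
    n = y.size
    selected: list[str] = []
    remaining = sorted(X.columns)
    while remaining:
        base = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in selected])
        Q, _ = np.linalg.qr(base)
        y_r = y - Q @ (Q.T @ y)
        best_name, best_p = None, np.inf
        drop: list[str] = []
        for name in remaining:
            x = X[name].to_numpy()
            x_r = x - Q @ (Q.T @ x)
            xss = float(x_r @ x_r)
            if xss / max(float(x @ x), 1.0) < 1e-10:
                drop.append(name)
                continue
            beta = float(x_r @ y_r) / xss
            rss = float(y_r @ y_r) - beta * beta * xss
            df = n - base.shape[1] - 1
            if df <= 0 or rss <= 0:
                p = 0.0
            else:
                se = np.sqrt(rss / df / xss)
                p = 2.0 * stats.t.sf(abs(beta) / se, df)
            if p < best_p:  # ties keep the alphabetically first (sorted order)
                best_name, best_p = name, p
        for name in drop:
            warnings.warn(f"factor {name!r} collinear with selection; dropped", stacklevel=2)
            remaining.remove(name)
        if best_name is None or best_p >= alpha:
            break
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


def _residualize(M: np.ndarray, covariates) -> tuple[np.ndarray, int]:
    """Project intercept + covariates out of the columns of M.

    Returns the residual matrix and the number of projected columns
    (model rank of the nuisance design).
    """
    n = M.shape[0]
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, R = np.linalg.qr(C)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
    Q = Q[:, keep]
    return M - Q @ (Q.T @ M), Q.shape[1]


def associate_matrix(features, dosages, covariates=None):
    """OLS association of every feature against every SNP.

    Parameters
    ----------
    features : DataFrame (n x F) or array
    dosages : DataFrame (n x S) or array, values in [0, 2]
    covariates : optional DataFrame/array shared by all features

    Returns
    -------
    dict with (F x S) arrays ``beta``, ``se``, ``t``, ``p``, ``z`` plus the
    residual degrees of freedom ``df`` and boolean mask ``monomorphic``.
    """
    Y = np.asarray(features, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if G.shape[0] != n:
        raise ValueError("features and dosages disagree on sample count")
    Yr, k = _residualize(Y, covariates)
    Gr, _ = _residualize(G, covariates)
    df = n - k - 1
    if df <= 0:
        raise ValueError(f"not enough samples for the model (n={n}, nuisance rank={k})")
    gss = np.einsum("ij,ij->j", Gr, Gr)
    mono = gss <= _MONO_TOL * n
    gss_safe = np.where(mono, 1.0, gss)
    yss = np.einsum("ij,ij->j", Yr, Yr)
    cross = Yr.T @ Gr  # F x S
    beta = cross / gss_safe[None, :]
    rss = np.maximum(yss[:, None] - beta * beta * gss_safe[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gss_safe[None, :])
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta = np.where(mono[None, :], 0.0, beta)
    p = np.where(mono[None, :], 1.0, p)
    t = np.where(mono[None, :], 0.0, t)
    z = signed_z(beta, p, t)
    return {"beta": beta, "se": se, "t": t, "p": p, "z": z, "df": df, "monomorphic": mono}


def signed_z(beta, p, t=None):
    """Signed normal-scale statistic z = sign(beta) * Phi^-1(1 - p/2).

    Makes test statistics comparable across cohorts of different size. Where
    p underflows double precision the t statistic itself is used (the two
    coincide for large samples).
    """
    p = np.asarray(p, dtype=float)
    sign = np.sign(np.asarray(beta, dtype=float))
    with np.errstate(divide="ignore"):
        z = sign * stats.norm.isf(np.clip(p, 1e-290, 1.0) / 2)
    if t is not None:
        z = np.where(p < 1e-290, t, z)
    return z


def associate(
    feature_values,
    dosages,
    covariates=None,
    snp_meta: pd.DataFrame | None = None,
    feature_label=None,
) -> pd.DataFrame:
    """Association records of one feature against a panel of SNPs.

    Returns a DataFrame with columns ``snp_id chr pos feature_label beta se
    z p n flag``. Monomorphic SNPs get beta=0, p=1 and flag ``monomorphic``;
    a perfect fit (zero residual) is flagged ``degenerate`` with p set NaN.
    """
    y = np.asarray(feature_values, dtype=float)
    if isinstance(dosages, pd.DataFrame):
        snp_ids = list(dosages.columns)
        G = dosages.to_numpy(dtype=float)
    else:
        G = np.asarray(dosages, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        snp_ids = [f"snp{j}" for j in range(G.shape[1])]
    res = associate_matrix(y, G, covariates)
    beta, se, p, z = res["beta"][0], res["se"][0], res["p"][0], res["z"][0]
    flags = np.where(res["monomorphic"], "monomorphic", "")
    degen = ~res["monomorphic"] & ~((se > 0) & np.isfinite(se))
    # zero-residual fits: slope exact, no sampling noise to form a P-value
    p = np.where(degen, np.nan, p)
    z = np.where(degen, np.nan, z)
    flags = np.where(degen, "degenerate", flags)
    out = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chr": "0",
            "pos": 0,
            "feature_label": feature_label if feature_label is not None else np.nan,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "n": y.size,
            "flag": flags,
        }
    )
    if snp_meta is not None:
        meta = snp_meta.set_index("snp_id")
        out["chr"] = meta.loc[out["snp_id"], "chr"].to_numpy()
        out["pos"] = meta.loc[out["snp_id"], "pos"].to_numpy()
    return out


def effective_tests(m, var_fraction: float = 0.995) -> int:
    """Effective number of independent tests among correlated features.

    Eigendecomposes the feature-feature correlation matrix and returns the
    smallest m such that the top-m eigenvalues capture ``var_fraction`` of
    the total variance (the simpleM estimator).
    """
    if isinstance(m, FeatureMatrix):
        corr = m.data.corr()
    elif isinstance(m, pd.DataFrame):
        corr = m.corr() if not _looks_like_corr(m) else m
    else:
        corr = pd.DataFrame(np.asarray(m, dtype=float))
        if not _looks_like_corr(corr):
            corr = corr.corr()
    C = corr.to_numpy()
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite feature correlations (too much missingness?)")
    if C.shape[0] < 2:
        raise ValueError("need at least two features")
    vals = np.linalg.eigvalsh((C + C.T) / 2)[::-1]
    vals = np.clip(vals, 0.0, None)
    frac = np.cumsum(vals) / vals.sum()
    return int(np.searchsorted(frac, var_fraction - 1e-12) + 1)


def _looks_like_corr(df: pd.DataFrame) -> bool:
    a = df.to_numpy()
    return (
        a.shape[0] == a.shape[1]
        and np.allclose(np.diag(a), 1.0, atol=1e-8)
        and np.all(np.abs(a) <= 1.0 + 1e-8)
    )


def thresholds(
    m_eff_features: int, n_effective_snps: int, n_hits: int | None = None
) -> dict:
    """Decision thresholds of the two-stage design.

    * ``suggestive``: the constant 5e-8 used to admit discovery pairs.
    * ``combined``: Bonferroni for both dimensions, 0.05 / (M_eff_features *
      n_effective_snps), applied to the meta-analysis P-value.
    * ``replication``: 0.05 / n_hits across the discovered independent
      associations (present only when ``n_hits`` is given).
    """
    if m_eff_features < 1 or n_effective_snps < 1:
        raise ValueError("counts must be positive integers")
    out = {
        "suggestive": SUGGESTIVE_P,
        "combined": 0.05 / (m_eff_features * n_effective_snps),
    }
    if n_hits is not None:
        if n_hits < 1:
            raise ValueError("n_hits must be positive")
        out["replication"] = 0.05 / n_hits
    return out
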