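"""Allelic heterogeneity: multivariate region models with a permutation model P.

Standard clumping keeps only the most significant SNP per locus and ignores
semi-independent secondary signals. To detect them, the feature is modelled
within a 1 Mb window around the lead SNP by forward stepwise selection
minimizing AIC over the region's SNPs. The gain of the selected multivariate
model over the best single-SNP model is summarized as
``R2_diff = R2_full − R2_best_single``, and its significance is assessed by
rerunning the entire stepwise procedure on permuted phenotypes: the model P
is the add-one permutation estimate (b + 1) / (n_perm + 1) of observing an
equal or larger R2_diff by chance.

Replication does not require the same SNPs (LD structure differs between
cohorts) but the same locus: the stepwise + permutation analysis is rerun on
the replication cohort's genotypes over the same window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegionModel", "stepwise_select", "permutation_model_p", "replicate_locus"]


@dataclass
class RegionModel:
    """Selected multivariate SNP model for one locus-feature pair."""

    feature_label: float | str
    window: tuple = (0, 0)
    snps: list[str] = field(default_factory=list)
    betas: dict = field(default_factory=dict)
    conditional_p: dict = field(default_factory=dict)
    r2: float = 0.0
    r2_diff: float = 0.0
    aic: float = float("nan")
    model_p: float | None = None
    best_single_snp: str | None = None
    skipped_collinear: list[str] = field(default_factory=list)


def _aic(n: int, rss: float, n_params: int) -> float:
    # Gaussian log-likelihood profile: n*log(RSS/n) + 2 * (#coefficients + sigma)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (n_params + 1)


def _residualize_y(y, covariates) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    return y - Q @ (Q.T @ y)


def _forward_aic(
    y_r: np.ndarray,
    G: np.ndarray,
    snp_ids: list[str],
    max_terms: int,
    collinear_r2: float = 0.99,
    collect_skipped: bool = False,
):
    """Forward AIC selection on a covariate-residualized phenotype.

    Returns (selected index list, R2_full, R2_best_single, aic, skipped).
    Implemented with incremental Gram-Schmidt: after each addition the
    remaining candidate SNPs are orthogonalized against the accepted basis,
    so each step costs one pass over the region.
    """
    n, m = G.shape
    tss = float(y_r @ y_r)
    if tss <= 0:
        return [], 0.0, 0.0, _aic(n, tss, 0), []
    Gc = G - G.mean(axis=0, keepdims=True)
    norms0 = np.einsum("ij,ij->j", Gc, Gc)
    alive = norms0 > 1e-12 * n  # polymorphic
    Gw = Gc.copy()
    yw = y_r.copy()
    rss = tss
    selected: list[int] = []
    skipped: list[str] = []
    best_single_rss = None
    aic_cur = _aic(n, rss, 0)
    while len(selected) < max_terms:
        norms = np.einsum("ij,ij->j", Gw, Gw)
        # skip candidates (nearly) collinear with the accepted set
        collinear = alive & (norms <= (1.0 - collinear_r2) * norms0)
        if collect_skipped and selected:
            for j in np.flatnonzero(collinear):
                if snp_ids[j] not in skipped:
                    skipped.append(snp_ids[j])
        usable = alive & ~collinear
        if not usable.any():
            break
        cross = yw @ Gw
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(usable, cross * cross / np.where(norms > 0, norms, 1.0), -np.inf)
        j = int(np.argmax(gain))
        rss_new = rss - float(gain[j])
        if best_single_rss is None:
            best_single_rss = tss - float(np.max(np.where(alive, gain, -np.inf)))
        aic_new = _aic(n, rss_new, len(selected) + 1)
        if aic_new >= aic_cur:
            break
        selected.append(j)
        aic_cur = aic_new
        rss = rss_new
        q = Gw[:, j] / np.sqrt(norms[j])
        yw = yw - q * float(q @ yw)
        Gw = Gw - np.outer(q, q @ Gw)
        alive[j] = False
    r2_full = 1.0 - rss / tss
    r2_single = 0.0 if best_single_rss is None else 1.0 - best_single_rss / tss
    return selected, r2_full, r2_single, aic_cur, skipped


def stepwise_select(
    feature_values,
    region_dosages: pd.DataFrame,
    covariates=None,
    max_terms: int = 10,
    window: tuple = (0, 0),
    feature_label="",
) -> RegionModel:
    """Forward stepwise (AIC) multivariate SNP model for one region.

    The feature is first residualized on the covariates; SNPs within the
    window are then added greedily as long as each addition lowers AIC (up
    to ``max_terms``). ``r2_diff`` is measured against the single SNP with
    the smallest marginal P in the window. SNPs nearly collinear
    (r² > 0.99) with the current selection are skipped with a note.
    """
    if region_dosages.shape[1] < 1:
        raise ValueError("region contains no SNPs")
    y_r = _residualize_y(feature_values, covariates)
    G = region_dosages.to_numpy(dtype=float)
    snp_ids = list(region_dosages.columns)
    sel, r2_full, r2_single, aic, skipped = _forward_aic(
        y_r, G, snp_ids, max_terms, collect_skipped=True
    )
    model = RegionModel(
        feature_label=feature_label,
        window=window,
        snps=[snp_ids[j] for j in sel],
        r2=r2_full,
        r2_diff=max(r2_full - r2_single, 0.0),
        aic=aic,
        skipped_collinear=skipped,
    )
    # best single SNP by marginal fit (largest single-SNP R2 = smallest marginal p)
    Gc = G - G.mean(axis=0, keepdims=True)
    norms = np.einsum("ij,ij->j", Gc, Gc)
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(norms > 1e-12, (y_r @ Gc) ** 2 / np.where(norms > 0, norms, 1.0), -np.inf)
    model.best_single_snp = snp_ids[int(np.argmax(gains))]
    if sel:
        X = np.column_stack([np.ones(len(y_r))] + [G[:, j] for j in sel])
        coef, *_ = np.linalg.lstsq(X, y_r, rcond=None)
        resid = y_r - X @ coef
        dof = len(y_r) - X.shape[1]
        sigma2 = float(resid @ resid) / max(dof, 1)
        XtX_inv = np.linalg.pinv(X.T @ X)
        for i, j in enumerate(sel, start=1):
            se = np.sqrt(sigma2 * XtX_inv[i, i])
            t = coef[i] / se if se > 0 else np.inf
            model.betas[snp_ids[j]] = float(coef[i])
            model.conditional_p[snp_ids[j]] = float(2 * stats.t.sf(abs(t), dof))
    return model


def permutation_model_p(
    feature_values,
    region_dosages: pd.DataFrame,
    covariates=None,
    observed_r2_diff: float | None = None,
    n_perm: int = 2500,
    seed: int = 0,
    max_terms: int = 10,
) -> float:
    """Permutation P-value for the multivariate model's R2_diff.

    The covariate-residualized feature is permuted ``n_perm`` times; the full
    stepwise selection is rerun on each permutation and its R2_diff recorded.
    The add-one estimator (#{perm R2_diff >= observed} + 1) / (n_perm + 1)
    can never return zero; its resolution floor is 1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse model-P resolution", stacklevel=2)
    y_r = _residualize_y(feature_values, covariates)
    G = region_dosages.to_numpy(dtype=float)
    snp_ids = list(region_dosages.columns)
    if observed_r2_diff is None:
        _, r2f, r2s, _, _ = _forward_aic(y_r, G, snp_ids, max_terms)
        observed_r2_diff = max(r2f - r2s, 0.0)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        yp = rng.permutation(y_r)
        _, r2f, r2s, _, _ = _forward_aic(yp, G, snp_ids, max_terms)
        if max(r2f - r2s, 0.0) >= observed_r2_diff:
            b += 1
    return (b + 1) / (n_perm + 1)


def replicate_locus(
    discovery_model: RegionModel,
    feature_values,
    region_dosages: pd.DataFrame,
    covariates=None,
    n_perm: int = 2500,
    seed: int = 0,
    max_terms: int = 10,
) -> dict:
    """Attempt to replicate allelic heterogeneity at a locus.

    The stepwise + permutation analysis is rerun in the replication cohort
    over the same window (not necessarily the same SNPs). The locus
    replicates when the replication model selects at least two SNPs and its
    permutation model P is below 0.05.
    """
    if region_dosages.shape[1] == 0:
        return {"replicated": False, "testable": False, "replication_model": None}
    model = stepwise_select(
        feature_values,
        region_dosages,
        covariates,
        max_terms=max_terms,
        window=discovery_model.window,
        feature_label=discovery_model.feature_label,
    )
    model.model_p = permutation_model_p(
        feature_values,
        region_dosages,
        covariates,
        observed_r2_diff=model.r2_diff,
        n_perm=n_perm,
        seed=seed,
        max_terms=max_terms,
    )
    replicated = len(model.snps) >= 2 and model.model_p < 0.05
    return {"replicated": bool(replicated), "testable": True, "replication_model": model}
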