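"""Spectral preprocessing: binning, replicate averaging, QC filtering, normalization.

The molecular phenotypes of an untargeted NMR GWAS are *metabolome features*:
the mean signal intensity inside fixed-width chemical-shift bins. This module
turns raw (ppm, intensity) spectra into a quality-filtered, normalized
:class:`FeatureMatrix` ready for association testing.

Conventions
-----------
* Bins are half-open intervals ``[lo, lo + width)``; a bin is labelled by its
  center ppm rounded to 4 decimals (so an 11-ppm range at 0.005 ppm yields
  2,200 bins labelled 0.5025, 0.5075, ...).
* Replicate spectra of one individual are log-averaged bin-wise; all later
  stages operate on the log scale.
* QC drops features with >5% missing values first, then samples, in that
  order.
* The default normalization is a per-individual Z-score across features
  (profile normalization), which empirically tracks total-metabolite-content
  normalization closely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinSpec",
    "FeatureMatrix",
    "bin_spectrum",
    "bin_matrix",
    "average_replicates",
    "filter_matrix",
    "normalize_profiles",
    "scale_features",
    "align_features",
    "EmptyMatrixError",
]

#: ppm region dominated by the suppressed water resonance; excluded only when
#: requested (see ``filter_matrix(exclude_region=...)``).
WATER_REGION = (4.5, 5.0)


class EmptyMatrixError(ValueError):
    """Raised when QC filtering removes every feature or every sample."""


@dataclass(frozen=True)
class BinSpec:
    """Uniform chemical-shift binning grid.

    Parameters
    ----------
    bin_width : float
        Bin width in ppm (0.005 is the usual choice for 700 MHz urine data).
    ppm_min, ppm_max : float
        Covered chemical-shift range.
    """

    bin_width: float
    ppm_min: float
    ppm_max: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.ppm_max <= self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")

    @property
    def n_bins(self) -> int:
        return int(round((self.ppm_max - self.ppm_min) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return self.ppm_min + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        """Bin labels: center ppm rounded to 4 decimals."""
        raw = self.ppm_min + self.bin_width * (np.arange(self.n_bins) + 0.5)
        return np.round(raw, 4)


class FeatureMatrix:
    """Individuals x ppm-labelled spectral bins, missing values as NaN.

    Thin wrapper around a :class:`pandas.DataFrame` whose columns are float
    ppm bin centers (strictly increasing) and whose index holds sample ids.
    """

    def __init__(self, data: pd.DataFrame):
        labels = np.asarray(data.columns, dtype=float)
        if len(labels) == 0 or data.shape[0] == 0:
            raise EmptyMatrixError("feature matrix has no features or no samples")
        if not np.all(np.diff(labels) > 0):
            raise ValueError("feature labels must be strictly increasing")
        df = data.copy()
        df.columns = labels
        self.data = df.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def feature_labels(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def feature_r2(self) -> pd.DataFrame:
        """Pairwise squared Pearson correlation between features."""
        c = self.data.corr()
        return c * c

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, f = self.shape
        return f"FeatureMatrix({n} samples x {f} features, {np.isnan(self.values).mean():.1%} missing)"


def bin_spectrum(raw, spec: BinSpec) -> pd.Series:
    """Bin one raw spectrum into mean intensities per chemical-shift bin.

    Parameters
    ----------
    raw : array-like of shape (n_points, 2) or DataFrame with columns (ppm, intensity)
        Points sorted by ppm.
    spec : BinSpec

    Returns
    -------
    pandas.Series indexed by bin-center labels; bins containing no raw point
    are NaN (missing).
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("raw spectrum must be a non-empty (ppm, intensity) table")
    ppm, inten = arr[:, 0], arr[:, 1]
    idx = np.floor((ppm - spec.ppm_min) / spec.bin_width).astype(int)
    keep = (idx >= 0) & (idx < spec.n_bins)
    idx, inten = idx[keep], inten[keep]
    sums = np.bincount(idx, weights=inten, minlength=spec.n_bins)
    counts = np.bincount(idx, minlength=spec.n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=spec.centers)


def bin_matrix(ppm: np.ndarray, intensities: np.ndarray, spec: BinSpec) -> pd.DataFrame:
    """Vectorized binning of many spectra sharing one ppm grid.

    ``intensities`` has shape (n_spectra, n_points); returns a DataFrame of
    shape (n_spectra, n_bins) with NaN for empty bins.
    """
    ppm = np.asarray(ppm, dtype=float)
    idx = np.floor((ppm - spec.ppm_min) / spec.bin_width).astype(int)
    keep = (idx >= 0) & (idx < spec.n_bins)
    idx = idx[keep]
    inten = np.asarray(intensities, dtype=float)[:, keep]
    counts = np.bincount(idx, minlength=spec.n_bins)
    # per-row bin sums via one matmul against a sparse-ish indicator
    sums = np.zeros((inten.shape[0], spec.n_bins))
    np.add.at(sums.T, idx, inten.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(means, columns=spec.centers)


def average_replicates(profiles) -> pd.Series:
    """Log-average binned replicate profiles of one individual.

    Each bin of the output is the mean of ``log(intensity)`` over the
    replicates with a non-missing value there; a bin missing in every
    replicate stays missing. Non-positive intensities cannot be logged and
    are flagged and treated as missing. The result (and everything
    downstream) is on the natural-log scale.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        df = pd.DataFrame([pd.Series(p) for p in profiles])
    if df.shape[0] < 1:
        raise ValueError("need at least one replicate profile")
    vals = df.to_numpy(dtype=float)
    bad = np.isfinite(vals) & (vals <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive intensities treated as missing for log-averaging",
            stacklevel=2,
        )
        vals = np.where(bad, np.nan, vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.log(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(logs, axis=0)
    return pd.Series(out, index=df.columns)


def filter_matrix(
    m: FeatureMatrix,
    max_missing: float = 0.05,
    exclude_region: tuple[float, float] | None = None,
) -> FeatureMatrix:
    """QC filter: drop features, then samples, exceeding a missingness cap.

    The order is deliberate and fixed: features with a missing fraction above
    ``max_missing`` are removed first, and sample missingness is then
    evaluated on the surviving features only. ``exclude_region`` optionally
    removes a ppm window (e.g. the residual-water region) beforehand.
    """
    df = m.data
    if exclude_region is not None:
        lo, hi = exclude_region
        labels = np.asarray(df.columns, dtype=float)
        df = df.loc[:, (labels < lo) | (labels >= hi)]
    feat_missing = df.isna().mean(axis=0)
    df = df.loc[:, feat_missing.to_numpy() <= max_missing]
    if df.shape[1] == 0:
        raise EmptyMatrixError("all features removed by missingness filter")
    samp_missing = df.isna().mean(axis=1)
    df = df.loc[samp_missing.to_numpy() <= max_missing, :]
    if df.shape[0] == 0:
        raise EmptyMatrixError("all samples removed by missingness filter")
    return FeatureMatrix(df)


def normalize_profiles(
    m: FeatureMatrix,
    method: str = "zscore",
    reference_label: float | None = None,
) -> FeatureMatrix:
    """Normalize each individual's metabolic profile.

    Methods
    -------
    ``zscore``
        Center and scale each sample's non-missing feature vector across
        features to zero mean and unit (population, 1/n) variance. Input is
        expected on the log scale. Idempotent.
    ``total_content``
        Divide by the sample's total intensity, then log. Input must be
        positive linear intensities.
    ``reference_feature``
        Divide by the intensity of one named bin (e.g. a creatinine
        resonance), then log. Input must be positive linear intensities.
    """
    vals = m.values.copy()
    if method == "zscore":
        mean = np.nanmean(vals, axis=1, keepdims=True)
        var = np.nanvar(vals, axis=1, keepdims=True)
        zero = np.flatnonzero(var.ravel() <= 0)
        if zero.size:
            bad = [m.sample_ids[i] for i in zero]
            raise ValueError(f"zero within-sample variance for sample(s): {bad}")
        out = (vals - mean) / np.sqrt(var)
    elif method == "total_content":
        totals = np.nansum(vals, axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("total_content requires positive intensities")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(vals / totals)
    elif method == "reference_feature":
        if reference_label is None:
            raise ValueError("reference_feature normalization needs reference_label")
        labels = m.feature_labels
        j = int(np.argmin(np.abs(labels - reference_label)))
        ref = vals[:, [j]]
        if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
            raise ValueError("reference feature missing or non-positive for some sample")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log(vals / ref)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return FeatureMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def scale_features(m: FeatureMatrix) -> FeatureMatrix:
    """Standardize each feature across samples (mean 0, SD 1).

    Applied after profile normalization when standardized regression effect
    sizes are wanted; features with zero variance are left centered only.
    """
    vals = m.values.copy()
    mean = np.nanmean(vals, axis=0, keepdims=True)
    sd = np.nanstd(vals, axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    out = (vals - mean) / sd
    return pd.DataFrame(out, index=m.data.index, columns=m.data.columns).pipe(FeatureMatrix)


def align_features(
    labels_a,
    labels_b,
    width_a: float,
    width_b: float,
    tolerance: float | None = None,
) -> list[tuple[float, float]]:
    """Match features of grid *a* to the nearest features of grid *b*.

    Used to pair bins of cohorts binned at different widths (e.g. 1.2025 at
    0.005 ppm with 1.2040 at 0.0032 ppm). Each *a* label pairs with the *b*
    label of nearest bin center, provided the distance is at most
    ``tolerance`` (default ``max(width_a, width_b)``). The pairing is a
    function of *a*: distinct *a* labels may share a *b* partner.
    """
    a = np.sort(np.asarray(labels_a, dtype=float))
    b = np.sort(np.asarray(labels_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return []
    tol = max(width_a, width_b) if tolerance is None else tolerance
    if a.max() < b.min() - tol or b.max() < a.min() - tol:
        warnings.warn("feature grids do not overlap; no pairs", stacklevel=2)
        return []
    pos = np.searchsorted(b, a)
    pairs: list[tuple[float, float]] = []
    for lab, j in zip(a, pos):
        cands = []
        if j > 0:
            cands.append(b[j - 1])
        if j < b.size:
            cands.append(b[j])
        # nearest candidate, ties resolved toward the lower ppm
        best = min(cands, key=lambda c: (abs(c - lab), c))
        if abs(best - lab) <= tol:
            pairs.append((float(lab), float(best)))
    return pairs
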