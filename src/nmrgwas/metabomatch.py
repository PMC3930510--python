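"""Metabomatching: pseudo-spectrum compound identification.

A genetic effect on a metabolite with a multi-peak NMR spectrum shows up as
associations of the SNP with several metabolome features at once. The
*pseudo-spectrum* of a SNP — its per-feature association significances
(−log10 P) laid out along the ppm axis — therefore resembles the NMR spectrum
of the driven metabolite. Metabomatching scores every reference metabolite by
summing the squared association statistics over the k independent features
matched by its peak list; under the null the sum is χ²_k-distributed, which
yields a P-value, and metabolites are ranked by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceSpectrum",
    "PseudoSpectrum",
    "MatchResult",
    "pseudo_spectrum",
    "map_peaks",
    "prune_correlated",
    "score_metabolite",
    "rank_library",
    "score_pair",
    "rank_pairs",
]

# floor for -log10(p) conversion; p-values that underflow are clipped here
_P_FLOOR = 1e-320


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Peak list of one reference metabolite.

    ``peaks`` is a list of (ppm position, relative intensity in (0, 1]).
    Relative intensities are carried for display but not used in scoring:
    the χ² statistic weights all matched peaks equally.
    """

    metabolite_id: str
    name: str
    peaks: tuple = ()

    def __post_init__(self):
        if len(self.peaks) < 1:
            raise ValueError(f"{self.metabolite_id}: reference spectrum needs >=1 peak")
        for pos, h in self.peaks:
            if not np.isfinite(pos):
                raise ValueError(f"{self.metabolite_id}: non-finite peak position")
            if not (0 < h <= 1):
                raise ValueError(f"{self.metabolite_id}: relative intensity must be in (0,1]")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.peaks], dtype=float)


@dataclass
class PseudoSpectrum:
    """Per-feature association profile of one SNP.

    ``table`` has one row per feature with columns ``feature_ppm`` (sorted),
    ``z`` (signed association statistic) and ``minus_log10_p``.
    """

    snp_id: str
    table: pd.DataFrame
    gaps: list = field(default_factory=list)  # feature labels with no record

    @property
    def feature_labels(self) -> np.ndarray:
        return self.table["feature_ppm"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, snp_id: str = "") -> "PseudoSpectrum":
        tab = pd.read_csv(path, sep="\t")
        return cls(snp_id=snp_id, table=tab[["feature_ppm", "z", "minus_log10_p"]])


@dataclass
class MatchResult:
    """Score of one metabolite (or metabolite pair) against a pseudo-spectrum."""

    metabolite_ids: tuple
    name: str
    k: int
    score: float
    p: float
    n_unmatched_peaks: int = 0
    rank: int | None = None
    percentile: float | None = None

    @property
    def scorable(self) -> bool:
        return self.k >= 1


def pseudo_spectrum(records: pd.DataFrame, all_features=None) -> PseudoSpectrum:
    """Reshape the association records of one SNP into a pseudo-spectrum.

    ``records`` needs columns ``feature_label``, ``z``, ``p`` (one row per
    feature). If ``all_features`` is given, features without a record are
    listed as gaps.
    """
    snp_ids = records["snp_id"].unique() if "snp_id" in records else np.array([""])
    if len(snp_ids) != 1:
        raise ValueError("pseudo_spectrum expects records of exactly one SNP")
    labels = records["feature_label"].to_numpy(dtype=float)
    if len(np.unique(labels)) != len(labels):
        raise ValueError("duplicate feature labels in association records")
    p = np.clip(records["p"].to_numpy(dtype=float), _P_FLOOR, 1.0)
    tab = pd.DataFrame(
        {
            "feature_ppm": labels,
            "z": records["z"].to_numpy(dtype=float),
            "minus_log10_p": -np.log10(p),
        }
    ).sort_values("feature_ppm", ignore_index=True)
    gaps = []
    if all_features is not None:
        gaps = sorted(set(np.asarray(all_features, dtype=float)) - set(labels))
    return PseudoSpectrum(snp_id=str(snp_ids[0]), table=tab, gaps=gaps)


def map_peaks(
    ref: ReferenceSpectrum, feature_labels, tolerance: float = 0.02
) -> tuple[np.ndarray, int]:
    """Map reference peaks to feature bins.

    Each peak maps to the nearest bin center within ``tolerance`` ppm; an
    exact midpoint resolves to the lower ppm. Peaks landing in the same bin
    collapse to one matched feature; unmatched peaks are dropped and counted.

    Returns (sorted unique matched indices into ``feature_labels``, number of
    unmatched peaks).
    """
    labels = np.asarray(feature_labels, dtype=float)
    if labels.size == 0:
        return np.array([], dtype=int), len(ref.peaks)
    if np.any(np.diff(labels) < 0):
        raise ValueError("feature labels must be sorted")
    matched: set[int] = set()
    n_unmatched = 0
    pos = np.searchsorted(labels, ref.positions)
    for ppm, j in zip(ref.positions, pos):
        cands = []
        if j > 0:
            cands.append(j - 1)
        if j < labels.size:
            cands.append(j)
        best = min(cands, key=lambda i: (abs(labels[i] - ppm), labels[i]))
        if abs(labels[best] - ppm) <= tolerance:
            matched.add(int(best))
        else:
            n_unmatched += 1
    return np.array(sorted(matched), dtype=int), n_unmatched


def prune_correlated(
    matched_idx: np.ndarray,
    z: np.ndarray,
    feature_r2: pd.DataFrame,
    feature_labels,
    r2_prune: float = 0.4,
) -> np.ndarray:
    """Greedily reduce matched features to an independent subset.

    Keep the matched feature with the largest \\|z\\| (ties: lower ppm), drop
    every other matched feature correlated with it at r² > ``r2_prune``,
    repeat. The survivors define the degrees of freedom k of the χ² score.
    """
    labels = np.asarray(feature_labels, dtype=float)
    remaining = list(matched_idx)
    kept: list[int] = []
    while remaining:
        best = min(remaining, key=lambda i: (-abs(z[i]), labels[i]))
        kept.append(best)
        remaining.remove(best)
        survivors = []
        for i in remaining:
            try:
                r2 = float(feature_r2.loc[labels[best], labels[i]])
            except KeyError as exc:
                raise KeyError(
                    f"feature correlation missing for pair ({labels[best]}, {labels[i]})"
                ) from exc
            if not (r2 > r2_prune):
                survivors.append(i)
        remaining = survivors
    return np.array(sorted(kept), dtype=int)


def _score_from_indices(ps: PseudoSpectrum, kept: np.ndarray) -> tuple[int, float, float]:
    z = ps.z[kept]
    score = float(np.sum(z * z))
    k = int(kept.size)
    p = float(stats.chi2.sf(score, df=k)) if k >= 1 else float("nan")
    # survival function may underflow exactly to 0 for huge scores
    p = max(p, _P_FLOOR) if k >= 1 else p
    return k, score, p


def score_metabolite(
    ps: PseudoSpectrum,
    ref: ReferenceSpectrum,
    feature_r2: pd.DataFrame,
    tolerance: float = 0.02,
    r2_prune: float = 0.4,
) -> MatchResult:
    """Score one reference metabolite against a pseudo-spectrum.

    score = Σ z_i² over the k independent matched features;
    p = χ²_k survival probability at the score. A metabolite none of whose
    peaks maps to a feature is returned unscorable (k = 0).
    """
    idx, n_unmatched = map_peaks(ref, ps.feature_labels, tolerance)
    if idx.size == 0:
        return MatchResult(
            metabolite_ids=(ref.metabolite_id,), name=ref.name, k=0,
            score=float("nan"), p=float("nan"), n_unmatched_peaks=n_unmatched,
        )
    kept = prune_correlated(idx, ps.z, feature_r2, ps.feature_labels, r2_prune)
    k, score, p = _score_from_indices(ps, kept)
    return MatchResult(
        metabolite_ids=(ref.metabolite_id,), name=ref.name, k=k,
        score=score, p=p, n_unmatched_peaks=n_unmatched,
    )


def _rank(results: list[MatchResult]) -> pd.DataFrame:
    scorable = [r for r in results if r.scorable]
    if not scorable:
        raise ValueError("no scorable metabolite: no reference peak maps to any feature")
    scorable.sort(key=lambda r: (r.p, -r.score, r.metabolite_ids))
    n = len(scorable)
    rows = []
    for i, r in enumerate(scorable, start=1):
        r.rank = i
        r.percentile = 100.0 * i / n
        rows.append(
            {
                "rank": i,
                "metabolite_id": "+".join(r.metabolite_ids),
                "name": r.name,
                "k": r.k,
                "score": r.score,
                "p": r.p,
                "percentile": r.percentile,
            }
        )
    return pd.DataFrame(rows)


def rank_library(
    ps: PseudoSpectrum,
    library: list[ReferenceSpectrum],
    feature_r2: pd.DataFrame,
    tolerance: float = 0.02,
    r2_prune: float = 0.4,
) -> pd.DataFrame:
    """Score and rank every library metabolite against a pseudo-spectrum.

    Returns a table sorted by ascending p (ties: descending score, then
    metabolite id), with 1-based ranks and percentile ranks over the
    scorable metabolites. Unscorable metabolites are excluded.
    """
    if not library:
        raise ValueError("empty reference library")
    results = [
        score_metabolite(ps, ref, feature_r2, tolerance, r2_prune) for ref in library
    ]
    return _rank(results)


def score_pair(
    ps: PseudoSpectrum,
    ref_a: ReferenceSpectrum,
    ref_b: ReferenceSpectrum,
    feature_r2: pd.DataFrame,
    tolerance: float = 0.02,
    r2_prune: float = 0.4,
) -> MatchResult:
    """Two-compound metabomatching: score the union of two peak lists.

    Peaks of both metabolites are pooled, mapped and pruned jointly; features
    hit by both collapse, so scoring a metabolite against itself reduces to
    the single-compound score.
    """
    idx_a, un_a = map_peaks(ref_a, ps.feature_labels, tolerance)
    idx_b, un_b = map_peaks(ref_b, ps.feature_labels, tolerance)
    idx = np.array(sorted(set(idx_a) | set(idx_b)), dtype=int)
    ids = tuple(sorted({ref_a.metabolite_id, ref_b.metabolite_id}))
    name = " + ".join(sorted({ref_a.name, ref_b.name}))
    if idx.size == 0:
        return MatchResult(metabolite_ids=ids, name=name, k=0, score=float("nan"),
                           p=float("nan"), n_unmatched_peaks=un_a + un_b)
    kept = prune_correlated(idx, ps.z, feature_r2, ps.feature_labels, r2_prune)
    k, score, p = _score_from_indices(ps, kept)
    return MatchResult(metabolite_ids=ids, name=name, k=k, score=score, p=p,
                       n_unmatched_peaks=un_a + un_b)


def rank_pairs(
    ps: PseudoSpectrum,
    library: list[ReferenceSpectrum],
    feature_r2: pd.DataFrame,
    anchor_id: str | None = None,
    tolerance: float = 0.02,
    r2_prune: float = 0.4,
) -> pd.DataFrame:
    """Rank metabolite pairs by two-compound score.

    With ``anchor_id`` set (the typical use: one suspected compound such as
    formate, paired with every other library member), only anchor x other
    pairs are scored; otherwise all unordered pairs.
    """
    by_id = {r.metabolite_id: r for r in library}
    if anchor_id is not None:
        if anchor_id not in by_id:
            raise KeyError(f"anchor metabolite {anchor_id!r} not in library")
        anchor = by_id[anchor_id]
        pairs = [(anchor, r) for r in library if r.metabolite_id != anchor_id]
    else:
        pairs = [
            (library[i], library[j])
            for i in range(len(library))
            for j in range(i + 1, len(library))
        ]
    results = [score_pair(ps, a, b, feature_r2, tolerance, r2_prune) for a, b in pairs]
    return _rank(results)
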