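"""Pruning, replication, meta-analysis and locus grouping of association hits.

A metabolome-wide scan yields many suggestive SNP-feature pairs that tag the
same underlying signal through linkage disequilibrium (between SNPs) and
spectral correlation (between features). ``clump_pairs`` extends PLINK-style
clumping to this two-dimensional setting: two pairs are equivalent only when
their SNPs are in LD (r² above a threshold) AND their features are
correlated (r² above a second threshold). Survivors are tested for
replication in an independent cohort, combined by fixed-effect
inverse-variance meta-analysis, and grouped into loci by chromosomal
proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import signed_z

__all__ = [
    "LDLookup",
    "MetaRecord",
    "clump_pairs",
    "assess_replication",
    "ivw_meta",
    "harmonize_effects",
    "group_loci",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class LDLookup:
    """Pairwise LD (squared Pearson correlation of genotype dosages).

    Built from a dosage matrix (samples x SNPs); values are cached on demand.
    A precomputed symmetric r² DataFrame can be supplied instead.
    """

    def __init__(self, dosages: pd.DataFrame | None = None, r2_table: pd.DataFrame | None = None):
        if (dosages is None) == (r2_table is None):
            raise ValueError("provide exactly one of dosages or r2_table")
        self._dos = dosages
        self._table = r2_table
        self._cache: dict[tuple[str, str], float] = {}

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        if key in self._cache:
            return self._cache[key]
        if self._table is not None:
            try:
                val = float(self._table.loc[a, b])
            except KeyError as exc:
                raise KeyError(f"no LD entry for SNP pair ({a}, {b})") from exc
        else:
            for s in (a, b):
                if s not in self._dos.columns:
                    raise KeyError(f"no LD entry for SNP pair ({a}, {b}): {s} not in panel")
            x = self._dos[a].to_numpy(dtype=float)
            y = self._dos[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.std() == 0 or y.std() == 0:
                val = 0.0
            else:
                r = np.corrcoef(x, y)[0, 1]
                val = float(r * r)
        self._cache[key] = val
        return val


@dataclass
class MetaRecord:
    """Fixed-effect inverse-variance combination of two cohort records."""

    snp_id: str
    feature_label: float
    x_m: float
    se_m: float
    p_m: float
    records: tuple = field(default_factory=tuple)
    chr: str = "0"
    pos: int = 0


def _feat_r2(feature_corr: pd.DataFrame, fa: float, fb: float) -> float:
    try:
        v = float(feature_corr.loc[fa, fb])
    except KeyError as exc:
        raise KeyError(f"no feature correlation entry for pair ({fa}, {fb})") from exc
    return v


def clump_pairs(
    hits: pd.DataFrame,
    ld: LDLookup,
    feature_corr: pd.DataFrame,
    r2_snp: float = 0.3,
    r2_feat: float = 0.4,
) -> pd.DataFrame:
    """Greedy two-dimensional clumping of suggestive SNP-feature pairs.

    Hits are sorted by ascending P (ties: snp_id, then feature label). The
    best remaining hit becomes a representative and absorbs every remaining
    hit whose SNP is in LD with it (r² > ``r2_snp``) AND whose feature is
    correlated with it (r² > ``r2_feat``); both conditions are required.
    Absorption is greedy from the representative, not transitively closed.

    ``feature_corr`` is a symmetric table of squared feature correlations
    indexed by feature label. Returns the representatives with an
    ``n_members`` column counting absorbed hits (including themselves).
    """
    if hits.empty:
        raise ValueError("no hits to clump")
    work = hits.sort_values(
        ["p", "snp_id", "feature_label"], kind="mergesort", ignore_index=True
    )
    taken = np.zeros(len(work), dtype=bool)
    reps: list[int] = []
    members: list[int] = []
    for i in range(len(work)):
        if taken[i]:
            continue
        taken[i] = True
        reps.append(i)
        count = 1
        si, fi = work.at[i, "snp_id"], work.at[i, "feature_label"]
        for j in range(i + 1, len(work)):
            if taken[j]:
                continue
            sj, fj = work.at[j, "snp_id"], work.at[j, "feature_label"]
            if ld.r2(si, sj) > r2_snp and _feat_r2(feature_corr, fi, fj) > r2_feat:
                taken[j] = True
                count += 1
        members.append(count)
    out = work.iloc[reps].copy().reset_index(drop=True)
    out["n_members"] = members
    return out


def harmonize_effects(
    beta_b: float,
    ea_a: str,
    oa_a: str,
    ea_b: str,
    oa_b: str,
) -> tuple[float, bool, bool]:
    """Align cohort B's effect to cohort A's effect allele.

    Returns (possibly sign-flipped beta_b, flipped?, strand_ambiguous?).
    A/T and C/G SNPs are flagged as strand-ambiguous but still harmonized by
    allele label.
    """
    ambiguous = (ea_a.upper(), oa_a.upper()) in AMBIGUOUS_PAIRS
    if (ea_b.upper(), oa_b.upper()) == (ea_a.upper(), oa_a.upper()):
        return beta_b, False, ambiguous
    if (ea_b.upper(), oa_b.upper()) == (oa_a.upper(), ea_a.upper()):
        return -beta_b, True, ambiguous
    raise ValueError(
        f"alleles do not match: ({ea_a}/{oa_a}) vs ({ea_b}/{oa_b})"
    )


def ivw_meta(a, b) -> MetaRecord:
    """Fixed-effect inverse-variance meta-analysis of two cohort records.

    ``a`` and ``b`` are mappings (Series/dict/records) with at least ``beta``
    and ``se``; effect alleles must already be harmonized. Weights are
    w_i = 1/se_i²; x_m = Σ w_i x_i / Σ w_i, se_m = sqrt(1/Σ w_i), and p_m
    follows from z = x_m / se_m against the standard normal.
    """
    xa, sa = float(a["beta"]), float(a["se"])
    xb, sb = float(b["beta"]), float(b["se"])
    if sa <= 0 or sb <= 0:
        raise ValueError("standard errors must be positive for IVW meta-analysis")
    wa, wb = 1.0 / sa**2, 1.0 / sb**2
    x_m = (wa * xa + wb * xb) / (wa + wb)
    se_m = float(np.sqrt(1.0 / (wa + wb)))
    zval = x_m / se_m
    p_m = float(2.0 * stats.norm.sf(abs(zval)))
    p_m = max(p_m, 1e-320)
    return MetaRecord(
        snp_id=str(a.get("snp_id", "")) if hasattr(a, "get") else "",
        feature_label=float(a.get("feature_label", np.nan)) if hasattr(a, "get") else np.nan,
        x_m=float(x_m),
        se_m=se_m,
        p_m=p_m,
        records=(a, b),
        chr=str(a.get("chr", "0")) if hasattr(a, "get") else "0",
        pos=int(a.get("pos", 0)) if hasattr(a, "get") else 0,
    )


def assess_replication(
    discovery_hits: pd.DataFrame,
    replication_records: pd.DataFrame,
    combined_threshold: float,
    n_hits: int | None = None,
) -> pd.DataFrame:
    """Apply the three replication rules to each discovered representative.

    A hit replicates iff (1) the discovery and replication effect directions
    agree, (2) the replication P-value beats the Bonferroni level
    0.05/#hits, and (3) the IVW-combined P-value beats the metabolome- and
    genome-wide ``combined_threshold``. Replication records are matched on
    ``snp_id`` and ``feature_label`` (align features across bin grids
    first); unmatched hits are reported as not testable.
    """
    if n_hits is None:
        n_hits = len(discovery_hits)
    rep_thr = 0.05 / n_hits
    rep = replication_records.set_index(["snp_id", "feature_label"])
    rows = []
    for _, h in discovery_hits.iterrows():
        key = (h["snp_id"], h["feature_label"])
        row = {
            "snp_id": h["snp_id"],
            "feature_label": h["feature_label"],
            "p_discovery": h["p"],
            "beta_discovery": h["beta"],
        }
        if key not in rep.index:
            row.update(
                testable=False, concordant=False, replication_significant=False,
                combined_significant=False, replicated=False,
                beta_replication=np.nan, p_replication=np.nan, p_meta=np.nan, x_meta=np.nan,
            )
            rows.append(row)
            continue
        r = rep.loc[key]
        meta = ivw_meta(h, {"beta": r["beta"], "se": r["se"]})
        concordant = np.sign(h["beta"]) == np.sign(r["beta"]) and h["beta"] != 0
        rep_sig = r["p"] < rep_thr
        comb_sig = meta.p_m < combined_threshold
        row.update(
            testable=True,
            concordant=bool(concordant),
            replication_significant=bool(rep_sig),
            combined_significant=bool(comb_sig),
            replicated=bool(concordant and rep_sig and comb_sig),
            beta_replication=r["beta"],
            p_replication=r["p"],
            p_meta=meta.p_m,
            x_meta=meta.x_m,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def group_loci(meta_records, window: int = 1_000_000) -> pd.DataFrame:
    """Group replicated SNP-feature associations into genetic loci.

    Single-linkage grouping: hits on the same chromosome belong to one locus
    whenever they chain with gaps of at most ``window`` bp (1 Mb by
    default). Each locus reports its lead SNP (smallest meta P; ties go to
    the smaller position) and the union of associated features.

    ``meta_records`` may be a list of :class:`MetaRecord` or a DataFrame with
    columns ``snp_id feature_label chr pos p_m``.
    """
    if not isinstance(meta_records, pd.DataFrame):
        meta_records = pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "feature_label": r.feature_label,
                    "chr": r.chr,
                    "pos": r.pos,
                    "p_m": r.p_m,
                    "x_m": r.x_m,
                }
                for r in meta_records
            ]
        )
    df = meta_records.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
    locus_ids = np.zeros(len(df), dtype=int)
    locus = -1
    prev_chr, prev_pos = None, None
    for i, row in df.iterrows():
        if row["chr"] != prev_chr or row["pos"] - prev_pos > window:
            locus += 1
        locus_ids[i] = locus
        prev_chr, prev_pos = row["chr"], row["pos"]
    df["locus"] = locus_ids
    out = []
    for lid, grp in df.groupby("locus"):
        lead = grp.sort_values(["p_m", "pos"], kind="mergesort").iloc[0]
        out.append(
            {
                "locus": int(lid),
                "chr": lead["chr"],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "lead_snp": lead["snp_id"],
                "lead_pos": int(lead["pos"]),
                "lead_p_m": lead["p_m"],
                "features": sorted(set(grp["feature_label"])),
                "n_associations": len(grp),
            }
        )
    return pd.DataFrame(out)
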