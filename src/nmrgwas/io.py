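"""Readers and writers for the toolkit's plain-text interchange formats.

Formats
-------
* dosage TSV: samples x SNPs, first column ``sample_id``.
* VCF v4.2 with a ``DS`` FORMAT field carrying expected allele dosages
  (written as text; read back through cyvcf2).
* feature-matrix TSV: samples x ppm-labelled columns, ``NA`` for missing.
* raw spectrum TSV: two columns ``ppm`` and ``intensity``.
* reference library CSV: ``metabolite_id,name,peak_ppm,rel_intensity``
  (one row per peak, HMDB peak-list export convention).
* summary-statistics TSV: ``snp_id chr pos feature_label beta se z p n``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metabomatch import ReferenceSpectrum
from .spectra import FeatureMatrix

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf_dosages",
    "write_feature_matrix", "read_feature_matrix",
    "write_spectrum_tsv", "read_spectrum_tsv",
    "write_library_csv", "read_library_csv",
    "write_sumstats", "read_sumstats",
]


def write_dosage_tsv(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_vcf(dosages: pd.DataFrame, snp_meta: pd.DataFrame, path) -> None:
    """Write dosages as a VCF v4.2 with GT set missing and DS carrying dosage."""
    meta = snp_meta.set_index("snp_id")
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp in dosages.columns:
            row = meta.loc[snp]
            ds = "\t".join(f"{v:.4g}" for v in dosages[snp].to_numpy(dtype=float))
            fh.write(
                f"{row['chr']}\t{int(row['pos'])}\t{snp}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'G')}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a DS-format VCF back into (dosages, snp_meta) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chrs, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID)
        chrs.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        ds = np.asarray(var.format("DS"), dtype=float).ravel()
        rows.append(ds)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=snp_ids)
    snp_meta = pd.DataFrame(
        {"snp_id": snp_ids, "chr": chrs, "pos": poss, "ref": refs, "alt": alts}
    )
    return dosages, snp_meta


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.8g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    return FeatureMatrix(df)


def write_spectrum_tsv(ppm, intensity, path) -> None:
    pd.DataFrame({"ppm": ppm, "intensity": intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_spectrum_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[["ppm", "intensity"]].to_numpy(dtype=float)


def write_library_csv(library: list[ReferenceSpectrum], path) -> None:
    rows = [
        {"metabolite_id": r.metabolite_id, "name": r.name, "peak_ppm": p, "rel_intensity": h}
        for r in library
        for p, h in r.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_library_csv(path) -> list[ReferenceSpectrum]:
    df = pd.read_csv(path)
    out = []
    for (mid, name), grp in df.groupby(["metabolite_id", "name"], sort=True):
        peaks = tuple(sorted(zip(grp["peak_ppm"].astype(float), grp["rel_intensity"].astype(float))))
        out.append(ReferenceSpectrum(metabolite_id=str(mid), name=str(name), peaks=peaks))
    return out


def write_sumstats(records: pd.DataFrame, path) -> None:
    cols = [c for c in ["snp_id", "chr", "pos", "feature_label", "beta", "se", "z", "p", "n"] if c in records]
    records[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
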