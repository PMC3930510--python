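"""Synthetic cohort generator: genotypes, metabolome, spectra, ground truth.

Every downstream stage of the toolkit (binning, GWAS, clumping, replication,
metabomatching, heterogeneity, MR) is testable without external data through
this forward model:

1. **Genotypes** — diallelic SNPs simulated by haplotype copying with
   per-block founder pools. SNPs are partitioned into LD blocks; within a
   block, K founder haplotypes share one founder ordering, so founder
   minor-allele sets at nearby SNPs are nested and copying the same founder
   across SNPs creates positive LD. Each sampled haplotype keeps its current
   founder with probability ``ld_rho`` per SNP and redraws uniformly
   otherwise; ``ld_rho = 0`` gives (near-)independent SNPs, ``ld_rho`` close
   to 1 gives block-long haplotypes. With two populations, cohorts are
   concatenated with separate block boundaries and founder pools, which
   reproduces the locus-narrowing effect of meta-analysing cohorts with
   different LD structure.
2. **Metabolome** — log-concentration of metabolite m is
   ``intercept + Σ beta·dosage + covariate terms + Normal(0, noise_sd)``;
   a causal SNP with dosage variance 2·MAF·(1−MAF) explains
   ``2·MAF·(1−MAF)·beta²`` of the log-concentration variance.
3. **Spectra** — each metabolite gets a reference peak list (uniform
   positions, Lorentzian lineshape); a sample's spectrum is the
   concentration-weighted sum of metabolite signatures, shifted globally by
   a per-sample chemical-shift jitter (pH / referencing drift) plus baseline
   noise. Missing values are injected after binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabomatch import ReferenceSpectrum
from .spectra import BinSpec, FeatureMatrix, bin_matrix, filter_matrix, normalize_profiles

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimConfigError",
    "simulate_genotypes",
    "simulate_metabolome",
    "make_library",
    "render_spectra",
    "simulate_cohort",
    "beta_for_variance_explained",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a small but realistic urine-NMR GWAS setting: a few
    hundred individuals, LD-blocked common variants, tens of metabolites
    with 2-6 peaks each across the 0.5-9.5 ppm window, unit log-normal
    concentration noise and sub-bin chemical-shift jitter.
    """

    n_individuals: int = 300
    n_snps: int = 100
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.8
    n_populations: int = 1
    n_metabolites: int = 50
    peaks_per_metabolite: tuple = (2, 6)
    ppm_range: tuple = (0.5, 9.5)
    peak_width: float = 0.003
    effect_table: list = field(default_factory=list)  # (snp_idx, met_idx, beta)
    noise_sd: float = 1.0
    shift_jitter_sd: float = 0.001
    missing_rate: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    # model internals with sensible defaults
    n_founders: int = 32
    block_size: int = 20  # mean LD-block length in SNPs (population 1)
    pos_spacing: int = 10_000  # bp between adjacent SNPs
    n_covariates: int = 0
    covariate_effect_sd: float = 0.3
    baseline_noise_sd: float = 0.01
    ppm_step: float = 0.00125  # raw-spectrum grid resolution
    #: seed for the reference library; set it to share one chemistry across
    #: discovery/replication cohorts that differ in everything else
    library_seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_snps": self.n_snps,
            "n_metabolites": self.n_metabolites,
            "n_replicates": self.n_replicates,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if self.n_individuals < 2:
            raise SimConfigError("n_individuals must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must lie within (0, 0.5] and be non-empty")
        if not (0 <= self.ld_rho < 1):
            raise SimConfigError("ld_rho must be in [0, 1)")
        if self.n_populations not in (1, 2):
            raise SimConfigError("n_populations must be 1 or 2")
        if not (0 <= self.missing_rate < 1):
            raise SimConfigError("missing_rate must be in [0, 1)")
        klo, khi = self.peaks_per_metabolite
        if not (1 <= klo <= khi):
            raise SimConfigError("peaks_per_metabolite must be a valid count range")
        if self.ppm_range[1] <= self.ppm_range[0]:
            raise SimConfigError("ppm_range must be a nonempty interval")
        if self.peak_width <= 0:
            raise SimConfigError("peak_width must be positive")
        for s, m, _ in self.effect_table:
            if not (0 <= int(s) < self.n_snps):
                raise SimConfigError(f"effect_table references unknown SNP index {s}")
            if not (0 <= int(m) < self.n_metabolites):
                raise SimConfigError(f"effect_table references unknown metabolite index {m}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["maf_range"] = list(self.maf_range)
        d["peaks_per_metabolite"] = list(self.peaks_per_metabolite)
        d["ppm_range"] = list(self.ppm_range)
        d["effect_table"] = [list(e) for e in self.effect_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("maf_range", "peaks_per_metabolite", "ppm_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "effect_table" in d:
            d["effect_table"] = [tuple(e) for e in d["effect_table"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """What the simulator actually did, for checking downstream inference."""

    concentrations: pd.DataFrame  # individuals x metabolites, log scale
    causal_map: list  # (snp_idx, met_idx, beta) actually applied
    library: list  # ReferenceSpectrum list used for rendering
    covariates: pd.DataFrame | None = None


def beta_for_variance_explained(maf: float, explained: float, total_var: float = 1.0) -> float:
    """Per-dosage effect size giving a target explained-variance fraction.

    Under Hardy-Weinberg the dosage variance is 2*maf*(1-maf), so
    beta = sqrt(explained * total_var / (2*maf*(1-maf))).
    """
    return float(np.sqrt(explained * total_var / (2.0 * maf * (1.0 - maf))))


def _block_bounds(n_snps: int, mean_len: int, rng: np.random.Generator) -> np.ndarray:
    """Random block start indices with geometric-ish lengths."""
    starts = [0]
    pos = 0
    while pos < n_snps:
        length = max(1, int(rng.geometric(1.0 / max(mean_len, 1))))
        pos += length
        if pos < n_snps:
            starts.append(pos)
    return np.array(starts, dtype=int)


def _simulate_population(
    n_ind: int,
    maf: np.ndarray,
    ld_rho: float,
    n_founders: int,
    block_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_snps = maf.size
    K = n_founders
    starts = _block_bounds(n_snps, block_size, rng)
    block_of = np.zeros(n_snps, dtype=int)
    for b, s in enumerate(starts):
        end = starts[b + 1] if b + 1 < len(starts) else n_snps
        block_of[s:end] = b
    # founder minor-allele membership: shared ordering per block => nested sets
    m_counts = np.clip(np.round(maf * K).astype(int), 1, K - 1)
    ranks = np.empty((len(starts), K), dtype=int)
    for b in range(len(starts)):
        ranks[b] = rng.permutation(K)
    # haplotype founder paths
    n_hap = 2 * n_ind
    alleles = np.empty((n_hap, n_snps), dtype=np.int8)
    cur = rng.integers(0, K, size=n_hap)
    for j in range(n_snps):
        if j > 0 and block_of[j] == block_of[j - 1]:
            switch = rng.random(n_hap) >= ld_rho
        else:
            switch = np.ones(n_hap, dtype=bool)
        if switch.any():
            cur = np.where(switch, rng.integers(0, K, size=n_hap), cur)
        alleles[:, j] = ranks[block_of[j]][cur] < m_counts[j]
    return (alleles[0::2] + alleles[1::2]).astype(float)


def simulate_genotypes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dosage genotypes and SNP metadata.

    Returns (dosages, snp_meta): dosages is individuals x SNPs with values in
    {0, 1, 2}; snp_meta has columns ``snp_id chr pos maf ref alt`` (maf is
    the empirical cohort frequency). With ``n_populations = 2`` the cohort is
    split in half, the second half simulated with its own, shorter LD blocks
    and founder pool; a ``population`` column on the sample index records the
    origin.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 101])
    rng_maf, rng_p1, rng_p2 = [np.random.default_rng(s) for s in ss.spawn(3)]
    lo, hi = config.maf_range
    maf = rng_maf.uniform(lo, hi, size=config.n_snps)
    if config.n_populations == 1:
        dose = _simulate_population(
            config.n_individuals, maf, config.ld_rho, config.n_founders,
            config.block_size, rng_p1,
        )
        pops = np.zeros(config.n_individuals, dtype=int)
    else:
        n1 = config.n_individuals // 2
        n2 = config.n_individuals - n1
        d1 = _simulate_population(
            n1, maf, config.ld_rho, config.n_founders, config.block_size, rng_p1
        )
        # population 2: distinct block boundaries (own rng) and shorter blocks
        d2 = _simulate_population(
            n2, maf, config.ld_rho, config.n_founders,
            max(2, config.block_size // 4), rng_p2,
        )
        dose = np.vstack([d1, d2])
        pops = np.r_[np.zeros(n1, dtype=int), np.ones(n2, dtype=int)]
    sample_ids = [f"ind{i:04d}" for i in range(config.n_individuals)]
    snp_ids = [f"rs{j:05d}" for j in range(config.n_snps)]
    dosages = pd.DataFrame(dose, index=sample_ids, columns=snp_ids)
    dosages.attrs["population"] = pops
    snp_meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chr": "1",
            "pos": config.pos_spacing * (1 + np.arange(config.n_snps)),
            "maf": dose.mean(axis=0) / 2.0,
            "ref": "A",
            "alt": "G",
        }
    )
    return dosages, snp_meta


def simulate_metabolome(genotypes: pd.DataFrame, config: SimConfig) -> GroundTruth:
    """Simulate log-scale metabolite concentrations from genotypes.

    ``log-conc[i, m] = intercept_m + Σ beta·dosage[i, snp] + covariates
    + Normal(0, noise_sd)``. Covariates (if ``n_covariates > 0``) are iid
    standard normal with per-metabolite effects ~ Normal(0,
    covariate_effect_sd).
    """
    config.validate()
    n, n_met = genotypes.shape[0], config.n_metabolites
    ss = np.random.SeedSequence([config.seed, 202])
    rng_base, rng_cov, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    intercepts = rng_base.normal(1.0, 0.3, size=n_met)
    conc = np.tile(intercepts, (n, 1))
    G = genotypes.to_numpy(dtype=float)
    for s, m, beta in config.effect_table:
        if int(s) >= G.shape[1]:
            raise SimConfigError(f"effect references unknown SNP index {s}")
        conc[:, int(m)] += float(beta) * G[:, int(s)]
    covariates = None
    if config.n_covariates > 0:
        X = rng_cov.normal(size=(n, config.n_covariates))
        gamma = rng_cov.normal(0.0, config.covariate_effect_sd, size=(config.n_covariates, n_met))
        conc += X @ gamma
        covariates = pd.DataFrame(
            X, index=genotypes.index,
            columns=[f"cov{j}" for j in range(config.n_covariates)],
        )
    if config.noise_sd > 0:
        conc += rng_noise.normal(0.0, config.noise_sd, size=conc.shape)
    met_ids = [f"M{m:03d}" for m in range(n_met)]
    return GroundTruth(
        concentrations=pd.DataFrame(conc, index=genotypes.index, columns=met_ids),
        causal_map=[tuple(e) for e in config.effect_table],
        library=make_library(config),
        covariates=covariates,
    )


def make_library(config: SimConfig, resolution: float = 0.005) -> list[ReferenceSpectrum]:
    """Generate the reference peak-list library used for rendering.

    Each metabolite gets ``peaks_per_metabolite`` peaks at positions uniform
    over ``ppm_range``, distinct at ``resolution`` (one peak per bin), with
    relative intensities in (0, 1] (maximum normalized to 1).
    """
    config.validate()
    lo, hi = config.ppm_range
    n_cells = int(np.floor((hi - lo) / resolution))
    klo, khi = config.peaks_per_metabolite
    if khi > n_cells:
        raise SimConfigError(
            f"peaks_per_metabolite up to {khi} exceeds the {n_cells} distinct "
            f"positions available at {resolution} ppm resolution"
        )
    lib_seed = config.seed if config.library_seed is None else config.library_seed
    rng = np.random.default_rng(np.random.SeedSequence([lib_seed, 303]))
    library = []
    for m in range(config.n_metabolites):
        k = int(rng.integers(klo, khi + 1))
        cells = rng.choice(n_cells, size=k, replace=False)
        positions = lo + (cells + 0.5) * resolution
        heights = rng.uniform(0.2, 1.0, size=k)
        heights = heights / heights.max()
        peaks = tuple(sorted(zip(positions.tolist(), heights.tolist())))
        library.append(
            ReferenceSpectrum(metabolite_id=f"M{m:03d}", name=f"metabolite-{m:03d}", peaks=peaks)
        )
    return library


def render_spectra(truth: GroundTruth, config: SimConfig):
    """Render raw per-replicate spectra from concentrations and the library.

    ``intensity(ppm) = Σ_m exp(conc_m) · Σ_peaks height · L(ppm − (pos + δ);
    peak_width) + baseline noise`` with Lorentzian lineshape
    ``L(x; w) = w² / (x² + w²)`` and a per-sample (per-replicate) global
    shift ``δ ~ Normal(0, shift_jitter_sd)``. Returns (ppm grid, intensity
    array of shape (n_individuals, n_replicates, n_points)).
    """
    config.validate()
    lo, hi = config.ppm_range
    grid = np.arange(lo, hi, config.ppm_step)
    n_met = len(truth.library)
    if truth.concentrations.shape[1] != n_met:
        raise ValueError("library and concentration matrix disagree on metabolite count")
    w = config.peak_width
    sig = np.zeros((n_met, grid.size))
    for m, ref in enumerate(truth.library):
        for pos, h in ref.peaks:
            d = grid - pos
            sig[m] += h * w * w / (d * d + w * w)
    amplitudes = np.exp(truth.concentrations.to_numpy())  # n x n_met
    base = amplitudes @ sig  # n x n_points
    n = base.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    out = np.empty((n, config.n_replicates, grid.size))
    for r in range(config.n_replicates):
        if config.shift_jitter_sd > 0:
            jitter = rng.normal(0.0, config.shift_jitter_sd, size=n)
        else:
            jitter = np.zeros(n)
        for i in range(n):
            # global shift: sample the sample's spectrum at grid - delta
            out[i, r] = np.interp(grid - jitter[i], grid, base[i])
        if config.baseline_noise_sd > 0:
            out[:, r, :] += np.abs(
                rng.normal(0.0, config.baseline_noise_sd, size=(n, grid.size))
            )
    return grid, out


def simulate_cohort(
    config: SimConfig,
    bin_width: float = 0.005,
    max_missing: float = 0.05,
    normalize: str | None = "zscore",
):
    """Full forward simulation: genotypes -> metabolome -> spectra -> features.

    Bins the rendered spectra at ``bin_width``, log-averages replicates,
    injects missing values at ``missing_rate`` (after binning), QC-filters
    and normalizes. Returns (dosages, snp_meta, truth, FeatureMatrix).
    """
    dosages, snp_meta = simulate_genotypes(config)
    truth = simulate_metabolome(dosages, config)
    grid, raw = render_spectra(truth, config)
    spec = BinSpec(bin_width=bin_width, ppm_min=config.ppm_range[0], ppm_max=config.ppm_range[1])
    n, n_rep = raw.shape[0], raw.shape[1]
    binned = bin_matrix(grid, raw.reshape(n * n_rep, -1), spec).to_numpy()
    binned = binned.reshape(n, n_rep, -1)
    if config.missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
        mask = rng.random(binned.shape) < config.missing_rate
        binned = np.where(mask, np.nan, binned)
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.where(binned > 0, np.log(np.where(binned > 0, binned, 1.0)), np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(logs, axis=1)  # replicate log-average
    fm = FeatureMatrix(pd.DataFrame(avg, index=dosages.index, columns=spec.centers))
    fm = filter_matrix(fm, max_missing=max_missing)
    if normalize is not None:
        fm = normalize_profiles(fm, method=normalize)
    # keep genotypes aligned with surviving samples
    dosages = dosages.loc[fm.data.index]
    return dosages, snp_meta, truth, fm
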