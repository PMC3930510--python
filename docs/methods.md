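# Methods

`nmrgwas` implements an untargeted metabolome- and genome-wide association
workflow for 1D ¹H-NMR data: spectral bins are used directly as molecular
phenotypes ("metabolome features"), associated SNP-by-SNP, pruned and
replicated across cohorts, and only then assigned to metabolites by matching
each SNP's association profile against reference peak lists. A synthetic
cohort generator provides ground-truth data for every stage.

## Feature construction

Spectra are binned into uniform chemical-shift increments (default
0.005 ppm; an 11-ppm window gives 2,200 bins). Bins are half-open intervals
`[lo, lo + w)` labelled by their center rounded to 4 decimals; a bin with no
raw data points is missing. Replicate spectra of an individual are combined
bin-wise as the mean of log-intensities; all later stages stay on the log
scale. Quality control removes features with more than 5% missing values
first, then samples by the same rule evaluated on the surviving features —
the order matters and is fixed. An optional window exclusion (e.g. the
residual-water region near 4.5–5.0 ppm) is off by default.

Profiles are normalized per individual by a Z-score across features
(population 1/n variance; idempotent). This is a profile normalization, not
per-feature scaling; on simulated log-normal urine-like profiles it tracks
total-content normalization closely (median per-feature correlation > 0.8 in
the bundled test). Because regression effect sizes are conventionally
reported per SD of phenotype, `scale_features` optionally standardizes each
feature across samples before association; the association P-values are
unaffected, only the scale of β changes.

## Association scan

Each feature is regressed by OLS on SNP dosage (expected minor-allele count
in [0, 2]) plus an intercept and the feature's covariates. Covariates are
chosen per feature by forward stepwise selection among candidate factors,
admitting the factor with the smallest conditional P-value while it is below
a Bonferroni level (default 0.05/#factors); ties break by factor name, and
factors collinear with the current selection are dropped with a warning.
The scan is computed via Frisch–Waugh–Lovell residualization, which makes
the per-SNP fit a simple regression while remaining algebraically exact,
including the residual degrees of freedom. Monomorphic SNPs yield flagged
records with β = 0, P = 1; zero-residual fits are flagged degenerate.
Alongside the t-based P-value we store a signed normal-scale statistic
z = sign(β)·Φ⁻¹(1 − P/2), which is comparable across cohorts of different
size and is the statistic metabomatching squares.

The multiple-testing burden over correlated features uses the eigenvalue
(simpleM) estimate: the effective number of tests is the number of leading
principal components of the feature correlation matrix needed to reach a
fixed variance fraction (default 99.5%). Decision thresholds are the
conventional suggestive level 5×10⁻⁸, a combined Bonferroni level
0.05/(M_eff_features × n_effective_snps), and a replication level
0.05/#hits. The effective SNP count is an explicit input rather than a
value the package guesses.

## Discovery pruning, replication, meta-analysis

Suggestive SNP–feature pairs are pruned by a two-dimensional extension of
greedy clumping: pairs sorted by ascending P; the best remaining pair
becomes a representative and absorbs every remaining pair whose SNP is in
LD with it (r² > 0.3) *and* whose feature is correlated with it
(r² > 0.4). Both conditions are required, absorption is greedy from the
representative (not transitively closed), and ties in P break by SNP id
then feature label.

A representative replicates when the replication-cohort effect has the same
direction, its P-value beats 0.05/#hits, and the inverse-variance-weighted
combined P-value beats the combined threshold. IVW meta-analysis is fixed
effect only: weights 1/se², no heterogeneity gate (a Cochran-Q step could
be added but cross-cohort effect-size differences driven by allele-frequency
differences are expected and are informative in themselves). Effect alleles
are harmonized by REF/ALT label; strand-ambiguous A/T and C/G SNPs are
flagged. Replicated associations are grouped into loci by single-linkage
chaining within 1 Mb (chosen over lead-centred ±500 kb windows because
chained regions slightly larger than 1 Mb should remain one locus); the
locus lead is the smallest combined P, ties to the smaller position.

## Metabomatching

The pseudo-spectrum of a SNP is its per-feature association profile (signed
z and −log₁₀P along the ppm axis). For a reference metabolite with peak
positions p₁…p_m, each peak maps to the nearest bin center within a
tolerance (default 0.02 ppm; exact midpoints resolve to the lower ppm, and
peaks sharing a bin collapse). Matched features are then pruned to an
independent subset: greedily keep the feature with the largest |z| and drop
matched features correlated with it at r² > 0.4. The score is the sum of
squared z over the k surviving features, χ²_k-distributed under the null,
giving a P-value per metabolite; the library is ranked by ascending P (ties:
descending score, then id) with percentile ranks for top-x% statements.
Two-compound matching pools two peak lists before mapping and pruning,
either for one anchor compound against all partners or for all pairs.
Reference relative intensities are carried but unweighted — the χ² statistic
treats all matched peaks equally.

The χ² null is exact only when the pruned features are independent. Rendered
spectra (and real NMR data) violate this: Lorentzian tails and per-sample
chemical-shift jitter make bins covary in metabolite-sized clusters, so the
dispersion of one SNP's z-profile fluctuates seed to seed and absolute
metabomatching P-values on such data are approximate. The bundled null
calibration therefore runs the association-to-ranking code path on a cohort
with independent features, where the KS uniformity check holds; on rendered
spectra the method is validated by what it is used for — ranking — with the
true metabolite recovered at rank 1 in ≥90% of seeds at 10% explained
variance (n = 500, 100-metabolite library).

## Allelic heterogeneity

For a locus-feature pair the feature (residualized on covariates) is
modelled by forward stepwise selection over the region's SNPs, minimizing
AIC (Gaussian profile form n·log(RSS/n) + 2k), capped at 10 terms, skipping
SNPs nearly collinear (r² > 0.99) with the selection. The heterogeneity
summary is R²_diff, the gain of the selected model over the single SNP with
the best marginal fit. Its significance is a permutation P: the full
selection is rerun on each of n_perm permuted phenotypes (default 2,500)
and model_p = (#{perm R²_diff ≥ observed} + 1)/(n_perm + 1). The add-one
estimator never returns 0; its resolution floor is 1/(n_perm + 1)
(≈ 4.0×10⁻⁴ at 2,500 permutations). Replication reruns the whole procedure
on the replication cohort over the same window — not the same SNPs, since
LD structures differ — and declares success when ≥2 SNPs are selected with
model_p < 0.05.

A measured property worth knowing: with a strong primary signal present,
the permutation scheme is mildly liberal (about 12% of single-causal null
simulations reach model_p < 0.05 at the 5% level in the bundled study),
because the observed selection keeps the region's largest noise gains for
steps 2+ while each permutation consumes its own largest noise direction at
step 1. The scheme is kept as specified; heterogeneity claims should lean
on replication, as the workflow does.

## Mendelian randomization

Single-instrument toolkit: first-stage F (t² of the instrument in the
exposure regression); one-sample 2SLS with the standard SE correction
(structural residuals formed with the observed exposure); two-sample Wald
ratio b_GY/b_GX with a first-order delta-method SE; the regression-based
Durbin–Hausman exogeneity test (first-stage residual added to the outcome
model, t-test on its coefficient); and analytic power via the non-central
χ²₁ with λ = n·r²_gx·β²·var_x/var_y, inverted by bisection for required
sample size. The qualitative assumption audit is reduced to the one
implementable check — association tests of the instrument against supplied
confounders, reported but not gating. Exposure/outcome preprocessing and
units are the caller's responsibility.

## Synthetic cohorts

* **Genotypes** — haplotype copying with per-block founder pools. SNPs are
  partitioned into LD blocks (geometric lengths, mean 20 SNPs); each block
  has K = 32 founder haplotypes sharing one founder ordering, so
  minor-allele founder sets at nearby SNPs are nested; each sampled
  haplotype keeps its founder with probability `ld_rho` per SNP and redraws
  uniformly otherwise. This yields empirical MAFs at round(p·K)/K (target
  drawn uniformly from `maf_range`; quantization ≤ 1/(2K)), positive
  within-block LD monotone in `ld_rho`, and block-structured r² decay. Two
  populations are concatenated with separate block boundaries and founder
  pools (population 2 has 4× shorter blocks), reproducing the
  locus-narrowing behaviour of meta-analysing cohorts with different LD.
* **Metabolome** — log-concentration = intercept + Σβ·dosage + optional
  covariate terms + N(0, noise_sd); a causal SNP explains 2·MAF(1−MAF)·β²
  of the variance (helper `beta_for_variance_explained`). Defaults: unit
  noise SD, intercepts N(1, 0.3).
* **Spectra** — each metabolite receives 2–6 peaks uniform over 0.5–9.5 ppm
  with relative intensities in (0, 1]; intensity is the
  concentration-weighted sum of Lorentzian signatures (width 0.003 ppm,
  height form w²/(d² + w²)) plus half-normal baseline noise, with a
  per-sample global chemical-shift jitter N(0, 0.001 ppm) emulating
  pH/referencing drift. Missing values are injected after binning.
  J-coupling multiplets, water-suppression artifacts and baseline
  distortions are not modelled; peak-overlap covariance, shift jitter and
  log-normal amplitude variation are, which is what stresses bin mapping,
  pruning and the calibration caveats above.

What passing tests on these cohorts show — and do not show: recovery and
calibration results demonstrate the statistical machinery under the stated
generative model; real urine spectra add phased/misreferenced lineshapes,
pH-dependent local (not global) shifts, and metabolite correlations from
shared physiology, so absolute performance numbers do not transfer, while
the contracts (filtering order, clumping semantics, threshold arithmetic,
estimator equivalences) are data-independent.

## Study sizes used in the bundled validation

Oracle equivalence uses 100 random small instances per estimator
(OLS/IVW vs statsmodels, clumping/pruning vs brute-force greedy oracles,
agreement to 1e-8). Metabomatching: null KS on a 200-metabolite decoy
library; recovery over 25 seeds (n = 500, 10% explained variance, 3-peak
metabolite, 100-metabolite library). Discovery calibration: 10 null cohorts
of 200 individuals × 2,000 SNPs × ~300 features (6M tests). Heterogeneity:
50 seeds at n = 800 with 500 permutations (recovery) and 50 single-causal
seeds with 300 permutations (calibration bound). MR: 400-seed coverage at
n = 5,000, 400-seed Durbin–Hausman size at n = 1,000, and a 3-point
analytic-vs-simulated power comparison at 2,000 replicates per point.
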