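# Methods

`countgwas` implements a developmental genetic analysis of an overdispersed
count phenotype measured repeatedly across childhood and adolescence: a
social-communication problem score (a 12-item informant-report screen with
integer scores 0–24) observed at up to four ages in a population cohort of
unrelated, genotyped individuals. The pipeline estimates how much trait
variance common SNPs capture at each age, how stable those genetic effects
are across ages, which individual variants associate with the counts, and
whether the associated regions co-locate with a candidate-gene set more
often than a permutation null allows.

## Models and procedures

### Synthetic cohort generator

Real cohorts of this kind are access-restricted, so a generator stands in
for them and defines the conditions every downstream test runs under.

**Genotypes.** SNPs are laid out in blocks. Each haplotype draws one
standard-normal factor per block plus an independent residual per SNP, so
latent values within a block have exchangeable correlation
`within_block_rho`; an allele is called where the latent value falls below
the allele-frequency quantile, and dosage is the sum of two haplotypes.
This thresholded-Gaussian LD model is deliberately simple: the implied
dosage r² between any two SNPs is checkable by direct Monte-Carlo
integration, which is how the generator is tested. Allele frequencies are
uniform on `maf_range` (default 0.05–0.5). It makes no attempt at realistic
human haplotype structure, recombination maps or ascertainment.

**Phenotypes.** Each individual carries a latent Gaussian liability per
age, split into a genetic part and a residual part. The genetic part is
built from a shared set of causal SNPs whose per-age effect vectors are
mixed through the matrix square root of the target genetic-correlation
matrix `rg_matrix`; the residual part is multivariate normal with
correlation `re_matrix`. Both are scaled so the latent-scale heritability
per age equals `h2_by_timepoint`. Given the liability, the observed score
is Poisson with rate `exp(baseline + covariates + liability) × frailty`,
where the frailty is Gamma(θ, θ) — so the marginal count distribution is
negative-binomial with variance/mean → 1 as θ → ∞. The true
score-generating distribution of the instrument is unknown; the
negative-binomial choice is a stand-in whose closed-form moments make the
generator testable.

The frailty is drawn **once per individual and shared across ages** by
default. This represents a stable reporter effect — the same informant
rates the same child at every age — and is what lets the generator
reproduce the observed-scale cross-age score correlations (≈0.4–0.6 in
cohorts of this kind) while keeping the per-age margins negative-binomial.
With independent per-age frailty (`shared_frailty=False`) the count-scale
correlations attenuate to ≈0.15–0.25 even when the latent correlations are
0.5–0.6, because Poisson and frailty noise dominate at a median count of 1.

Default generative targets (frozen before any acceptance measurement, from
the cohort the generator emulates): per-age heritabilities
(0.24, 0.16, 0.08, 0.45) at ages (8, 11, 14, 17); genetic correlations
0.82–0.97 between adjacent ages decaying to ≈0.51 across the 8–17 span;
residual correlations 0.35–0.56; count median 1–2, SD ≈ 3.5–3.8, range
0–24. The count-scale parameters `latent_sd = 1.2`, `dispersion_theta = 4`,
`baseline_log_mean = 0` were calibrated once against those targets: at
n = 5,000 with the bounded instrument (`clip_to_range=True`) the generator
yields per-age SDs 3.3–3.5, median 1, and adjacent-age Spearman
correlations 0.41/0.37/0.32. Clipping at the instrument maximum of 24 is
**off** by default because a hard ceiling distorts the count model the
association tests assume; it is turned on when emulating the bounded
instrument.

What the generator does *not* emulate — family structure and cryptic
relatedness, item-level psychometrics of the instrument, genotyping batch
effects, real LD decay — bounds what passing tests show: they validate the
estimators under the stated model, not robustness to those artefacts.

### Heritability (GRM + REML)

The genetic relationship matrix is the standard allele-frequency-
standardised cross-product, averaged over SNPs non-missing in both members
of each pair; monomorphic SNPs are excluded. Phenotypes entering REML are
residuals on age, sex and two ancestry covariates, mapped through the
rank-based inverse-normal transform with the Blom offset
((rank − 3/8)/(n + 1/4); ties get average ranks). The offset is not
identified by any external constraint; Blom is the common default and is
configurable.

The variance-component fit works in the eigenbasis of the GRM: with a
single GRM and iid residuals, `V = σ²_g A + σ²_e I` is diagonal after
rotation (2×2-block-diagonal in the bivariate case, since both traits
share the GRM), so one symmetric eigendecomposition per fit makes every
REML iteration O(n). Updates are average-information (AI) steps with
step-halving whenever a step would decrease the restricted likelihood; the
univariate fallback is the EM update (guaranteed ascent, property-tested),
the bivariate fallback a bounded Nelder–Mead polish of the same
log-likelihood. Convergence requires |Δ log L| < 10⁻⁶ and a maximum
component change < 10⁻⁶; non-convergence raises an error carrying the
log-likelihood trajectory. Variance components are constrained
non-negative by default (floor 10⁻⁸ × trait variance); correlation-type
covariances are clamped to |r| ≤ 0.9999, which is why identical traits
report r_g ≈ 0.9999 rather than exactly 1.

Degenerate inputs: a GRM whose eigenvalue spectrum is (near-)constant —
e.g. the identity — makes σ²_g and σ²_e jointly unidentifiable; the fit
refuses with an explicit error rather than returning an arbitrary split.
In the bivariate model, a trait whose genetic variance collapses below 1%
of its phenotypic variance has no meaningful genetic correlation; r_g is
returned as NaN with a flag rather than a clamped ±1.

Standard errors come from the inverse AI matrix with the delta method for
h² and the correlations. The heritability likelihood-ratio test against
σ²_g = 0 is referenced to χ²₁ with 1 df by default — matching the
reporting convention of the analyses this package reproduces — with the
½χ²₀ + ½χ²₁ boundary mixture available as an option.

### Association scan (quasi-Poisson + genomic control)

Untransformed counts at one age are regressed on intercept, age at
measurement, sex, two ancestry covariates and allele dosage, with a
Poisson log link fitted by IRLS (start: zero slopes, intercept
log(mean + 0.5); tolerance 10⁻⁸ on deviance; 50 iterations max). The
quasi-likelihood dispersion φ = Pearson X²/(n − p) scales the Poisson
standard errors by √φ; Wald statistics are referenced to the standard
normal (n is in the hundreds to thousands; a t reference would change
nothing material). φ may be 0 for a saturated/constant fit, in which case
the SEs are degenerate and non-inferential. Missing scores are handled by
per-age listwise deletion; missing dosages per SNP. Per-SNP failures (e.g.
a dosage collinear with the intercept in the analysed subsample) yield NaN
rows and the scan continues.

Genomic control: λ = median(Wald²)/0.454936 (the χ²₁ median); corrected
statistics are Wald²/max(λ, 1), corrected p-values the χ²₁ upper tail.
Flooring λ at 1 (no deflation of p-values when λ < 1) is the conservative
convention and is configurable. Correction is rank-preserving by
construction.

### LD clumping

LD is the squared Pearson correlation of dosage vectors (composite LD; no
phasing). Index selection is p-value-ordered greedy clumping: the
smallest-p unassigned SNP becomes an index and absorbs every unassigned
SNP within ±window (default 500 kb) with r² > threshold (default 0.3);
ties on p break to the smaller genomic coordinate, so the result is
invariant to input row order. Clumped regions span the member SNP
positions; gene overlap is evaluated in 0-based half-open coordinates with
≥1 bp sufficing.

### Permutation null

The empirical familywise null jointly permutes each individual's entire
phenotype record — scores **and** ages-at-measurement at all time-points
travel together — against the genotype + sex + ancestry record (sex and
ancestry are genotype-linked and stay put). A scores-only mode exists for
comparison. Index SNPs and their clumped regions come from the observed
data and stay fixed across permutations. Each permutation rescans the
index panel at every configured age, re-estimates genomic control within
the permuted scan (the thresholds are GC-corrected p-values, so permuted
statistics must be on the same scale), and records the minimum corrected
p over all index SNPs and ages.

For each threshold, `k_exceed` counts permutations whose minimum beats it
and `k_coloc` counts those where additionally a passing SNP's region
overlaps ≥1 candidate gene. The primary co-location p is the **joint**
event k_coloc/S — the only reading under which a co-location p can be
smaller than its exceedance p, as in the results this machinery mirrors —
with the conditional ratio k_coloc/k_exceed reported alongside. Empirical
p-values use k/S to match the convention of the reported values; the
(k+1)/(S+1) estimator is available as an option. Standard errors are
binomial, √(p(1−p)/S).

Per-permutation RNG seeds are spawned from the master seed by permutation
counter, so chunked, resumed or re-ordered execution reproduces the
single-run counts exactly (property-tested). The score-test fast path for
permuted scans is not implemented; the exact refit is fast enough at the
panel sizes the permutation stage sees (index SNPs only).

### Pipeline

Stage order: simulate/load → marker QC (remove MAF < 0.01, call rate
< 0.95, HWE p < 5×10⁻⁷ by 1-df chi-square on hard calls, imputation
R² ≤ 0.8; reasons reported with precedence maf → call_rate → hwe →
impute_r2) → GRM → per-age REML → scan the configured number of ages with
the highest estimated h² (reproducing the phenotype-selection logic rather
than hard-coding ages) → genomic control → clumping on the scan with the
strongest signal → permutation null → JSON report. Every artifact carries
the config hash and seed; completed stages are no-ops on re-run unless
forced; a stage failure surfaces the stage name and leaves a resumable
state file. The 1-df chi-square HWE test (not the exact test) matches the
QC regime this pipeline mirrors; at the 5×10⁻⁷ threshold both order
markers identically, and the function is isolated so it can be swapped.

## Problem sizes and error budget for the replication suites

The suites in `countgwas.benchmarks` (driven by both the heavy tests and
`scripts/acceptance.py`) use sizes chosen so each conclusion is resolved
with margin:

- **GREML recovery**: 12 replicates at n = 1,200, m = 2,000 per true h² ∈
  {0.10, 0.25, 0.45}. The per-replicate sampling SD of ĥ² is ≈ √(2m)/n ≈
  0.053, so the mean over 12 replicates has SE ≈ 0.015 against the 0.05
  acceptance band. Recovery is evaluated on the latent Gaussian
  liabilities, where the configured h² is exact ground truth; count-scale
  estimates are attenuated by Poisson/frailty noise by design.
- **Bivariate recovery**: 6 replicates at n = 1,200, true r_g = 0.5,
  r_e = 0.4, h² = 0.4 both traits; the mean is compared at 2 SE.
- **Quasi-Poisson calibration**: 1,000 null SNPs at n = 2,000 with gamma
  frailty giving φ ≈ 2; the 3-binomial-SE band around 0.05 is ±0.021.
- **Genomic control**: one null scan of 10,000 SNPs at n = 800.
- **Clumping**: 200 random 20-SNP instances against a literal brute-force
  re-execution of the greedy definition.
- **Permutation machinery**: n = 500, 200 index SNPs, two ages, S = 200,
  with the 5%-threshold pre-calibrated from an independent pre-run.
- **End-to-end smoke**: n = 500, m = 2,000 (1,200 in the script), S = 100
  (50 in the script), run twice and compared byte-for-byte.

## Known limitations

- Sample-level QC (sex checks, heterozygosity, relatedness pruning) is out
  of scope; the generator produces unrelateds.
- The bivariate REML requires both traits observed on the same individuals
  (individuals missing either trait are dropped); unequal designs are not
  supported.
- Single-chromosome simulation; multi-chromosome inputs are handled by the
  QC/clumping code (windows never span chromosomes) but the generator does
  not produce them.
- X-chromosome dosage conventions, mixed-model association, reference-panel
  LD and multi-component GREML are not implemented.
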