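# Methods

This note documents the models, defaults, and numerical choices behind
`admixprs`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The C+T model and its evaluation

The score for individual *i* is `PRS_i = Σ_j β_j G_ij` over the variants
surviving clumping and a p-value ceiling, with `β_j` the base-GWAS log-odds
effect aligned to the target's counted allele. Harmonization matches base to
target by chromosome and position; a swapped allele pair negates the effect;
strand-ambiguous (A/T, C/G) pairs are excluded outright — no
frequency-based rescue is attempted, the conservative default when the
provenance of strand information is unknown. Missing dosages are mean-imputed
per variant before both LD computation and scoring, the standard C+T
behaviour.

Clumping is greedy: the unabsorbed variant with the smallest p becomes an
index and absorbs unabsorbed same-chromosome variants within
`|Δpos| ≤ window_kb·1000` whose dosage r² with the index exceeds `r2_max`.
LD is computed on the analysis cohort's own dosages (the tool-default
"target LD" convention), on the training side only. Ties on p break by
chromosome label (numeric labels first), then position, then variant ID, so
the output is invariant to input row order.

The inclusion-threshold scan uses a fine additive grid: 5×10⁻⁸, then steps
of 5×10⁻⁵ up to the ceiling, plus the ceiling itself. This lets the selected
threshold fall strictly below the ceiling (e.g. 8.5×10⁻⁵ under a 10⁻³
ceiling), as threshold-optimizing tools report. The scan keeps the fit
maximizing `R²_PRS`; thresholds where no variant survives are recorded and
skipped.

### Logistic engine

Fits are maximum-likelihood logistic regressions solved by Newton/IRLS with
step halving: convergence at |Δ log-likelihood| < 1e-8, at most 100
iterations; perfect separation is reported (never silently converged) when
any coefficient passes |15|; rank-deficient designs are an error. The solver
is in-package because the permutation machinery refits the whole threshold
scan per permutation (hundreds of thousands of small fits); the test suite
cross-checks coefficients, standard errors, and log-likelihoods against an
independent implementation (statsmodels) and against direct numerical
maximization of the likelihood.

### Variance decomposition

Nagelkerke's R² is the Cox–Snell ratio `1 − exp(2(ll₀ − ll₁)/n)` rescaled by
its maximum `1 − exp(2·ll₀/n)`. Both the full (PRS + covariates) and null
(covariates only) models are referenced to the intercept-only likelihood, so
`R²_PRS = R²_full − R²_null ≥ 0` holds by construction.

The ascertainment adjustment maps observed-scale R² to the liability scale
via the Lee et al. (2012) transformation with prevalence K, case fraction P,
threshold `t = Φ⁻¹(1−K)` and `z = φ(t)`:
`C = K(1−K)/z² · K(1−K)/(P(1−P))`, `θ = d(d−t)` with `d = (z/K)(P−K)/(1−K)`,
adjusted `= C·R²/(1 + C·θ·R²)`. When P = K this reduces to the pure
observed-to-liability factor. The default prevalence is 1.386×10⁻⁴ (global
Parkinson's disease prevalence); it is a default, not a fitted quantity, and
is configurable everywhere it enters (liability adjustment and PPV/NPV).

### Permutation significance

The observed statistic is the Wald p of the selected (max-R²_PRS) fit; each
permutation shuffles phenotype labels (covariates stay attached to samples,
case/control counts are preserved exactly), refits every threshold of the
scan, and records the scan-minimum Wald p — this corrects for the
optimization over thresholds. The empirical p is
`(#{perm best p ≤ observed p} + 1)/(n_perm + 1)`, floor `1/(n_perm+1)`.
The reference protocol uses 10,000 permutations; tests and the bundled
configuration profiles use 199–200 and record the value in the run log.

### Discrimination and predictive values

AUC is the Mann–Whitney estimator (ties 0.5) with a DeLong-variance normal
95% CI; paired model comparisons use the DeLong placement-value test, with
the zero-variance self-comparison returning p = 1 with a warning.
Confusion metrics use the fixed probability cut-off 0.5. Top-percentile risk
flags (5/10/20% by default) break score ties by strict score order then
sample ID so the flagged count is exact; cohort sensitivity and specificity
at the flag are converted to PPV/NPV by Bayes' rule under the external
prevalence — the cohort's (ascertained) case fraction never enters.

The train/validation split is unstratified, uniform without replacement,
with training size round-half-up of `proportion·n` (0.7 × 1,398 = 978.6 →
979/419). Stability is assessed across 20 random splits by default. The
validation stage applies the training-selected window/r²/ceiling and
re-scans only the fine threshold (clumping is recomputed on the validation
cohort's own LD, as a fresh run of the tool on that cohort would).

### Attribution

Leave-one-out ranking freezes the final model's betas and SNP set: each SNP
is removed in turn without re-clumping or re-thresholding, the covariate
model is refit, and the AUC change recorded; ranking is on the training
cohort (configurable). A removed SNP with aligned beta 0 has ΔAUC exactly 0
without refitting. Carrier-ancestry profiles count haplotypes (an individual
with dosage 2 contributes two carrier haplotypes), because local ancestry is
haplotype-resolved; percentages are over hard-call segments, not marginal
probabilities.

### Covariate scenarios

The seven scenarios are the non-empty subsets of {AGE, SEX, ANC}, with ANC
an atomic block of the retained ancestry-proportion columns. One ancestry
column (default MAL, the smallest mean contribution in the default design)
is dropped against perfect multicollinearity, since the full proportion set
sums to 1. The threshold scan is repeated per scenario — the selected SNP
count legitimately differs across covariate sets. The null R² of a scenario
depends only on the cohort and covariate set, never on the base summary
statistics; the suite asserts this by running two distinct base files.

## The synthetic cohort generator

The generator emulates the data shapes the pipeline consumes, not any
specific population's genetics:

- **Admixture.** Each individual draws ancestry proportions from a
  five-component Dirichlet (labels AFR, EUR, MAL, NAMA, SAS; default
  concentration (3.0, 2.5, 1.0, 2.5, 1.0), i.e. mean proportions
  0.30/0.25/0.10/0.25/0.10 with realistic between-individual spread).
  Haplotypes are tiled by tracts whose switch points follow a Poisson
  process with rate g per Morgan (default g = 15 generations, an admixture
  age of roughly three to four centuries) on a uniform 1 cM/Mb map; each
  tract's ancestry is an independent draw from the individual's proportions.
  Same-ancestry neighbours merge, so observed switch counts are
  `g·L·(1 − E[Σ p_k²])` in expectation.
- **Allele frequencies.** Balding–Nichols: ancestral frequencies uniform on
  (0.05, 0.95); population-specific frequencies Beta-distributed with mean
  equal to the ancestral frequency and variance `F·p(1−p)` (default F per
  ancestry 0.15/0.10/0.12/0.20/0.11). Alleles are drawn per haplotype from
  the local ancestry's frequency at each site. There is no background LD
  within ancestries — LD in the cohort arises from admixture structure only,
  so clumping instances are milder than in real imputed data.
- **Phenotype.** Logistic on the log-odds scale with centered genetic and
  covariate terms (age effect 0.04 per year, sex effect 0.4, ancestry
  effects ±0.2–0.3 by default); the intercept is solved by Brent's method so
  the expected case fraction equals 661/1398 ≈ 0.4728, the cohort shape the
  default n = 1,398 mirrors. A logistic (not threshold-liability) phenotype
  was chosen to match the downstream logistic evaluation model.
- **Base GWAS.** Estimated effects are the true effects plus Gaussian noise
  with SE `1/√(2·N·f(1−f))` (default discovery N = 40,000), p-values from
  the two-sided Wald statistic. The default genetic architecture is sparse:
  50 causal variants of ±0.12 log-odds among 1,200 sites on four 50-Mb
  chromosomes.

What passing tests on this generator do **not** show: performance on real
imputed genotypes with within-ancestry LD, relatedness structure,
imputation error, or genuine effect-size heterogeneity across ancestries.
The generator's parameters are illustrative study conditions, not a
calibration to any published cohort's headline numbers, which derive from
access-restricted data.

## Numerical and design choices

- Variant positions are 1-based (VCF convention); ancestry segments are
  0-based half-open (BED convention); conversion happens exactly once, at
  segment lookup (`pos − 1` into the half-open interval).
- Odds-ratio effect columns are accepted only via an explicit column map,
  never inferred from magnitudes.
- r² of a monomorphic dosage vector is 0 with a warning; fewer than two
  complete pairs is an error.
- Grid-search ties on R²_PRS break toward the smaller ceiling, then window,
  then r².
- All randomness flows from one master seed through fixed named offsets
  (phenotype +2, base GWAS +3, split +101, permutations +202/+203,
  stability +303+i), so any stage is independently reproducible.
- Problem sizes in the test suite (cohorts of 120–600 samples, 40–1,000
  variants, 199 permutations, 20–50 replicates) are the package's own
  scaled-down study conditions for fast, deterministic verification; the
  defaults of the library itself remain the full design (n = 1,398, 48-way
  grid, 10,000 permutations).

## Known limitations

- No reference-panel LD, conditional clumping, or shrinkage PRS
  (LDpred/lassosum-style methods are out of scope).
- Genome-build harmonization (LiftOver) is not performed; inputs must share
  one coordinate system.
- G-Nomix output is consumed only after conversion to the hard-call segment
  TSV dialect; marginal probabilities are not used.
- The liability-scale adjustment assumes a single homogeneous prevalence;
  ancestry-specific prevalences are not modelled.
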