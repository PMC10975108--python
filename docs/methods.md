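# Methods

This note documents the statistical machinery implemented in `pedprs`, the
assumptions baked into the synthetic cohort generator, and the numerical
conventions that matter for reproducing results.

## Study design being modeled

A cross-sectional pediatric cohort: preschool children genotyped on a
candidate panel of BMI-associated SNPs, with measured height/weight, serum
25(OH)D, and a roster of perinatal and socio-economic covariates. The
analysis asks how a weighted polygenic risk score (PRS) and vitamin D status
each relate to BMI-for-age z-score (zBMI), and whether they interact. All
outcome inference is rank-based because zBMI and 25(OH)D are not normally
distributed in such cohorts.

## Genotype quality control

Per SNP, in fixed order, with each SNP receiving exactly one verdict:

1. **missing rate** > 5% → `fail_missing` (an "unavailable" assay is the
   limiting case, missing rate 1);
2. **MAF** < 1% → `fail_maf`, computed from called genotypes only
   (complete-case; the folded frequency min(f, 1−f));
3. **HWE** exact p < 10⁻⁶ → `fail_hwe`.

Filtering missing-first guarantees unavailable SNPs never contribute
unstable frequency estimates; when the failure sets are disjoint the
per-reason counts do not depend on the order.

The Hardy–Weinberg test is the conditional exact test: given the observed
allele counts, the heterozygote count under random mating has distribution

P(n_het) = 2^{n_het} n! / (n_rr! n_het! n_cc!) × n_r! n_c! / (2n)!

over counts with the parity of the rare-allele total. The two-sided p-value
sums the probabilities of all configurations no more probable than the
observed one (ties included, with a 10⁻¹⁰ relative tolerance). Probabilities
are computed by log-gamma and renormalized; the test suite verifies equality
with exact rational enumeration for every table with n ≤ 50. The exact test
was preferred over the 1-df chi-square because at the 10⁻⁶ threshold the
chi-square tail is unreliable for rare alleles; the chi-square version
remains available (`hwe_method="chi2"`) and is checked against the exact
test's accept/reject decisions at large n.

## Polygenic risk score

PRS_i = (Σ β_j g_ij) × n_i / (Σ β_j), both sums over subject *i*'s called
SNPs. Implemented exactly as defined, including the *signed* denominator:
with mixed-sign weights the per-subject β-sum can approach zero, in which
case the score explodes. Subjects whose |Σβ| falls within 10⁻¹⁰ are flagged
unscorable and excluded from downstream analysis (counted in the run
report) rather than silently zeroed; an advisory log line reports the sign
and magnitude of the full-panel β-sum. A magnitude-normalized variant
(divide by Σ|β|) exists behind `normalization="abs"` for sensitivity
analysis but is off by default.

Risk groups use floor-rank counts: k = ⌊0.1·n⌋ subjects at each extreme.
This is the only convention that produces a 104/838/104 split at n = 1046.
Boundary ties are resolved by stable input order — ascending stable sort,
earlier-seen subjects fill `low`, later-seen fill `high` — and logged.

## LMS z-scores

z = ((X/M)^L − 1)/(L·S), with the log-form limit used for |L| ≤ 10⁻⁸, then
the restricted adjustment of growth-standard software: scores beyond |z| = 3
are linearized in units of the SD2–SD3 gap, SDk = M(1 + L·S·k)^{1/L}. The
transform is continuous at the seams (verified to 10⁻¹² in tests), strictly
increasing in X, and exactly invertible; `lms_inverse` round-trips z over
[−5, 5] to better than 10⁻⁹.

Ages are matched to the reference grid by the completed-month convention
(nearest whole-month knot ≤ age + 0.5). Under-5 and over-5 references can be
supplied as a single table spanning the cohort's ages; the package ships a
smooth synthetic LMS table (both sexes, 36–84 months) whose CSV schema
matches real references, which are drop-in replacements. |z| > 5 is flagged
implausible but retained; exclusion is the pipeline's ± 4 SD screen.

## Nonparametric inference

All tests rank jointly with average ranks for ties and report two-sided
p-values.

- **Spearman**: Pearson correlation of ranks; p from the t-reference with
  n − 2 df.
- **Partial Spearman** (covariate adjustment): rank every variable,
  residualize ranked x and ranked y on the ranked covariate matrix by least
  squares with intercept, correlate the residuals; t-reference with
  n − 2 − k df. Categorical covariates are indicator-coded (first level as
  reference). If the covariates explain either rank vector to numerical
  exhaustion, the partial correlation is reported as 0 with p = 1.
  The adjustment scheme for rank correlations is not uniquely defined in the
  field; rank residualization is the common choice and is verified against
  pingouin's partial correlation in tests.
- **Wilcoxon rank-sum**: exact enumeration of all C(N, n_a) rank
  assignments when the pooled size is ≤ 12 (the distribution is symmetric
  about its mean, so the two-sided p is the mass at least as far from the
  mean as observed); otherwise tie-corrected normal approximation without
  continuity correction.
- **Kruskal–Wallis**: tie-corrected H against chi-square with k − 1 df;
  an all-identical sample returns H = 0, p = 1.
- **Dunn's post-hoc**: pairwise z on joint mean ranks with pooled tie
  correction, valid for unequal group sizes; Bonferroni adjustment over all
  pairs by default (Holm optional). Bonferroni was chosen because the
  adjustment used by the classical SAS macro implementations is not
  specified; it is conservative, which the familywise-error simulation in
  the tests confirms.
- **Trend across ordered groups**: Jonckheere–Terpstra (cross-group
  concordant pairs, ties counted ½), chosen as the standard ordered-
  alternative rank test; exact enumeration for N ≤ 10, otherwise the
  tie-corrected normal variance (Hollander–Wolfe form). Two-sided p is
  twice the smaller tail, observed point included, capped at 1.
- **Interaction**: Scheirer–Ray–Hare on ranks, kept inside the rank
  paradigm. The interaction sum of squares is SSE(additive) − SSE(full
  cell-means) via least squares (the Type-II interaction SS, verified
  against statsmodels' two-way ANOVA on ranks), divided by
  MS_total = SS_total/(N−1) and referred to chi-square with (a−1)(b−1) df.
  This is an interpretation of "rank-based interaction test", not a
  reproduction of any particular macro.
- **Chi-square**: Pearson statistic without continuity correction;
  zero-marginal rows/columns dropped with a warning; expected counts < 5
  warned.
- **rank R²**: R² of ranked-y on ranked-x least squares, identically the
  squared Spearman coefficient.

## Pipeline conventions

- Exclusion ledger with first-reason precedence (unscorable PRS → missing
  anthropometry → missing 25(OH)D → outlier), so analyzed + excluded counts
  always reconcile with the input count.
- Outlier screen: single pass, mean ± 4 SD computed on the pre-filter
  sample, applied to zBMI and 25(OH)D by default (configurable). The
  monitored-variable set is a design choice; the rule is deliberately not
  iterated.
- Descriptives: median (P25, P75) with linear-interpolation quartiles;
  categorical counts with percentages rounded to one decimal (totals may
  not reach 100%).
- Adjustment models: I crude; II sex, age, birth length, birth weight;
  III additionally all remaining covariates including SES.
- Vitamin D dichotomized at 30 ng/mL, boundary inclusive on the
  insufficient side.
- Reports are fully deterministic given (inputs, config): no timestamps in
  the report body.

## The synthetic cohort generator

What it emulates, with defaults as the study conditions:

- **Genotypes**: per-SNP independent draws from HWE proportions with an
  optional inbreeding coefficient F planting heterozygote deficits
  (P(het) = 2pq(1−F)); independent missingness. No linkage disequilibrium,
  population stratification, or genotyping-error model.
- **Weights**: β ~ N(0, 0.02) — signed, symmetric about zero. An
  all-positive panel could never yield the negative score medians seen with
  mixed-direction GWAS weights.
- **25(OH)D**: log-normal with median 33.63 ng/mL and log-sd 0.324 (set
  from a 26.79–41.46 IQR) — right-skewed, positive support.
- **Covariates**: drawn independently of each other and of genotype, with
  realistic marginals for a rural preschool cohort (e.g. 3.7% premature,
  60.4% vaginal delivery, 49.8% in the nutrition-intervention arm). The
  true covariance structure of such covariates is unknown; independence is
  the documented default, which means covariate adjustment in simulated
  data changes estimates only through noise.
- **Phenotype planting**: the latent zBMI combines the *normal scores* of
  the true PRS and of 25(OH)D with independent Gaussian noise, scaled to
  unit variance, with coefficients 2·sin(π·r_s/6) so the realized Spearman
  correlations are centered on the configured targets (+0.10, −0.11 in the
  main preset) regardless of the variables' marginals — planting on raw
  standardized values would attenuate the rank correlation for the skewed
  25(OH)D. Weight and height are then obtained by inverting the LMS
  reference at the latent z (height from a linear age trend with 3 cm
  noise), so re-scoring the cohort recovers the planted z to floating-point
  accuracy.
- **Seeding**: one integer seed, split into independent per-stage streams
  via numpy `SeedSequence` spawn keys; identical (config, seed) gives
  byte-identical outputs.

Presets: `paper_cohort` (1046 subjects × 55 clean SNPs, planted effects
+0.10/−0.11) and `qc_stress` (85 candidates: 8 with effect-allele frequency
0.002, 13 with F = 0.9 at MAF ≥ 0.10 so they cannot also trip the MAF
filter, 9 fully missing, 55 clean at 2% missingness — engineered so the
9/8/13/55 QC partition is near-certain at n = 1046).

What passing tests on synthetic data do **not** show: robustness to LD
between panel SNPs, to confounding between genotype and environment, to
assay batch effects, or to misspecified growth references. The simulator
validates the *machinery*, not the epidemiology.

## Problem sizes and runtime choices

Simulation-based checks use sizes chosen to keep the whole suite fast while
leaving Monte Carlo error well inside the asserted bands: type-I error
calibration at 10,000 null replicates (5,000 for the interaction test on the
cohort-shaped 3×2 layout at n = 1046), planted-effect recovery over 100
seeded cohorts of 1046, effect-calibration means over 200 cohorts, and
familywise-error simulation for Dunn at 2,000 replicates. The HWE exact
test is verified against rational enumeration for all ~1,300 distinct
allele-count configurations with n ≤ 50.

## Known limitations

- The signed-denominator PRS rescaling is faithful to the scoring
  convention but numerically fragile when a subject's available β-sum nears
  zero; such subjects are excluded, not repaired.
- The exact Wilcoxon path enumerates combinations and is limited to pooled
  n ≤ 12; beyond that the normal approximation (no continuity correction)
  is used.
- The Scheirer–Ray–Hare chi-square reference is asymptotic; its finite-
  sample level is verified by simulation only for cohort-sized designs.
- VCF ingestion matches alleles exactly (no strand flipping); palindromic
  A/T and C/G SNPs only produce a warning, so strand-ambiguous panels need
  upstream harmonization.
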