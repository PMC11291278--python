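# Methods

This note documents the models, estimators, defaults and design choices in
divqtl, and what the synthetic-truth benchmarks do and do not establish.

## Synthetic cohort

The generator emulates a globally diverse RNA-seq cohort: 5 continental
groups nesting 26 populations (7/4/5/5/5 by default, reducible), 28 samples
per population (matching the 27–30 per population of comparable real
resources), sequencing batches stratified within populations, and random sex.

**Genotypes** follow a nested Balding–Nichols model. Ancestral allele
frequency p ~ Uniform(0.05, 0.95); group frequency
Beta(p(1−F)/F, (1−p)(1−F)/F) with `f_group = 0.10` (continental-scale human
differentiation); population frequencies nested with `f_pop = 0.01`.
Haplotypes are Bernoulli draws from the population frequency, so dosages are
haplotype sums and phase is exact. When `use_ld_templates` is on, haplotypes
are instead copied from per-population pools of 16 template haplotypes in
blocks of 20 adjacent variants, inducing local LD whose pattern differs
between populations (the ingredient needed for the interaction-mechanism
study); expected frequencies are unchanged. This is a deliberate
simplification of coalescent LD: no recombination maps, no admixture decay
curves. Degenerate case: F = 0 uses the parent frequency exactly.

**Expression** is generated from the allelic-fold-change model, multiplicative
across causal variants and averaged over the two haplotypes, times
2^(batch + sex + interaction + ε) with ε ~ N(0, 0.5·m_g) log2 units (m_g
per-group noise multipliers, default 1). Counts are Poisson around
library-size-scaled means (library sizes log-uniform in [0.5, 2]); a
negative-binomial switch (`overdispersion`, default 0; 0.1 recommended for
DE realism) exists for differential-expression studies. Genes carry 0–3
causal cis variants with probabilities (0.25, 0.40, 0.25, 0.10) — chosen so
that roughly the observed proportions of genes with no, one, or several
independent signals arise — and |log2 aFC| uniform in [0.25, 2] with random
sign. Causal variants require realized MAF ≥ 0.05.

**Splicing** phenotypes are per-cluster Dirichlet intron-excision ratios
(2–4 introns, concentration 60); an sQTL multiplies one intron's
concentration by 2^(β·g). Ratios sum to one within a cluster by construction.

**Variance-partition phenotypes.** `simulate_varpart_phenotype` defines its
`between_pop_frac` parameter as the *expected plain eta-squared* of the
one-way population model at the generated design, and solves
(k−1)(1 + (m−1)v) = f(n−1)(1 + v) for the population-effect variance v.
Rationale: the reported estimator is plain eta-squared, whose null floor is
(k−1)/(n−1) (≈3.4% at 26 populations and n≈730); defining the generator's
fraction on the estimator's own scale makes "recover 8% within ±2 points" a
statement about the pipeline rather than about small-sample ANOVA bias. No
bias adjustment is applied to the estimator itself.

## Phenotype preparation

Median-of-ratios size factors against the geometric-mean pseudo-reference
(features containing any zero excluded from factor estimation; factors
normalised to geometric mean 1), then log2(count/sf + 1), then a per-feature
rank inverse-normal transform Φ⁻¹((rank−0.5)/n) with average ranks for ties,
then OLS residualisation on batch indicators + sex (+ optionally the top 10
expression PCs as a hidden-factor stand-in; count configurable). The
normalization recipe is recorded in code as a swappable choice. Missing
genotypes are imputed to the rounded per-variant mean dosage; variants with
>5% missingness are dropped.

## Variance partitioning

Per feature, eta-squared from two separate one-way fits (group labels;
population labels), reported in percent. Two separate fits rather than a
sequential nested ANOVA: the two averages are reported side by side and the
nesting is enforced as the invariant R²_pop ≥ R²_group instead of being
decomposed. The permutation test is global (one p per label level): the
statistic is the across-feature mean R², labels are permuted jointly so the
population→group nesting is preserved, and p = (1+#{null ≥ obs})/(1+n_perm).
The heteroskedasticity test models the N = features × groups per-feature
per-group sample variances with a Gamma GLM (log link) of variance on group
label; the analysis-of-deviance LRT (scaled by the full model's dispersion)
is χ² with df = n_groups − 1, one-tailed. Realizing the test this way is an
interpretive choice: the shape of the reported statistic (df = 4, N = genes ×
groups) constrains but does not uniquely determine the model. Zero-variance
cells are floored at 1e-12 and flagged.

## cis scanning and eGene calling

Candidates: variants within 1 Mb of the TSS, inclusive at both boundaries,
sample MAF ≥ 0.01 (the downstream frequency analyses apply their own printed
thresholds). Nominal test: per-variant simple regression of the prepared
phenotype on dosage, t = r√(df/(1−r²)) with df = n − 2 − k for k residualised
covariates. Gene-level empirical p: permute the phenotype (1000 by default),
take the best nominal p per permutation, fit Beta(a, b) to the permutation
minima by maximum likelihood, and evaluate its CDF at the observed best p;
the direct empirical rank p is also reported and used as fallback if the fit
fails. eGenes: Benjamini–Hochberg at 5% FDR (BH rather than Storey for
dependency-free reproducibility; switchable), with the per-gene nominal
threshold recovered through the Beta quantile at the BH cutoff.

## Fine-mapping

The sum-of-single-effects model with L = 10 effects, fitted by iterative
Bayesian stepwise selection in sufficient-statistic space (XᵀX, Xᵀy), so a
sweep costs O(Lp²) independent of n. Per effect, the prior variance is
estimated by maximising the single-effect marginal likelihood (bounded
scalar optimisation on the log scale, guarded never to step downhill, with a
null check that switches the effect off when the fitted model does not beat
the null). Residual variance updates to ERSS/n each sweep. The ELBO uses the
exact closed-form KL of each effect's posterior against its prior and is
asserted non-decreasing (1e-8 slack); convergence at ΔELBO < 1e-4.

Credible sets: smallest posterior-sorted prefix reaching 95% coverage, per
active effect; purity = minimum absolute genotype correlation among members,
sets with purity ≤ 0.5 dropped; identical sets deduplicated. Intron-level
sets of a gene are merged by shared-variant connected components (iterated to
closure); union of variants, per-variant PIP the maximum across merged sets.
An LD-based alternative (merging leads with r² > 0.8) is not implemented;
the shared-variant rule is the recorded interpretation of "iteratively
merging". Lead QTL: highest PIP, ties by smaller |TSS distance|, then
lexicographic variant id.

## Effect sizes (aFC)

Dosage-based (phase-free) multiplicative model, exact for one causal variant
and an approximation of the haplotype model for several; fitted by
box-constrained least squares on log2 of the size-factor-scaled counts plus
pseudocount 1, intercept profiled out, initialised from marginal per-lead
slopes. Effects are capped at |log2 aFC| ≤ log2 100 (the convention of
reference implementations; the capped flag marks a binding bound). Collinear
leads: later duplicates are dropped and reported as NaN. Standard errors by
nonparametric bootstrap over individuals (200 resamples by default; 0
disables). Scale equivariance and allele-flip antisymmetry hold exactly up
to optimizer tolerance (~1e-8).

## Population differentiation

Per-group AF = mean dosage/2; classes U (MAF = 0), R (0 < MAF < 0.05),
C (MAF ≥ 0.05); fd-QTL flags composed from classes (globally common;
unobserved in the reference group but present elsewhere; unobserved in the
reference and second group). F_ST is Hudson's estimator; per-variant values
are the ratio as printed (negative estimates reported, not clipped), and
aggregate summaries use the ratio-of-averages, the less biased convention for
means over many variants. The focal-group statistic pools the complement
(all other groups as one sample) — whether the original analysis pooled or
averaged pairwise is not determinable from the text; the pairwise matrix is
also available. NB differential expression: per-gene dispersion by 1-D
maximum likelihood around a Poisson start (method-of-moments initialisation),
fixed across the nested fits; LRT of the focal-vs-rest indicator with log
size-factor offsets, BH at 5%. Dispersion is per gene without shrinkage —
a documented divergence from shrinkage-based DE practice, adequate at n≈500.
DE deciles are p-rank deciles (10th = most significant); the F_ST/DE link is
tested by a two-tailed Mann–Whitney U on DE vs non-DE genes' lead F_ST.

## Interaction (he-QTL) tests

Eligibility: MAF ≥ 0.05 in ≥ 2 continental groups. Full model
y ~ g + group + g:group (+ other leads in the multi-causal variant, + any
covariates); F = ((RSS_r − RSS_f)/df1)/(RSS_f/df2) with df from matrix ranks,
upper-tail p. Interaction terms are restricted to groups where the focal
variant is polymorphic and that keep ≥ 5 samples (unestimable otherwise —
the source is silent on this). The genotype-by-PC variant replaces g:group
with g:PC_j terms and is exactly equivalent to the categorical test when the
PCs are an affine recoding of a two-group indicator. Bonferroni summaries
count significant tests at α/n_tests within each model family, stratified by
credible-set count. The "top nominal pass" eQTL is operationalised as the
variant with the smallest nominal p per gene.

## Enrichment

Backgrounds matched on MAF decile × |TSS distance| decile (10×10, deciles
from the candidate pool), one variant per lead per draw, without replacement
within a draw; empty or exhausted bins widen to the nearest non-empty
neighbours (logged). Enrichment = lead proportion over mean background
proportion, log2; 95% CI from the percentile distribution of per-draw log2
ratios, zero-proportion draws taking a 0.5/n_leads pseudo-count (depletion is
therefore quantified rather than dropped). The ≥5-leads-per-category rule is
applied when assembling category tables, not inside the statistic, so
depletion of lead-free categories remains measurable. Bin counts and the CI
construction are package choices; only the matching covariates are given by
the reported design.

## Colocalization

Wakefield's approximate Bayes factor (prior sd 0.15) for summary-level
signals, or per-effect log Bayes factors from the fine-mapper, entering the
standard five-hypothesis sums with priors p1 = p2 = 1e-4, p12 = 5e-6 (the
conventional defaults; the source does not print its priors), log-sum-exp
stabilised, H3 computed as the pair-sum complement of the shared-variant sum.
Classification: moderate PP4 ≥ 0.5, strong PP4 ≥ 0.8. With two
sum-of-single-effects fits, every pair of active effects is scored
separately, which is what lets multiple causal variants per signal
colocalise independently.

## Benchmark study conditions

The validation suite and `scripts/acceptance.py` run at: n = 500 samples
(5 groups × 2 populations × 50) for recovery/calibration studies, 200 genes
for single-causal recovery, 100 for two-causal, 200 cis variants per window,
2,000–20,000 replicates for type-I-error studies, 20 replicates of a
50-true/150-null mixture for FDR, and the full 26-population design (n = 728
scaled to 520) for variance partitioning. These sizes make every study a
few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins. The interaction-calibration check uses 20,000 replicates
with the correspondingly tighter binomial 95% CI — more replicates make the
check stricter, and the F-test is exact under the simulator's Gaussian
noise, so the level is 5% by construction.

## What passing benchmarks do and do not show

The generator has independent variants (or block-template LD), Gaussian log
noise, Poisson counts, no admixed individuals, no cell-type heterogeneity,
no read-level artefacts, and cis windows that never overlap. Passing
benchmarks therefore demonstrate internal correctness — estimator formulas,
calibration under the stated models, recovery when the generative model
matches the estimation model — not robustness to real-data violations
(fine-scale LD, rare-variant stratification, expression outliers, shared
hidden factors). The interaction-mechanism result shows the additive-signal
explanation is sufficient to produce apparent genotype-by-ancestry
interactions at realistic magnitudes; it does not rule out true
heterogeneity in real cohorts.

## Numerical details

Degenerate inputs: constant features are rejected by the inverse-normal
transform; monomorphic candidates are pre-filtered and error if passed;
zero-variance groups floor at 1e-12; Beta-fit failures fall back to direct
empirical p with a flag; full-rank checks guard every regression design.
Ties: average ranks in the INT; lead selection breaks PIP ties by distance
then id; BH uses the standard step-up. All randomness flows through
numpy Generator objects seeded from a single integer; same seed, same bytes.
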