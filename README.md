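# divqtl

Multi-ancestry *cis*-QTL analysis on structured-population data: variance
partitioning of expression across nested population labels, cis-eQTL/sQTL
scanning with permutation-based gene-level FDR, sum-of-single-effects
fine-mapping with credible-set merging, conditional allelic-fold-change
effect sizes, frequency-differentiated QTL classification, matched-background
functional enrichment, colocalization posteriors, and genotype-by-ancestry
interaction testing under single- and multi-causal models.

The package is aimed at statistical geneticists who want to study — on
synthetic cohorts with known ground truth — how population structure shapes
eQTL discovery: which causal variants are found, how well their effects are
estimated, and, centrally, why "population-specific" eQTL effects can be an
artefact of unmodelled allelic heterogeneity rather than true
genotype-by-ancestry interaction.

## Models

**Genotypes.** A nested Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.95); continental-group frequency
p_g ~ Beta(p(1−F_g)/F_g, (1−p)(1−F_g)/F_g) with F_g = 0.10 by default;
population frequencies nested the same way with f_pop = 0.01. Haplotypes are
Bernoulli(p_pop), optionally copied from per-population template pools in
blocks of adjacent variants to induce local LD. The expected Hudson F_ST
between groups equals F_g.

**Expression.** The allelic fold change (aFC) generative model: a haplotype
carrying alleles a_k at causal variants with effects β_k = log2(aFC_k)
contributes ∏_k 2^(β_k a_k); an individual's expected count is

    C · (hap₁ + hap₂)/2 · 2^(batch + sex + ε),   ε ~ N(0, σ²_g),

with Poisson (optionally negative-binomial) counts and log-uniform library
sizes. Estimation inverts the same model: E[y | g₁…g_K] =
C ∏_k ((2−g_k) + g_k·2^(β_k))/2, fitted jointly over all lead QTLs of a gene
by box-constrained least squares on the log2 scale (|log2 aFC| ≤ log2 100).

**Fine-mapping.** The sum-of-single-effects regression y = Σ_l X b_l + e, each
b_l selecting one variant with a Gaussian effect prior, fitted by iterative
Bayesian stepwise selection with per-effect prior-variance estimation; 95%
credible sets are posterior-sorted prefixes filtered at purity 0.5, merged
across introns/effects by shared-variant connected components.

**Heterogeneity.** For a focal variant g: F-test of y ~ g + group + g:group
(+ leads) against the model without g:group, one-tailed. The multi-causal
variant conditions on all lead QTLs of the gene and tests one at a time.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (5 continental groups × 2 populations × 25 samples, 100 genes, 100 cis
variants each, 0–3 causal variants per gene) and write tables under
`results/study/`:

```
cd analysis
python 01_simulate.py && python 02_prepare.py && python 03_variance_partition.py
python 04_scan_qtls.py && python 05_finemap.py && python 06_effect_sizes.py
python 07_population_differentiation.py && python 08_interactions.py
python 09_enrichment.py && python 10_colocalization.py
```

Output (abridged):

```
continental group explains 7.76% (s.d. 7.10) of expression variance on average;
population label 11.79% (s.d. 7.89)
one-tailed permutation p: group 0.001996, population 0.001996 (minimum attainable)
tested 100 genes; 77 eGenes at 5% FDR
77 fine-mapped eGenes, 117 gene-level credible sets (median size 1)
39% of fine-mapped genes have more than one credible set
84% of true causal variants (all effect sizes) fall inside a credible set
117 leads are true causal variants: median |error| vs truth = 0.074
117 unique lead variants: 59% globally common; 8 unobserved in EUR but present elsewhere
AFR: DE vs non-DE eGene lead F_ST Mann-Whitney two-tailed p = 1.23e-05
single model: 0 of 77 tests Bonferroni-significant   (no true interactions simulated)
regulatory_element (positive control): log2 fold = 7.27 [5.27, 7.27]
shared-causal pairs called strong (PP4 >= 0.8): 91%
```

Reading: structured genotypes push the plain between-population eta-squared
above its (k−1)/(n−1) null floor; most causal variants land in small credible
sets; conditional aFC recovers the simulated effect sizes to <0.1 log2 units;
lead QTLs are differentiated in frequency exactly where the expression of
their genes differs between groups; and with no simulated interactions the
interaction tests stay silent.

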