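"""Shared configuration for the numbered analysis scripts.

The study is a synthetic multi-ancestry cohort: 5 continental groups x 2
populations x 25 samples (n = 250), 100 genes with 100 cis variants each,
0-3 causal variants per gene with |log2 aFC| in [0.25, 2], template-block LD,
batch and sex effects. Every script reads its inputs from RESULTS/study and
writes its outputs there; run them in order (01 ... 10).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from divqtl.io import (batch_sex_covariates, inverse_normal_transform,
                       normalize_expression, read_phenotype_bed,
                       read_sample_table, read_vcf, residualize)
from divqtl.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "study"
SIM_DIR = RESULTS / "sim"

SEED = 2024
N_PERM = 500
FDR = 0.05

SIM_CONFIG = SimConfig(
    n_genes=100,
    populations_per_group=2,
    samples_per_population=25,
    variants_per_cis_window=100,
    causal_per_gene_probs=(0.25, 0.40, 0.25, 0.10),
    use_ld_templates=True,
    seed=SEED,
)


def load_inputs():
    """Genotypes, counts, samples as written by 01_simulate.py."""
    genotypes = read_vcf(SIM_DIR / "genotypes.vcf")
    counts = read_phenotype_bed(SIM_DIR / "expression.bed", value_kind="counts")
    samples = read_sample_table(SIM_DIR / "samples.tsv")
    return genotypes, counts, samples


def load_prepared():
    """Residualised phenotype matrix and covariate count from 02_prepare.py."""
    resid = pd.read_csv(RESULTS / "residuals.tsv", sep="\t", index_col=0)
    n_cov = len(pd.read_csv(RESULTS / "covariates.tsv", sep="\t").columns)
    return resid, n_cov


def prepare(counts, samples):
    norm = normalize_expression(counts)
    Y = inverse_normal_transform(norm.values)
    cov = batch_sex_covariates(samples)
    return residualize(Y, cov), norm, cov


def load_truth():
    causal = pd.read_csv(SIM_DIR / "truth_causal.tsv", sep="\t")
    genes = pd.read_csv(SIM_DIR / "truth_genes.tsv", sep="\t")
    return causal, genes
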