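"""Structured-population genotype and phenotype simulator with known truth.

Genotypes follow a nested Balding–Nichols model: an ancestral allele frequency
``p ~ Uniform(0.05, 0.95)`` is perturbed into continental-group frequencies
``Beta(p(1-F_g)/F_g, (1-p)(1-F_g)/F_g)`` and those again into population
frequencies with ``f_pop``, so the expected Hudson F_ST between groups is
controlled in closed form. Haplotypes are Bernoulli draws from the population
frequency; optional template-block copying induces local LD so the fine-mapper
sees correlated candidates.

Expression is generated from the allelic-fold-change model: each haplotype
contributes ``prod_k 2^(beta_k * a_k)`` over the causal variants it carries
(``beta_k = log2 aFC``), the two haplotype contributions are averaged,
multiplied by batch/sex/interaction factors and log-normal noise, and counts
are Poisson (optionally negative-binomial) around the library-scaled mean.

Splicing phenotypes are per-cluster Dirichlet intron-excision ratios where an
sQTL multiplies one intron's concentration by ``2^(beta*g)``.

Every random draw flows from ``SimConfig.seed``; the same config yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CovariateMatrix, GenotypeMatrix, PhenotypeMatrix, SampleTable,
                 write_phenotype_bed, write_sample_table, write_vcf)

GROUP_CODES = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic multi-ancestry cohort.

    Defaults emulate the real design: 5 continental groups, 26 populations
    (7/4/5/5/5 per group), 28 samples per population, group-level
    differentiation ``f_group = 0.10`` (human continental scale) and
    within-group ``f_pop = 0.01``.
    """

    n_genes: int = 50
    n_groups: int = 5
    populations_per_group: tuple[int, ...] | int = (7, 4, 5, 5, 5)
    samples_per_population: int = 28
    f_group: float = 0.10
    f_pop: float = 0.01
    variants_per_cis_window: int = 200
    causal_per_gene_probs: tuple[float, ...] = (0.25, 0.40, 0.25, 0.10)  # P(0..3)
    log2_afc_range: tuple[float, float] = (0.25, 2.0)
    noise_sd_log2: float = 0.5
    batch_effect_sd: float = 0.1
    n_batches: int = 4
    interaction_fraction: float = 0.0
    interaction_delta: float = 0.5
    group_noise_multipliers: tuple[float, ...] | None = None  # default all 1
    use_ld_templates: bool = False
    ld_block_len: int = 20
    ld_n_templates: int = 16
    overdispersion: float = 0.0  # NB dispersion; 0 -> Poisson
    base_mean: float = 300.0  # baseline count scale per gene (log-normal spread)
    min_causal_maf: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.populations_per_group, int):
            self.populations_per_group = (self.populations_per_group,) * self.n_groups
        if len(self.populations_per_group) != self.n_groups:
            raise ValueError("populations_per_group length must equal n_groups")
        if not 0 <= self.f_group <= 1 or not 0 <= self.f_pop <= 1:
            raise ValueError("differentiation parameters must lie in [0, 1]")
        if self.samples_per_population < 2:
            raise ValueError("need >= 2 samples per population")
        if abs(sum(self.causal_per_gene_probs) - 1.0) > 1e-9:
            raise ValueError("causal_per_gene_probs must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_samples(self) -> int:
        return self.samples_per_population * sum(self.populations_per_group)


@dataclass
class TruthTable:
    """Machine-readable ground truth for recovery tests."""

    causal: pd.DataFrame  # gene_id, variant_id, beta (log2 aFC), interaction deltas
    gene_info: pd.DataFrame  # gene_id, tss, n_causal, var_frac_group, var_frac_population
    variant_af: pd.DataFrame  # variant_id, ancestral_af, per-group AF columns

    def causal_of(self, gene_id: str) -> pd.DataFrame:
        return self.causal[self.causal["gene_id"] == gene_id]


def make_sample_table(config: SimConfig, rng: np.random.Generator) -> SampleTable:
    """Population labels nested in groups, random sex, batch stratified by design."""
    rows = []
    i = 0
    for g, npop in enumerate(config.populations_per_group):
        group = GROUP_CODES[g % len(GROUP_CODES)] if config.n_groups <= 5 else f"G{g+1}"
        for p in range(npop):
            pop = f"{group}{p+1}"
            for _ in range(config.samples_per_population):
                rows.append((f"S{i:04d}", pop, group))
                i += 1
    t = pd.DataFrame(rows, columns=["sample_id", "population", "continental_group"])
    t["sex"] = rng.choice(["F", "M"], size=len(t))
    # stratify batches across populations: cycle within each population
    t["batch"] = t.groupby("population").cumcount() % config.n_batches
    return SampleTable(t)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _nested_af(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols draw of daughter AFs around p; exact copy when f=0."""
    if f == 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def simulate_genotypes(
    config: SimConfig,
    samples: SampleTable,
    n_variants: int,
    chrom: str = "chr1",
    pos_start: int = 1,
    pos_step: int = 5_000,
    rng: np.random.Generator | None = None,
    id_prefix: str = "v",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw phased genotypes under the nested Balding–Nichols model.

    Returns the genotype matrix (with haplotypes) and a per-variant AF table
    holding the ancestral and drawn per-group frequencies.
    """
    rng = rng or np.random.default_rng(config.seed)
    pops = samples.populations
    groups = samples.groups
    pop_codes, pop_idx = np.unique(pops, return_inverse=True)
    pop_to_group = {p: groups[pops == p][0] for p in pop_codes}
    group_codes = list(dict.fromkeys(samples.table["continental_group"]))

    p_anc = rng.uniform(0.05, 0.95, size=n_variants)
    group_af = np.stack(
        [_nested_af(p_anc, config.f_group, rng) for _ in group_codes], axis=1)
    g_of_pop = np.array([group_codes.index(pop_to_group[p]) for p in pop_codes])
    pop_af = np.stack(
        [_nested_af(group_af[:, g_of_pop[k]], config.f_pop, rng)
         for k in range(len(pop_codes))], axis=1)

    n = len(pops)
    af_per_sample = pop_af[:, pop_idx]  # (variants, samples)
    if config.use_ld_templates:
        haps = _template_haplotypes(af_per_sample, pop_idx, len(pop_codes),
                                    config, rng)
    else:
        haps = (rng.random((n_variants, n, 2)) < af_per_sample[:, :, None]
                ).astype(np.int8)
    dosages = haps.sum(axis=2).astype(np.int8)

    pos = pos_start + pos_step * np.arange(n_variants)
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
        "variant_id": [f"{id_prefix}{i:06d}" for i in range(n_variants)],
    })
    af_table = pd.DataFrame({"variant_id": variants["variant_id"],
                             "ancestral_af": p_anc})
    for j, gcode in enumerate(group_codes):
        af_table[f"af_{gcode}"] = group_af[:, j]
    gm = GenotypeMatrix(variants, dosages, samples.sample_ids, haplotypes=haps)
    return gm, af_table


def _template_haplotypes(af_per_sample, pop_idx, n_pops, config, rng):
    """Copy haplotypes from per-population template pools in blocks of adjacent
    variants, inducing local LD while preserving expected AFs."""
    n_variants, n = af_per_sample.shape
    haps = np.empty((n_variants, n, 2), dtype=np.int8)
    T = config.ld_n_templates
    for start in range(0, n_variants, config.ld_block_len):
        stop = min(start + config.ld_block_len, n_variants)
        for k in range(n_pops):
            cols = np.where(pop_idx == k)[0]
            if cols.size == 0:
                continue
            af_block = af_per_sample[start:stop, cols[0]]  # same AF within pop
            templates = (rng.random((stop - start, T)) < af_block[:, None]
                         ).astype(np.int8)
            choice = rng.integers(0, T, size=(cols.size, 2))
            haps[start:stop][:, cols, 0] = templates[:, choice[:, 0]]
            haps[start:stop][:, cols, 1] = templates[:, choice[:, 1]]
    return haps


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _eta_squared(y: np.ndarray, labels: np.ndarray) -> float:
    grand = y.mean()
    ss_tot = ((y - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_b = 0.0
    for lab in np.unique(labels):
        yl = y[labels == lab]
        ss_b += yl.size * (yl.mean() - grand) ** 2
    return float(ss_b / ss_tot)


def simulate_expression(
    genotypes_per_gene: list[GenotypeMatrix],
    samples: SampleTable,
    config: SimConfig,
    rng: np.random.Generator,
    tss_list: list[int] | None = None,
    gene_chroms: list[str] | None = None,
) -> tuple[PhenotypeMatrix, TruthTable, pd.DataFrame]:
    """Generate gene expression counts from the aFC model, one cis window per gene.

    Returns the count matrix, the truth table and the per-variant AF table is
    left to the caller (it comes from :func:`simulate_genotypes`).
    """
    n = samples.table.shape[0]
    groups = samples.groups
    pops = samples.populations
    group_codes = list(dict.fromkeys(groups))
    gmult = (np.ones(len(group_codes)) if config.group_noise_multipliers is None
             else np.asarray(config.group_noise_multipliers, dtype=float))
    group_of_sample = np.array([group_codes.index(g) for g in groups])

    batch_eff = rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
    sex_eff = rng.normal(0.0, config.batch_effect_sd)
    batch_term = batch_eff[samples.table["batch"].to_numpy()]
    sex_term = sex_eff * (samples.table["sex"] == "M").to_numpy(float)

    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n))

    causal_rows, gene_rows, count_rows, feat_rows = [], [], [], []
    lo, hi = config.log2_afc_range
    for gi, gm in enumerate(genotypes_per_gene):
        gene_id = f"gene{gi:04d}"
        tss = (tss_list[gi] if tss_list is not None
               else int(gm.variants["pos"].iloc[len(gm.variants) // 2]))
        chrom = gene_chroms[gi] if gene_chroms is not None else gm.variants["chrom"].iloc[0]
        n_causal = rng.choice(len(config.causal_per_gene_probs),
                              p=config.causal_per_gene_probs)
        maf = gm.maf()
        eligible = np.where(maf >= config.min_causal_maf)[0]
        if eligible.size < n_causal:  # re-draw impossible; cap (logged via truth)
            n_causal = eligible.size
        causal_idx = rng.choice(eligible, size=n_causal, replace=False) \
            if n_causal else np.array([], dtype=int)
        betas = rng.uniform(lo, hi, size=n_causal) * rng.choice([-1, 1], size=n_causal)

        has_inter = rng.random() < config.interaction_fraction and n_causal > 0
        deltas = np.zeros((n_causal, len(group_codes)))
        if has_inter:
            k = rng.integers(n_causal)
            g = rng.integers(len(group_codes))
            deltas[k, g] = config.interaction_delta * rng.choice([-1, 1])

        # per-haplotype multiplicative contributions
        log2_signal = np.zeros(n)
        if n_causal:
            a = gm.haplotypes[causal_idx]  # (K, n, 2)
            beta_eff = betas[:, None] + deltas[:, group_of_sample]  # (K, n)
            hap = 2.0 ** (beta_eff[:, :, None] * a)  # (K, n, 2)
            contrib = hap.prod(axis=0)  # (n, 2)
            log2_signal = np.log2(contrib.mean(axis=1))
        eps = rng.normal(0.0, config.noise_sd_log2 * gmult[group_of_sample])
        C = config.base_mean * np.exp(rng.normal(0.0, 0.5))
        mean = C * 2.0 ** (log2_signal + batch_term + sex_term + eps)
        lam = lib * mean
        if config.overdispersion > 0:
            r = 1.0 / config.overdispersion
            counts = rng.negative_binomial(r, r / (r + lam))
        else:
            counts = rng.poisson(lam)
        count_rows.append(counts)
        feat_rows.append((gene_id, gene_id, chrom, tss, "+"))

        vids = gm.variants["variant_id"].to_numpy()
        for k in range(n_causal):
            causal_rows.append((gene_id, vids[causal_idx[k]], betas[k],
                                ";".join(f"{group_codes[j]}:{deltas[k, j]:g}"
                                         for j in range(len(group_codes))
                                         if deltas[k, j] != 0) or ""))
        full_log2 = log2_signal + batch_term + sex_term + eps
        gene_rows.append((gene_id, tss, n_causal,
                          100 * _eta_squared(full_log2, groups),
                          100 * _eta_squared(full_log2, pops)))

    features = pd.DataFrame(feat_rows, columns=["feature_id", "gene_id", "chrom",
                                                "tss", "strand"])
    counts = PhenotypeMatrix(features, np.array(count_rows, dtype=float),
                             samples.sample_ids, value_kind="counts")
    truth = TruthTable(
        causal=pd.DataFrame(causal_rows, columns=["gene_id", "variant_id", "beta",
                                                  "interaction_deltas"]),
        gene_info=pd.DataFrame(gene_rows, columns=["gene_id", "tss", "n_causal",
                                                   "var_frac_group",
                                                   "var_frac_population"]),
        variant_af=pd.DataFrame(),
    )
    lib_df = pd.DataFrame({"sample_id": samples.sample_ids, "library_size": lib})
    return counts, truth, lib_df


def simulate_splicing(
    genotypes_per_gene: list[GenotypeMatrix],
    samples: SampleTable,
    config: SimConfig,
    rng: np.random.Generator,
    introns_per_cluster: tuple[int, int] = (2, 4),
    concentration: float = 60.0,
    tss_list: list[int] | None = None,
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Dirichlet intron-excision ratios; an sQTL multiplies one intron's
    concentration by ``2^(beta*g)``. Ratios sum to 1 within each cluster."""
    n = samples.table.shape[0]
    lo, hi = config.log2_afc_range
    feat_rows, value_rows, truth_rows = [], [], []
    for gi, gm in enumerate(genotypes_per_gene):
        gene_id = f"gene{gi:04d}"
        cluster_id = f"{gene_id}:clu{gi}"
        tss = (tss_list[gi] if tss_list is not None
               else int(gm.variants["pos"].iloc[len(gm.variants) // 2]))
        m = rng.integers(introns_per_cluster[0], introns_per_cluster[1] + 1)
        base_w = rng.dirichlet(np.full(m, 5.0))
        maf = gm.maf()
        eligible = np.where(maf >= config.min_causal_maf)[0]
        has_qtl = rng.random() < sum(config.causal_per_gene_probs[1:]) and eligible.size
        if has_qtl:
            ci = rng.choice(eligible)
            beta = rng.uniform(lo, hi) * rng.choice([-1, 1])
            target = rng.integers(m)
            g = gm.dosages[ci].astype(float)
            truth_rows.append((gene_id, cluster_id,
                               gm.variants["variant_id"].iloc[ci], beta, target))
        else:
            beta, target, g = 0.0, -1, np.zeros(n)
        w = np.tile(base_w, (n, 1))
        if target >= 0:
            w[:, target] *= 2.0 ** (beta * g)
        w /= w.sum(axis=1, keepdims=True)
        ratios = rng.dirichlet(np.ones(m), size=n)  # placeholder shape
        for i in range(n):
            ratios[i] = rng.dirichlet(concentration * w[i])
        for j in range(m):
            feat_rows.append((f"{cluster_id}:intron{j}", gene_id,
                              gm.variants["chrom"].iloc[0], tss + j, "+", cluster_id))
            value_rows.append(ratios[:, j])
    features = pd.DataFrame(feat_rows, columns=["feature_id", "gene_id", "chrom",
                                                "tss", "strand", "cluster_id"])
    pheno = PhenotypeMatrix(features, np.array(value_rows), samples.sample_ids,
                            value_kind="ratios")
    struth = pd.DataFrame(truth_rows, columns=["gene_id", "cluster_id",
                                               "variant_id", "beta",
                                               "target_intron"])
    return pheno, struth


# ---------------------------------------------------------------------------
# whole-dataset convenience + fixtures on disk
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    samples: SampleTable
    genotypes: GenotypeMatrix  # all windows concatenated
    genotypes_per_gene: list[GenotypeMatrix]
    counts: PhenotypeMatrix
    truth: TruthTable
    library_sizes: pd.DataFrame
    splicing: PhenotypeMatrix | None = None
    splicing_truth: pd.DataFrame | None = None


def simulate_study(config: SimConfig, with_splicing: bool = False) -> SimulatedStudy:
    """End-to-end synthetic study: one non-overlapping cis window per gene."""
    rng = np.random.default_rng(config.seed)
    samples = make_sample_table(config, rng)
    window_span = 2_500_000  # > 2 Mb so cis windows never overlap
    per_gene, af_tables, tss_list = [], [], []
    for gi in range(config.n_genes):
        start = 1 + gi * window_span
        step = max(1, 2_000_000 // max(config.variants_per_cis_window, 1))
        gm, af = simulate_genotypes(
            config, samples, config.variants_per_cis_window, chrom="chr1",
            pos_start=start, pos_step=step, rng=rng,
            id_prefix=f"gene{gi:04d}_v")
        per_gene.append(gm)
        af_tables.append(af)
        tss_list.append(start + (config.variants_per_cis_window // 2) * step)
    counts, truth, lib = simulate_expression(per_gene, samples, config, rng,
                                             tss_list=tss_list)
    truth.variant_af = pd.concat(af_tables, ignore_index=True)
    all_variants = pd.concat([g.variants for g in per_gene], ignore_index=True)
    all_dos = np.vstack([g.dosages for g in per_gene])
    all_haps = np.concatenate([g.haplotypes for g in per_gene], axis=0)
    genotypes = GenotypeMatrix(all_variants, all_dos, samples.sample_ids,
                               haplotypes=all_haps)
    study = SimulatedStudy(samples, genotypes, per_gene, counts, truth, lib)
    if with_splicing:
        study.splicing, study.splicing_truth = simulate_splicing(
            per_gene, samples, config, rng, tss_list=tss_list)
    return study


def simulate_varpart_phenotype(
    samples: SampleTable,
    n_features: int,
    between_pop_frac: float = 0.08,
    between_group_frac: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian phenotypes with a prescribed between-population variance share.

    ``between_pop_frac`` is defined as the expected plain eta-squared of the
    one-way population model at this design — the estimator the variance
    partition reports (which carries the usual (k-1)/(n-1) null floor). The
    population-effect variance v solving

        E[eta^2] ~= (k-1) (sigma^2 + m v) / ((n-1)(sigma^2 + v))

    (balanced design, m samples per population, sigma^2 = 1) is used, so
    recovery tests compare like with like. An optional group-level component
    is added uncalibrated on top.
    """
    rng = np.random.default_rng(seed)
    pops = samples.populations
    groups = samples.groups
    pop_codes, pop_idx = np.unique(pops, return_inverse=True)
    grp_codes, grp_idx = np.unique(groups, return_inverse=True)
    n, k = len(pops), len(pop_codes)
    m = n / k
    f = between_pop_frac
    floor = (k - 1) / (n - 1)
    if f < floor:
        v = 0.0
    else:
        # solve (k-1)(1 + (m-1) v') / ((n-1)(1 + v')) = f for v' = v/sigma^2
        num = f * (n - 1) / (k - 1) - 1.0
        den = (m - 1) - f * (n - 1) / (k - 1)
        v = max(num / den, 0.0)
    Y = np.empty((n_features, n))
    for i in range(n_features):
        pe = rng.normal(0, np.sqrt(v), size=k)
        ge = rng.normal(0, np.sqrt(between_group_frac), size=len(grp_codes))
        Y[i] = pe[pop_idx] + ge[grp_idx] + rng.normal(0, 1.0, n)
    return Y


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Emit VCF + phenotype BED + sample TSV + truth TSVs; all plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "expression_bed": outdir / "expression.bed",
        "samples": outdir / "samples.tsv",
        "truth_causal": outdir / "truth_causal.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
    }
    write_vcf(study.genotypes, paths["vcf"])
    write_phenotype_bed(study.counts, paths["expression_bed"])
    write_sample_table(study.samples, paths["samples"])
    study.truth.causal.to_csv(paths["truth_causal"], sep="\t", index=False)
    study.truth.gene_info.to_csv(paths["truth_genes"], sep="\t", index=False)
    study.library_sizes.to_csv(paths["library_sizes"], sep="\t", index=False)
    if study.splicing is not None:
        paths["splicing_bed"] = outdir / "splicing.bed"
        write_phenotype_bed(study.splicing, paths["splicing_bed"])
        paths["truth_splicing"] = outdir / "truth_splicing.tsv"
        study.splicing_truth.to_csv(paths["truth_splicing"], sep="\t", index=False)
    return paths
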