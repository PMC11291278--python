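"""Synthetic-truth benchmark computations for the pipeline's core claims.

Each function runs one property study end to end — simulate under known
truth, run the relevant stage(s), measure recovery/calibration — and returns
plain floats. They are shared by the validation test-suite and the
``scripts/acceptance.py`` reporting script, and are all deterministic given
``seed``.

Problem sizes are desk-scale study conditions: n = 500 samples (5 groups x 2
populations x 50, matching the real design's 27-30 per population up to the
reduced population count), 100-200 cis variants per window, effect sizes
|log2 aFC| in [0.25, 2].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import afc as afc_mod
from . import coloc as coloc_mod
from . import enrich as enrich_mod
from . import finemap as fm
from . import hetero as het
from . import popdiff as pop
from . import scan as scan_mod
from . import simulate as sim
from . import varpart as vp
from .io import GenotypeMatrix


def _toy_gm(dosages: np.ndarray, pos_step: int = 100) -> GenotypeMatrix:
    p, n = dosages.shape
    v = pd.DataFrame({"chrom": "chr1",
                      "pos": pos_step * (1 + np.arange(p)),
                      "ref": "A", "alt": "G",
                      "variant_id": [f"v{i:04d}" for i in range(p)]})
    return GenotypeMatrix(v, dosages.astype(np.int8),
                          np.array([f"s{i}" for i in range(n)]))


def _cohort(seed: int, spp: int = 50, **kw) -> tuple[sim.SimConfig, object]:
    cfg = sim.SimConfig(n_genes=1, populations_per_group=2,
                        samples_per_population=spp, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    return cfg, sim.make_sample_table(cfg, rng)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def fst_oracle_equivalence(seed: int, n_tuples: int = 10_000) -> float:
    """Max |hudson_fst - independent formula transcription| over random tuples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tuples):
        p1, p2 = rng.uniform(0.01, 0.99, 2)
        n1, n2 = rng.integers(2, 500, 2)
        got = pop.hudson_fst(p1, n1, p2, n2)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
            - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        worst = max(worst, abs(got - num / den))
    return worst


def fst_balding_nichols_mean(seed: int, n_variants: int = 2000,
                             f_group: float = 0.10) -> float:
    """Mean pairwise Hudson F_ST (ratio of averages) under the nested model."""
    cfg, samples = _cohort(seed, spp=20, f_group=f_group)
    rng = np.random.default_rng(seed + 1)
    gm, _ = sim.simulate_genotypes(cfg, samples, n_variants, rng=rng)
    groups = samples.groups
    codes = list(dict.fromkeys(groups))
    vals = []
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            da = gm.dosages[:, groups == a]
            db = gm.dosages[:, groups == b]
            vals.append(pop.hudson_fst_aggregate(
                da.mean(1) / 2, 2 * da.shape[1],
                db.mean(1) / 2, 2 * db.shape[1]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# aFC recovery
# ---------------------------------------------------------------------------

def afc_single_recovery(seed: int, n_genes: int = 200, n: int = 500
                        ) -> tuple[float, float]:
    """(median |error|, regression slope of estimate on truth) for single-causal
    genes at |log2 aFC| in [0.25, 2], MAF >= 0.1, noise 0.5."""
    rng = np.random.default_rng(seed)
    truths, ests = [], []
    while len(truths) < n_genes:
        beta = rng.uniform(0.25, 2.0) * rng.choice([-1, 1])
        maf = rng.uniform(0.1, 0.5)
        hap = rng.binomial(1, maf, (2, n))
        g = hap.sum(0).astype(float)
        if g.std() == 0:
            continue
        mean = ((2.0 ** (beta * hap[0]) + 2.0 ** (beta * hap[1])) / 2
                * 100 * 2.0 ** rng.normal(0, 0.5, n))
        y = rng.poisson(mean) + 1.0
        ests.append(afc_mod.afc_single(y, g).log2_afc)
        truths.append(beta)
    truths = np.array(truths)
    ests = np.array(ests)
    med_err = float(np.median(np.abs(ests - truths)))
    slope = float(np.polyfit(truths, ests, 1)[0])
    return med_err, slope


def afc_conditional_recovery(seed: int, n_genes: int = 100, n: int = 500
                             ) -> float:
    """Median |error| over both effects of two-causal genes (joint model)."""
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_genes):
        b1 = rng.uniform(0.25, 2.0) * rng.choice([-1, 1])
        b2 = rng.uniform(0.25, 2.0) * rng.choice([-1, 1])
        h1 = rng.binomial(1, rng.uniform(0.15, 0.5), (2, n))
        h2 = rng.binomial(1, rng.uniform(0.15, 0.5), (2, n))
        mean = ((2.0 ** (b1 * h1[0] + b2 * h2[0])
                 + 2.0 ** (b1 * h1[1] + b2 * h2[1])) / 2
                * 100 * 2.0 ** rng.normal(0, 0.5, n))
        y = rng.poisson(mean) + 1.0
        G = np.column_stack([h1.sum(0), h2.sum(0)]).astype(float)
        if (G.std(axis=0) == 0).any():
            continue
        ests = afc_mod.afc_conditional(y, G, n_boot=0)
        errs.extend([abs(ests[0].log2_afc - b1), abs(ests[1].log2_afc - b2)])
    return float(np.median(errs))


# ---------------------------------------------------------------------------
# fine-mapping
# ---------------------------------------------------------------------------

def finemap_single_causal_coverage(seed: int, n_genes: int = 200,
                                   n: int = 500, p: int = 200) -> float:
    """Fraction of 95% credible sets containing the causal variant
    (single-causal genes, 5% variance explained scale effects)."""
    rng = np.random.default_rng(seed)
    covered = total = 0
    for gi in range(n_genes):
        X = rng.binomial(2, rng.uniform(0.1, 0.5, p)[:, None], size=(p, n)).T \
            .astype(float)
        ci = int(rng.integers(p))
        g = X[:, ci]
        if g.std() == 0:
            continue
        beta = np.sqrt(0.05 / (g.var() * 0.95))
        y = beta * g + rng.normal(0, 1, n)
        fit = fm.ibss_fit(y, X, L=10,
                          variant_ids=np.array([f"v{j}" for j in range(p)]))
        cs = fm.extract_credible_sets(fit, X)
        for c in cs:
            total += 1
            covered += f"v{ci}" in c.variant_ids
    return covered / max(total, 1)


def finemap_two_causal_recovery(seed: int, n_genes: int = 100,
                                n: int = 500, p: int = 200) -> float:
    """Fraction of two-causal genes (r^2 < 0.05 between causals, each 5%
    variance) yielding exactly two credible sets, each holding its causal."""
    rng = np.random.default_rng(seed)
    ok = tried = 0
    while tried < n_genes:
        X = rng.binomial(2, rng.uniform(0.1, 0.5, p)[:, None], size=(p, n)).T \
            .astype(float)
        i, j = rng.choice(p, 2, replace=False)
        if np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2 >= 0.05:
            continue
        tried += 1
        b_i = np.sqrt(0.05 / (X[:, i].var() * 0.90))
        b_j = np.sqrt(0.05 / (X[:, j].var() * 0.90))
        y = b_i * X[:, i] + b_j * X[:, j] + rng.normal(0, 1, n)
        fit = fm.ibss_fit(y, X, L=10,
                          variant_ids=np.array([f"v{k}" for k in range(p)]))
        cs = fm.extract_credible_sets(fit, X)
        got_i = any(f"v{i}" in c.variant_ids for c in cs)
        got_j = any(f"v{j}" in c.variant_ids for c in cs)
        ok += (len(cs) == 2 and got_i and got_j)
    return ok / n_genes


# ---------------------------------------------------------------------------
# interaction tests
# ---------------------------------------------------------------------------

def interaction_calibration(seed: int, n_reps: int = 2000) -> float:
    """Type-I rate of the single-model interaction F-test at alpha = 0.05
    with one causal variant and no true interaction (n = 500)."""
    cfg, samples = _cohort(seed)
    rng = np.random.default_rng(seed + 1)
    groups = samples.groups
    n = len(groups)
    rej = done = 0
    while done < n_reps:
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        y = 0.5 * g + rng.normal(0, 1, n)
        try:
            r = het.interaction_test_single(y, g, groups)
        except ValueError:
            continue
        done += 1
        rej += r.p_value < 0.05
    return rej / n_reps


def interaction_mechanism(seed: int, n_genes: int = 500
                          ) -> tuple[float, float, float]:
    """The single- vs multi-causal interaction contrast.

    Genes carry two additive causal variants in group-varying LD (template
    blocks over differentiated frequencies) and no true interaction. Returns
    (single-model fraction significant at 0.05, multi-model fraction,
    fraction of single-model calls resolved by the multi model).
    """
    cfg = sim.SimConfig(n_genes=1, populations_per_group=2,
                        samples_per_population=50, use_ld_templates=True,
                        ld_n_templates=8, seed=seed)
    rng = np.random.default_rng(seed + 2)
    ps_s, ps_m = [], []
    while len(ps_s) < n_genes:
        rep_seed = int(rng.integers(2 ** 31))
        r2 = np.random.default_rng(rep_seed)
        samples = sim.make_sample_table(cfg, r2)
        gm, _ = sim.simulate_genotypes(cfg, samples, 20, rng=r2)
        maf = gm.maf()
        okv = np.where(maf >= 0.1)[0]
        if okv.size < 2:
            continue
        i1, i2 = r2.choice(okv, 2, replace=False)
        g1 = gm.dosages[i1].astype(float)
        g2 = gm.dosages[i2].astype(float)
        if abs(np.corrcoef(g1, g2)[0, 1]) > 0.95:
            continue
        y = 0.8 * g1 + 0.8 * g2 + r2.normal(0, 1, gm.n_samples)
        try:
            ps = het.interaction_test_single(y, g1, samples.groups).p_value
            pm = het.interaction_test_multi(y, np.column_stack([g1, g2]), 0,
                                            samples.groups).p_value
        except ValueError:
            continue
        ps_s.append(ps)
        ps_m.append(pm)
    ps_s = np.array(ps_s)
    ps_m = np.array(ps_m)
    frac_s = float((ps_s < 0.05).mean())
    frac_m = float((ps_m < 0.05).mean())
    spurious = ps_s < 0.05
    resolved = float((spurious & (ps_m >= 0.05)).sum() / max(spurious.sum(), 1))
    return frac_s, frac_m, resolved


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

def varpart_recovery(seed: int, n_genes: int = 200,
                     target_pct: float = 8.0) -> float:
    """Mean estimated percent variance between populations when the generator
    is set to the target fraction (full 26-population design)."""
    cfg = sim.SimConfig(n_genes=1, samples_per_population=20, seed=seed)
    rng = np.random.default_rng(seed)
    samples = sim.make_sample_table(cfg, rng)
    Y = sim.simulate_varpart_phenotype(samples, n_genes,
                                       between_pop_frac=target_pct / 100,
                                       seed=seed + 1)
    return vp.partition_variance(Y, samples).mean_pct_population


def varpart_permutation_calibration(seed: int, n_reps: int = 200) -> float:
    """KS uniformity p-value of the permutation p under label exchangeability."""
    cfg, samples = _cohort(seed, spp=20)
    rng = np.random.default_rng(seed + 3)
    n = len(samples.sample_ids)
    ps = []
    for rep in range(n_reps):
        Y = rng.normal(size=(5, n))
        _, pp = vp.permutation_null(Y, samples, n_perm=100, seed=seed + rep)
        ps.append(pp)
    return float(stats.kstest(ps, "uniform").pvalue)


# ---------------------------------------------------------------------------
# eGene calling
# ---------------------------------------------------------------------------

def egene_fdr(seed: int, n_reps: int = 20, n: int = 200, p: int = 100
              ) -> float:
    """Empirical FDR among eGene calls, 50 true + 150 null genes per replicate."""
    fdrs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        rows = []
        for gi in range(200):
            G = rng.binomial(2, rng.uniform(0.1, 0.5, p)[:, None],
                             size=(p, n))
            gm = _toy_gm(G)
            is_true = gi < 50
            y = (0.5 * G[0] if is_true else 0.0) + rng.normal(0, 1, n)
            emp, *_ = scan_mod.permutation_pass(y, gm, np.arange(p),
                                                n_perm=1000,
                                                seed=seed + rep * 1000 + gi)
            rows.append((f"g{gi}", emp, is_true))
        t = pd.DataFrame(rows, columns=["feature_id", "empirical_p",
                                        "is_true"])
        res = scan_mod.call_egenes(t[["feature_id", "empirical_p"]])
        called = res.table["is_egene"].to_numpy()
        fd = int((~t["is_true"].to_numpy() & called).sum())
        fdrs.append(fd / max(int(called.sum()), 1))
    return float(np.mean(fdrs))


def beta_vs_direct_p(seed: int, n_genes: int = 20, n: int = 200,
                     p: int = 100) -> float:
    """Max |beta-approximated p - 10,000-permutation direct p| over genes."""
    rng = np.random.default_rng(seed)
    diffs = []
    for rep in range(n_genes):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, p)[:, None], size=(p, n))
        gm = _toy_gm(G)
        y = 0.12 * G[0] + rng.normal(0, 1, n)
        emp, *_ = scan_mod.permutation_pass(y, gm, np.arange(p), n_perm=1000,
                                            seed=seed + rep)
        _, direct, _, _ = scan_mod.permutation_pass(y, gm, np.arange(p),
                                                    n_perm=10_000,
                                                    seed=seed + rep + 5000)
        diffs.append(abs(emp - direct))
    return float(np.max(diffs))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_planted(seed: int, n_reps: int = 20) -> tuple[float, float]:
    """(median log2 fold for 8x-planted annotation, fraction of replicate CIs
    excluding zero)."""
    rng = np.random.default_rng(seed)
    folds, excl = [], []
    for rep in range(n_reps):
        lead = rng.random(100) < 0.8
        bg = rng.random((500, 100)) < 0.1
        res = enrich_mod.enrichment_ci(lead, bg, "promoter")
        folds.append(res.log2_fold_enrichment)
        excl.append(res.ci_low > 0)
    return float(np.median(folds)), float(np.mean(excl))


def enrichment_random_centered(seed: int, n_annotations: int = 50) -> float:
    """Mean log2 fold of uniformly random pseudo-annotations (should be ~0)."""
    rng = np.random.default_rng(seed)
    folds = []
    for rep in range(n_annotations):
        lead = rng.random(200) < 0.3
        bg = rng.random((100, 200)) < 0.3
        folds.append(enrich_mod.enrichment_ci(lead, bg, "rand")
                     .log2_fold_enrichment)
    return float(np.mean(folds))


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def coloc_construction(seed: int, n_reps: int = 10
                       ) -> tuple[float, float, float]:
    """(median PP4 shared-causal pairs, median PP3 disjoint pairs, worst
    |sum of posteriors - 1|) on synthetic signal pairs from one panel."""
    rng = np.random.default_rng(seed)
    pp4s, pp3s, sums = [], [], []
    for rep in range(n_reps):
        X = rng.binomial(2, rng.uniform(0.2, 0.5, 80)[:, None],
                         size=(80, 400)).T.astype(float)
        ca = int(rng.integers(80))
        cb = (ca + 40) % 80
        y1 = X[:, ca] * 0.8 + rng.normal(0, 1, 400)
        y2s = X[:, ca] * 0.8 + rng.normal(0, 1, 400)
        y2d = X[:, cb] * 0.8 + rng.normal(0, 1, 400)
        fa = fm.ibss_fit(y1, X, L=5)
        fs = fm.ibss_fit(y2s, X, L=5)
        fd = fm.ibss_fit(y2d, X, L=5)
        shared = coloc_mod.susie_coloc(fa, fs)
        disjoint = coloc_mod.susie_coloc(fa, fd)
        if shared:
            best = max(shared, key=lambda r: r.pp4)
            pp4s.append(best.pp4)
            sums.append(abs(best.posteriors.sum() - 1))
        if disjoint:
            best = max(disjoint, key=lambda r: r.pp3)
            pp3s.append(best.pp3)
            sums.append(abs(best.posteriors.sum() - 1))
    return (float(np.median(pp4s)), float(np.median(pp3s)),
            float(np.max(sums)))


# ---------------------------------------------------------------------------
# determinism / round-trips
# ---------------------------------------------------------------------------

def determinism_and_roundtrip(seed: int, tmpdir) -> tuple[bool, bool]:
    """(same-seed rerun bitwise identical, VCF+BED round-trips lossless)."""
    from pathlib import Path

    from .io import read_phenotype_bed, read_vcf, write_phenotype_bed, write_vcf

    tmpdir = Path(tmpdir)
    cfg = sim.SimConfig(n_genes=6, populations_per_group=2,
                        samples_per_population=10,
                        variants_per_cis_window=30, seed=seed)
    a = sim.simulate_study(cfg)
    b = sim.simulate_study(cfg)
    identical = (np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
                 and np.array_equal(a.counts.values, b.counts.values)
                 and a.truth.causal.equals(b.truth.causal))
    vcf1 = tmpdir / "a.vcf"
    write_vcf(a.genotypes, vcf1)
    back = read_vcf(vcf1)
    vcf2 = tmpdir / "b.vcf"
    write_vcf(back, vcf2)
    bed1, bed2 = tmpdir / "a.bed", tmpdir / "b.bed"
    write_phenotype_bed(a.counts, bed1)
    write_phenotype_bed(read_phenotype_bed(bed1), bed2)
    lossless = (np.array_equal(back.dosages, a.genotypes.dosages)
                and vcf1.read_bytes() == vcf2.read_bytes()
                and bed1.read_bytes() == bed2.read_bytes())
    return identical, lossless
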