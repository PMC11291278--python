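"""Simulator: differentiation control, aFC generative model, determinism."""

import numpy as np
import pytest

from divqtl import popdiff, simulate
from divqtl.simulate import SimConfig, make_sample_table, simulate_genotypes


def test_zero_differentiation_gives_ancestral_af():
    cfg = SimConfig(n_genes=1, f_group=0.0, f_pop=0.0,
                    populations_per_group=2, samples_per_population=10, seed=1)
    rng = np.random.default_rng(1)
    s = make_sample_table(cfg, rng)
    _, af = simulate_genotypes(cfg, s, 50, rng=rng)
    for col in af.columns:
        if col.startswith("af_"):
            np.testing.assert_allclose(af[col], af["ancestral_af"])


def test_mean_fst_matches_configured_differentiation(small_samples):
    cfg = SimConfig(n_genes=1, f_group=0.10, populations_per_group=2,
                    samples_per_population=20, seed=2)
    rng = np.random.default_rng(2)
    gm, _ = simulate_genotypes(cfg, small_samples, 2000, rng=rng)
    groups = small_samples.groups
    codes = list(dict.fromkeys(groups))
    vals = []
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            da = gm.dosages[:, groups == a]
            db = gm.dosages[:, groups == b]
            vals.append(popdiff.hudson_fst_aggregate(
                da.mean(1) / 2, 2 * da.shape[1], db.mean(1) / 2, 2 * db.shape[1]))
    assert abs(np.mean(vals) - 0.10) < 0.02


def test_same_seed_bitwise_identical():
    cfg = SimConfig(n_genes=3, populations_per_group=2,
                    samples_per_population=10, variants_per_cis_window=30,
                    seed=33)
    a = simulate.simulate_study(cfg)
    b = simulate.simulate_study(cfg)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    np.testing.assert_array_equal(a.counts.values, b.counts.values)
    assert a.truth.causal.equals(b.truth.causal)


def test_truth_variants_present_in_genotypes(small_study):
    vset = set(small_study.genotypes.variants["variant_id"])
    assert set(small_study.truth.causal["variant_id"]) <= vset
    lo, hi = 0.25, 2.0
    betas = small_study.truth.causal["beta"].abs()
    assert ((betas >= lo) & (betas <= hi)).all()


def test_afc_generative_model_exact_fold_change():
    """With a single causal beta=1 and no noise, alt/alt homozygotes express
    exactly 2x the ref/ref mean."""
    beta = 1.0
    hap_alt = np.ones((1, 4, 2), dtype=np.int8)
    hap_ref = np.zeros((1, 4, 2), dtype=np.int8)
    contrib_alt = (2.0 ** (beta * hap_alt)).prod(axis=0).mean(axis=1)
    contrib_ref = (2.0 ** (beta * hap_ref)).prod(axis=0).mean(axis=1)
    np.testing.assert_allclose(contrib_alt / contrib_ref, 2.0 ** beta)


def test_null_gene_expression_independent_of_genotype():
    cfg = SimConfig(n_genes=20, populations_per_group=2,
                    samples_per_population=25, variants_per_cis_window=20,
                    causal_per_gene_probs=(1.0, 0.0, 0.0, 0.0), seed=9)
    study = simulate.simulate_study(cfg)
    assert study.truth.causal.empty
    # association slope CI covers 0 for an arbitrary variant
    y = np.log2(study.counts.values[0] + 1)
    g = study.genotypes_per_gene[0].dosages[0].astype(float)
    slope, intercept = np.polyfit(g, y, 1)
    resid = y - (slope * g + intercept)
    se = np.sqrt(resid.var(ddof=2) / ((g - g.mean()) ** 2).sum())
    assert abs(slope) < 3 * se


def test_ld_templates_induce_correlation(small_samples):
    cfg = SimConfig(n_genes=1, populations_per_group=2,
                    samples_per_population=20, use_ld_templates=True,
                    ld_n_templates=8, seed=4)
    rng = np.random.default_rng(4)
    gm, _ = simulate_genotypes(cfg, small_samples, 40, rng=rng)
    pops = small_samples.populations
    within, between = [], []
    for p in np.unique(pops):
        D = gm.dosages[:, pops == p].astype(float)
        ok = D.std(axis=1) > 0
        cc = np.corrcoef(D[ok])
        idx = np.where(ok)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                v = abs(cc[a, b])
                if idx[a] < 20 and idx[b] < 20:
                    within.append(v)
                elif idx[a] < 20 <= idx[b]:
                    between.append(v)
    # template copying induces within-block LD inside each population
    assert np.nanmean(within) > 1.5 * np.nanmean(between)


class TestSplicing:
    def test_ratios_sum_to_one_per_cluster(self, small_study):
        sp = small_study.splicing
        for cid, sub in sp.features.groupby("cluster_id"):
            total = sp.values[sub.index.to_numpy()].sum(axis=0)
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_null_cluster_matches_dirichlet_mean(self, small_samples):
        cfg = SimConfig(n_genes=1, populations_per_group=2,
                        samples_per_population=20,
                        causal_per_gene_probs=(1.0, 0.0, 0.0, 0.0), seed=6)
        rng = np.random.default_rng(6)
        gm, _ = simulate_genotypes(cfg, small_samples, 20, rng=rng)
        pheno, truth = simulate.simulate_splicing([gm], small_samples, cfg, rng)
        assert truth.empty
        # mean ratio per intron close to its base weight (all samples share w)
        means = pheno.values.mean(axis=1)
        assert means.sum() == pytest.approx(1.0, abs=1e-9)
        assert (pheno.values >= 0).all() and (pheno.values <= 1).all()


def test_varpart_phenotype_nesting_and_interaction_default(small_samples):
    cfg = SimConfig(n_genes=2, populations_per_group=2,
                    samples_per_population=10, seed=8)
    assert cfg.interaction_fraction == 0.0
    Y = simulate.simulate_varpart_phenotype(small_samples, 5,
                                            between_pop_frac=0.2, seed=1)
    assert Y.shape == (5, len(small_samples.sample_ids))
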