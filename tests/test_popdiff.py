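"""Allele-frequency classes, Hudson F_ST, NB differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divqtl import popdiff
from divqtl.popdiff import (classify_maf, fst_by_de_decile, group_af,
                            hudson_fst, hudson_fst_aggregate, nb_de)


class TestClasses:
    def test_class_thresholds(self):
        maf = np.array([0.0, 0.01, 0.049999, 0.05, 0.3])
        assert list(classify_maf(maf)) == ["U", "R", "R", "C", "C"]

    def test_group_af_and_flags(self, small_study):
        cls = group_af(small_study.genotypes, small_study.samples)
        # exhaustive consistency: class derived from MAF matches table
        for col in cls.maf.columns:
            np.testing.assert_array_equal(
                classify_maf(cls.maf[col].to_numpy()), cls.classes[col])
        # flags consistent with classes
        gc = (cls.classes == "C").all(axis=1)
        np.testing.assert_array_equal(cls.flags["globally_common"], gc)

    def test_high_frequency_variant_is_common(self):
        # a variant at AF 0.63 within a group classifies as common
        assert classify_maf(np.array([min(0.63, 1 - 0.63)]))[0] == "C"

    def test_enumeration_oracle(self, small_genotypes, small_samples):
        gm, _ = small_genotypes
        cls = group_af(gm, small_samples)
        groups = small_samples.groups
        codes = list(dict.fromkeys(groups))
        rng = np.random.default_rng(0)
        for vi in rng.integers(0, gm.n_variants, 20):
            for g in codes:
                af = gm.dosages[vi, groups == g].mean() / 2
                maf = min(af, 1 - af)
                expected = "U" if maf == 0 else ("R" if maf < 0.05 else "C")
                assert cls.classes.iloc[vi][g] == expected


class TestHudsonFst:
    def test_formula_oracle_grid(self):
        """Matches an independent transcription of the estimator to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            p1, p2 = rng.uniform(0.01, 0.99, 2)
            n1, n2 = rng.integers(2, 500, 2)
            got = hudson_fst(p1, n1, p2, n2)
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
                - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            assert got == pytest.approx(num / den, abs=1e-12)

    def test_fixation(self):
        assert hudson_fst(1.0, 100, 0.0, 100) == pytest.approx(1.0)

    def test_no_differentiation_small(self):
        assert abs(hudson_fst(0.5, 100, 0.5, 100)) < 0.02

    def test_undefined_when_both_fixed_same(self):
        assert np.isnan(hudson_fst(0.0, 100, 0.0, 100))

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            hudson_fst(0.5, 1, 0.5, 100)

    def test_aggregate_matches_configured_f(self, small_genotypes,
                                            small_samples):
        gm, _ = small_genotypes
        groups = small_samples.groups
        codes = list(dict.fromkeys(groups))
        da = gm.dosages[:, groups == codes[0]]
        db = gm.dosages[:, groups == codes[1]]
        agg = hudson_fst_aggregate(da.mean(1) / 2, 2 * da.shape[1],
                                   db.mean(1) / 2, 2 * db.shape[1])
        assert abs(agg - 0.10) < 0.03  # single pair, 500 variants


class TestNbDe:
    def test_null_calibration(self, small_samples):
        rng = np.random.default_rng(2)
        n = len(small_samples.sample_ids)
        counts = rng.poisson(100, size=(120, n)).astype(float)
        de = nb_de(counts, np.ones(n), small_samples,
                   list(dict.fromkeys(small_samples.groups))[0])
        assert stats.kstest(de["p_value"], "uniform").pvalue > 0.01

    def test_power_at_twofold_shift(self, small_samples):
        rng = np.random.default_rng(3)
        groups = small_samples.groups
        focal = list(dict.fromkeys(groups))[0]
        mu = np.where(groups == focal, 200.0, 100.0)
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu), size=(60, len(groups))
                                       ).astype(float)
        de = nb_de(counts, np.ones(len(groups)), small_samples, focal)
        assert (de["q_value"] <= 0.05).mean() >= 0.9

    def test_poisson_limit_matches_poisson_glm(self, small_samples):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        groups = small_samples.groups
        focal = list(dict.fromkeys(groups))[0]
        n = len(groups)
        counts = rng.poisson(50, size=(40, n)).astype(float)
        de = nb_de(counts, np.ones(n), small_samples, focal)
        X = np.column_stack([np.ones(n), (groups == focal).astype(float)])
        pois_p = []
        for y in counts:
            f1 = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            f0 = sm.GLM(y, X[:, :1], family=sm.families.Poisson()).fit()
            pois_p.append(stats.chi2.sf(2 * (f1.llf - f0.llf), 1))
        d = np.max(np.abs(np.sort(de["p_value"]) - np.sort(pois_p)))
        assert d < 0.05

    def test_deciles_partition_evenly(self, small_samples):
        rng = np.random.default_rng(5)
        n = len(small_samples.sample_ids)
        counts = rng.poisson(100, size=(100, n)).astype(float)
        de = nb_de(counts, np.ones(n), small_samples,
                   list(dict.fromkeys(small_samples.groups))[0])
        sizes = de["de_decile"].value_counts()
        assert sizes.min() >= len(de) // 10 - 1
        assert sizes.max() <= len(de) // 10 + 1


class TestFstByDecile:
    def test_flat_profile_under_identical_fst(self, small_samples):
        rng = np.random.default_rng(6)
        n_genes = 50
        leads = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                              "variant_id": [f"v{i}" for i in range(n_genes)]})
        fst = pd.DataFrame({"variant_id": leads["variant_id"],
                            "focal_group": "A", "fst": 0.1})
        de = pd.DataFrame({"gene_id": leads["gene_id"], "focal_group": "A",
                           "log_fc": 0.0, "lrt_stat": 0.0,
                           "p_value": rng.uniform(size=n_genes),
                           "dispersion": 0.1})
        de["q_value"] = de["p_value"]
        de["is_de"] = de["q_value"] <= 0.5
        ranks = de["p_value"].rank(method="first", ascending=False)
        de["de_decile"] = np.ceil(10 * ranks / len(de)).astype(int)
        table, u, p = fst_by_de_decile(leads, fst, de)
        assert table["mean_fst"].std() == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_too_few_genes_errors(self):
        leads = pd.DataFrame({"gene_id": ["g1"], "variant_id": ["v1"]})
        fst = pd.DataFrame({"variant_id": ["v1"], "focal_group": "A",
                            "fst": [0.1]})
        de = pd.DataFrame({"gene_id": ["g1"], "p_value": [0.5],
                           "is_de": [False], "de_decile": [1]})
        with pytest.raises(ValueError):
            fst_by_de_decile(leads, fst, de)
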