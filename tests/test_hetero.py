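"""Genotype-by-ancestry interaction tests: calibration, reduction, mechanism."""

import numpy as np
import pandas as pd
import pytest

from divqtl import hetero, simulate
from divqtl.hetero import (bonferroni_summary, eligibility_filter,
                           interaction_test_multi, interaction_test_pcs,
                           interaction_test_single)


class TestEligibility:
    def test_thresholds(self):
        maf = pd.DataFrame([[0.10, 0.06, 0.01, 0.0, 0.0],
                            [0.10, 0.01, 0.01, 0.0, 0.0]])
        flags = eligibility_filter(maf)
        assert flags.tolist() == [True, False]

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        maf = pd.DataFrame(rng.uniform(0, 0.5, size=(1000, 5)))
        got = eligibility_filter(maf)
        expected = (maf.to_numpy() >= 0.05).sum(axis=1) >= 2
        np.testing.assert_array_equal(got.to_numpy(), expected)


class TestSingle:
    def test_calibration_under_null(self, small_samples):
        rng = np.random.default_rng(1)
        groups = small_samples.groups
        n = len(groups)
        rej = 0
        nrep = 400
        for rep in range(nrep):
            g = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
            y = 0.5 * g + rng.normal(0, 1, n)
            r = interaction_test_single(y, g, groups)
            rej += r.p_value < 0.05
        lo, hi = 0.05 - 2 * np.sqrt(0.05 * 0.95 / nrep), \
            0.05 + 2 * np.sqrt(0.05 * 0.95 / nrep)
        assert lo <= rej / nrep <= hi

    def test_power_against_true_interaction(self):
        """Interaction delta 0.5 at n=500 under the generative noise level
        (0.5 log2 units) is detected at Bonferroni alpha for 200 tests."""
        cfg = simulate.SimConfig(n_genes=1, populations_per_group=2,
                                 samples_per_population=50, seed=2)
        rng = np.random.default_rng(2)
        s = simulate.make_sample_table(cfg, rng)
        groups = s.groups
        first = list(dict.fromkeys(groups))[0]
        n = len(groups)
        hits = 0
        for rep in range(40):
            g = rng.binomial(2, 0.4, n).astype(float)
            beta = np.where(groups == first, 1.0, 0.5)
            y = beta * g + rng.normal(0, 0.5, n)
            r = interaction_test_single(y, g, groups)
            hits += r.p_value < 0.05 / 200  # Bonferroni for 200 tests
        assert hits / 40 >= 0.8

    def test_degenerate_one_group_errors(self):
        rng = np.random.default_rng(3)
        groups = np.array(["A"] * 50)
        g = rng.binomial(2, 0.4, 50).astype(float)
        with pytest.raises(ValueError):
            interaction_test_single(g + rng.normal(0, 1, 50), g, groups)

    def test_monomorphic_group_excluded_from_terms(self, small_samples):
        rng = np.random.default_rng(4)
        groups = small_samples.groups
        codes = list(dict.fromkeys(groups))
        g = rng.binomial(2, 0.4, len(groups)).astype(float)
        g[groups == codes[2]] = 0  # monomorphic there
        r = interaction_test_single(g + rng.normal(0, 1, len(groups)), g,
                                    groups)
        assert codes[2] not in r.groups_tested


class TestMulti:
    def test_reduction_to_single(self, small_samples):
        rng = np.random.default_rng(5)
        groups = small_samples.groups
        n = len(groups)
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * g + rng.normal(0, 1, n)
        r1 = interaction_test_single(y, g, groups)
        r2 = interaction_test_multi(y, g[:, None], 0, groups)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)
        assert r1.f_stat == pytest.approx(r2.f_stat, abs=1e-10)

    def test_mechanism_additive_signals_resolved(self, small_samples):
        """Two additive causal variants in group-varying LD, no interaction:
        conditioning on both removes most spurious single-model calls."""
        cfg = simulate.SimConfig(
            n_genes=1, populations_per_group=2, samples_per_population=40,
            use_ld_templates=True, ld_n_templates=8, seed=0)
        rng = np.random.default_rng(6)
        ps_s, ps_m = [], []
        for rep in range(150):
            seed = int(rng.integers(2 ** 31))
            r2 = np.random.default_rng(seed)
            s = simulate.make_sample_table(cfg, r2)
            gm, _ = simulate.simulate_genotypes(cfg, s, 20, rng=r2)
            maf = gm.maf()
            ok = np.where(maf >= 0.1)[0]
            if ok.size < 2:
                continue
            i1, i2 = r2.choice(ok, 2, replace=False)
            g1 = gm.dosages[i1].astype(float)
            g2 = gm.dosages[i2].astype(float)
            if abs(np.corrcoef(g1, g2)[0, 1]) > 0.95:
                continue
            y = 0.8 * g1 + 0.8 * g2 + r2.normal(0, 1, gm.n_samples)
            try:
                ps_s.append(interaction_test_single(y, g1, s.groups).p_value)
                ps_m.append(interaction_test_multi(
                    y, np.column_stack([g1, g2]), 0, s.groups).p_value)
            except ValueError:
                continue
        ps_s, ps_m = np.array(ps_s), np.array(ps_m)
        frac_s = (ps_s < 0.05).mean()
        frac_m = (ps_m < 0.05).mean()
        assert frac_s >= 3 * frac_m
        assert frac_m <= 0.10
        # conditioning removes >= 2/3 of the spurious calls
        spurious = ps_s < 0.05
        resolved = spurious & (ps_m >= 0.05)
        assert resolved.sum() >= (2 / 3) * spurious.sum()

    def test_true_epistasis_survives_multi_model(self, small_samples):
        rng = np.random.default_rng(7)
        groups = small_samples.groups
        first = list(dict.fromkeys(groups))[0]
        n = len(groups)
        hits = 0
        for rep in range(30):
            g1 = rng.binomial(2, 0.4, n).astype(float)
            g2 = rng.binomial(2, 0.4, n).astype(float)
            beta1 = np.where(groups == first, 1.2, 0.4)  # real heterogeneity
            y = beta1 * g1 + 0.5 * g2 + rng.normal(0, 1, n)
            r = interaction_test_multi(y, np.column_stack([g1, g2]), 0, groups)
            hits += r.p_value < 0.05
        assert hits / 30 >= 0.5


class TestPcs:
    def test_equivalence_with_two_group_recoding(self):
        rng = np.random.default_rng(8)
        groups = np.array(["A"] * 100 + ["B"] * 100)
        g = rng.binomial(2, 0.4, 200).astype(float)
        y = 0.5 * g + rng.normal(0, 1, 200)
        pc = 2.0 * (groups == "B") - 1.0  # affine recoding of the indicator
        r_cat = interaction_test_single(y, g, groups)
        r_pc = interaction_test_pcs(y, g, pc[:, None])
        assert r_cat.p_value == pytest.approx(r_pc.p_value, abs=1e-8)

    def test_calibration_with_orthogonal_pcs(self, small_samples):
        rng = np.random.default_rng(9)
        n = len(small_samples.sample_ids)
        rej = 0
        nrep = 300
        for rep in range(nrep):
            g = rng.binomial(2, 0.4, n).astype(float)
            y = 0.5 * g + rng.normal(0, 1, n)
            pcs = rng.normal(size=(n, 2))
            rej += interaction_test_pcs(y, g, pcs).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / nrep)
        assert abs(rej / nrep - 0.05) < 2.5 * se


class TestBonferroni:
    def test_null_and_arithmetic(self):
        res = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                            "model": "single", "p_value": 1.0})
        per_model, _ = bonferroni_summary(res)
        assert per_model["n_significant"].iloc[0] == 0
        p = np.full(100, 0.5)
        p[:3] = 0.05 / 100 / 2  # clearly below alpha / 100
        res["p_value"] = p
        per_model, _ = bonferroni_summary(res)
        assert per_model["n_significant"].iloc[0] == 3

    def test_stratification_by_credible_set_count(self):
        res = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "model": "single",
            "p_value": [1e-6] * 10 + [0.5] * 30,
            "n_credible_sets": [2] * 10 + [1] * 30})
        _, strat = bonferroni_summary(res)
        s2 = strat[strat["n_credible_sets"] == 2]
        s1 = strat[strat["n_credible_sets"] == 1]
        f2 = s2["n_significant"].iloc[0] / s2["n_tests"].iloc[0]
        f1 = s1["n_significant"].iloc[0] / s1["n_tests"].iloc[0]
        assert f2 > f1
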