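"""cis candidate windows, nominal scan, permutation pass, eGene calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divqtl import scan
from divqtl.io import GenotypeMatrix


def _toy_genotypes(positions, dosages, sample_ids=None):
    n = dosages.shape[1]
    v = pd.DataFrame({"chrom": "chr1", "pos": positions, "ref": "A",
                      "alt": "G",
                      "variant_id": [f"v{i}" for i in range(len(positions))]})
    return GenotypeMatrix(v, dosages.astype(np.int8),
                          np.array(sample_ids or [f"s{i}" for i in range(n)]))


class TestCandidates:
    def test_window_boundaries_inclusive(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(3, 40))
        gm = _toy_genotypes([999_999, 1_000_000, 3_000_000], dos)
        idx = scan.cis_candidates(2_000_000, gm, maf_min=0.0)
        # 1,000,000 is exactly 1 Mb away -> included; 999,999 -> excluded;
        # 3,000,000 is exactly 1 Mb away on the other side -> included
        assert list(idx) == [1, 2]

    def test_maf_floor_count(self):
        rng = np.random.default_rng(1)
        n = 200
        dos = np.vstack([rng.binomial(2, 0.3, size=(7, n)),
                         np.zeros((3, n), dtype=int)])
        dos[7, 0] = 1  # MAF = 1/400 < 0.01
        gm = _toy_genotypes(list(range(100, 1100, 100)), dos)
        idx = scan.cis_candidates(500, gm, maf_min=0.01)
        assert len(idx) == 7


class TestNominal:
    def test_orthogonal_dosage_null(self):
        rng = np.random.default_rng(2)
        g = np.tile([0, 1, 2, 1], 25)
        y = np.tile([1.0, -1.0], 50)
        y -= y.mean()
        y -= (y @ (g - g.mean())) / ((g - g.mean()) ** 2).sum() * (g - g.mean())
        gm = _toy_genotypes([100], g[None, :])
        res = scan.nominal_scan(y, gm, np.array([0]), tss=100)
        assert abs(res.table["slope"].iloc[0]) < 1e-12
        assert res.table["p_value"].iloc[0] > 0.999

    def test_perfect_correlation(self):
        g = np.array([0, 1, 2] * 20)
        gm = _toy_genotypes([100], g[None, :])
        res = scan.nominal_scan(g.astype(float), gm, np.array([0]), tss=100)
        assert res.table["p_value"].iloc[0] < 1e-50

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 100)
        y = 0.5 * g + rng.normal(0, 1, 100)
        gm = _toy_genotypes([100], g[None, :])
        p1 = scan.nominal_scan(y, gm, np.array([0]), 100).table["p_value"]
        p2 = scan.nominal_scan(3 * y - 7, gm, np.array([0]), 100).table["p_value"]
        np.testing.assert_allclose(p1, p2)

    def test_power_at_large_effect(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(20):
            g = rng.binomial(2, 0.3, 500)
            y = 1.0 * g + rng.normal(0, 1, 500)
            gm = _toy_genotypes([100], g[None, :])
            p = scan.nominal_scan(y, gm, np.array([0]), 100).table["p_value"]
            hits += p.iloc[0] < 1e-10
        assert hits == 20

    def test_monomorphic_errors(self):
        gm = _toy_genotypes([100], np.zeros((1, 20), dtype=int))
        with pytest.raises(ValueError, match="monomorphic"):
            scan.nominal_scan(np.random.default_rng(0).normal(size=20), gm,
                              np.array([0]), 100)


class TestPermutationPass:
    def test_bound_when_observed_beats_all(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=(20, 300))
        gm = _toy_genotypes(list(range(100, 2100, 100)), g)
        y = g[3] * 2.0 + rng.normal(0, 0.1, 300)
        _, direct, _, _ = scan.permutation_pass(y, gm, np.arange(20),
                                                n_perm=100, seed=1)
        assert direct == pytest.approx(1 / 101)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.4, size=(30, 150))
        gm = _toy_genotypes(list(range(100, 3100, 100)), g)
        ps = []
        for rep in range(60):
            y = rng.normal(0, 1, 150)
            emp, *_ = scan.permutation_pass(y, gm, np.arange(30), n_perm=200,
                                            seed=rep)
            ps.append(emp)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_beta_approximation_close_to_direct(self):
        """Beta-approximated empirical p tracks a high-resolution direct p."""
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.4, size=(40, 200))
        gm = _toy_genotypes(list(range(100, 4100, 100)), g)
        emps, directs = [], []
        for rep in range(10):
            y = 0.15 * g[rep] + rng.normal(0, 1, 200)
            emp, _, _, _ = scan.permutation_pass(y, gm, np.arange(40),
                                                 n_perm=1000, seed=rep)
            _, direct, _, _ = scan.permutation_pass(y, gm, np.arange(40),
                                                    n_perm=5000, seed=rep + 99)
            emps.append(emp)
            directs.append(direct)
        assert np.max(np.abs(np.array(emps) - np.array(directs))) < 0.1

    def test_monotone_in_best_nominal_p(self):
        """With noise held fixed and permutations seeded identically, the
        gene-level empirical p preserves the ordering of best nominal p."""
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.4, size=(10, 100))
        gm = _toy_genotypes(list(range(100, 1100, 100)), g)
        noise = rng.normal(0, 1, 100)
        pairs = []
        for strength in (0.0, 0.2, 0.4, 0.8):
            y = strength * g[0] + noise
            emp, _, best_p, _ = scan.permutation_pass(y, gm, np.arange(10),
                                                      n_perm=200, seed=42)
            pairs.append((best_p, emp))
        order_best = np.argsort([p[0] for p in pairs])
        order_emp = np.argsort([p[1] for p in pairs])
        np.testing.assert_array_equal(order_best, order_emp)


class TestCallEgenes:
    def test_all_null(self):
        t = pd.DataFrame({"feature_id": list("abc"), "empirical_p": [1.0] * 3})
        res = scan.call_egenes(t)
        assert res.table["is_egene"].sum() == 0

    def test_bh_arithmetic_by_hand(self):
        """10 p=0.001 among 90 p=0.9: BH accepts exactly the 10."""
        p = np.array([0.001] * 10 + [0.9] * 90)
        t = pd.DataFrame({"feature_id": [f"g{i}" for i in range(100)],
                          "empirical_p": p})
        res = scan.call_egenes(t, fdr=0.05)
        # hand BH: sorted p_(10)=0.001 <= 0.05*10/100 = 0.005 -> accept 10;
        # p_(11)=0.9 > 0.05*11/100 -> stop
        assert res.table["is_egene"].sum() == 10
        assert set(res.table.loc[res.table["is_egene"], "feature_id"]) == \
            {f"g{i}" for i in range(10)}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            scan.call_egenes(pd.DataFrame(columns=["feature_id",
                                                   "empirical_p"]))
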