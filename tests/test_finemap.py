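"""Sum-of-single-effects fine-mapping: SER oracle, IBSS behaviour, credible sets."""

import numpy as np
import pytest

from divqtl import finemap
from divqtl.finemap import (CredibleSet, extract_credible_sets, ibss_fit,
                            merge_intron_sets_to_gene, select_lead,
                            single_effect_regression)


class TestSingleEffectRegression:
    def test_orthogonal_variants_uniform_alpha(self):
        rng = np.random.default_rng(0)
        X = np.kron(np.eye(4), np.ones((25, 1)))  # orthogonal blocks
        y = rng.normal(size=100)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # orthogonal to all
        _, alpha, _, _ = single_effect_regression(y + 0.0, X, prior_var=0.5)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-10)

    def test_dominant_variant(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        y = X[:, 2] * 1.0
        _, alpha, _, _ = single_effect_regression(y, X, prior_var=1.0)
        assert alpha[2] > 0.99

    def test_closed_form_oracle(self):
        """alpha matches a direct evaluation of the Bayes-factor formula."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        y = 0.3 * X[:, 0] + rng.normal(size=50)
        V, s2 = 0.4, 1.3
        lbf, alpha, mean, var = single_effect_regression(y, X, prior_var=V,
                                                         residual_var=s2)
        yc = y - y.mean()
        Xc = X - X.mean(0)
        for j in range(5):
            d = Xc[:, j] @ Xc[:, j]
            bhat = (Xc[:, j] @ yc) / d
            shat2 = s2 / d
            # BF of N(bhat; 0, V + shat2) vs N(bhat; 0, shat2)
            expected = (0.5 * np.log(shat2 / (shat2 + V))
                        + 0.5 * bhat ** 2 / shat2 * V / (shat2 + V))
            assert lbf[j] == pytest.approx(expected, abs=1e-10)
            tau2 = 1 / (1 / V + d / s2)
            assert mean[j] == pytest.approx(tau2 * (Xc[:, j] @ yc) / s2,
                                            abs=1e-10)
        w = np.exp(lbf - lbf.max())
        np.testing.assert_allclose(alpha, w / w.sum(), atol=1e-12)


class TestIbss:
    def test_elbo_monotone_and_alpha_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, rng.uniform(0.1, 0.5, 80), size=(250, 80)).astype(float)
        y = 0.7 * X[:, 10] - 0.5 * X[:, 55] + rng.normal(size=250)
        fit = ibss_fit(y, X, L=10)
        diffs = np.diff(fit.elbo)
        assert (diffs > -1e-8).all()
        np.testing.assert_allclose(fit.alpha.sum(axis=1), 1.0, atol=1e-9)
        assert ((fit.pip >= 0) & (fit.pip <= 1)).all()

    def test_pip_identity(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, size=(150, 30)).astype(float)
        y = X[:, 5] + rng.normal(size=150)
        fit = ibss_fit(y, X, L=5)
        active = fit.prior_var > 1e-9
        expected = 1 - np.prod(1 - fit.alpha[active], axis=0) if active.any() \
            else np.zeros(30)
        np.testing.assert_allclose(fit.pip, expected, atol=1e-12)

    def test_null_yields_no_credible_sets(self):
        rng = np.random.default_rng(5)
        zero_sets = 0
        for rep in range(20):
            X = rng.binomial(2, rng.uniform(0.1, 0.5, 100),
                             size=(250, 100)).astype(float)
            y = rng.normal(size=250)
            fit = ibss_fit(y, X, L=10)
            cs = extract_credible_sets(fit, X)
            zero_sets += len(cs) == 0
        assert zero_sets >= 19  # >= 95% of null replicates

    def test_two_unlinked_causal_variants_recovered(self):
        rng = np.random.default_rng(6)
        ok = 0
        for rep in range(25):
            X = rng.binomial(2, rng.uniform(0.2, 0.5, 100),
                             size=(400, 100)).astype(float)
            i, j = 10, 60
            sd = np.sqrt(X[:, i].var() * 0.05 ** -1 - X[:, i].var())
            y = X[:, i] * 1.0 + X[:, j] * 1.0 + rng.normal(0, 2.0, 400)
            fit = ibss_fit(y, X, L=10,
                           variant_ids=np.array([f"v{k}" for k in range(100)]))
            cs = extract_credible_sets(fit, X)
            got_i = any("v10" in c.variant_ids for c in cs)
            got_j = any("v60" in c.variant_ids for c in cs)
            ok += (len(cs) == 2 and got_i and got_j)
        assert ok >= 15  # >= 60%

    def test_l1_reduces_to_ser_ranking(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.3, size=(200, 40)).astype(float)
        y = X[:, 8] * 0.8 + rng.normal(size=200)
        fit = ibss_fit(y, X, L=1)
        _, alpha, _, _ = single_effect_regression(
            y, X, prior_var=float(fit.prior_var[0]),
            residual_var=fit.sigma2)
        assert np.argmax(fit.alpha[0]) == np.argmax(alpha)
        np.testing.assert_allclose(fit.alpha[0], alpha, atol=1e-6)


class TestCredibleSets:
    def _fit_like(self, alpha_row, prior_var=1.0):
        L, p = 1, alpha_row.size
        return finemap.SusieFit(
            alpha=alpha_row[None, :], mu=np.zeros((L, p)),
            mu2=np.zeros((L, p)), lbf_variant=np.zeros((L, p)),
            lbf_effect=np.zeros(L), prior_var=np.array([prior_var]),
            sigma2=1.0, pip=alpha_row, elbo=[0.0], converged=True,
            variant_ids=np.array([f"v{j}" for j in range(p)]))

    def test_prefix_rule_singleton(self):
        alpha = np.array([0.97, 0.01, 0.01, 0.01])
        X = np.random.default_rng(8).binomial(2, 0.4, size=(50, 4)).astype(float)
        cs = extract_credible_sets(self._fit_like(alpha), X, coverage=0.95)
        assert len(cs) == 1 and cs[0].variant_ids == ["v0"]

    def test_diffuse_set_fails_purity_on_unlinked_genotypes(self):
        p = 200
        alpha = np.full(p, 1.0 / p)
        rng = np.random.default_rng(9)
        X = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(300, p)).astype(float)
        cs = extract_credible_sets(self._fit_like(alpha), X, purity_min=0.5)
        assert cs == []

    def test_inactive_effect_dropped(self):
        alpha = np.array([0.99, 0.01])
        X = np.random.default_rng(10).binomial(2, 0.4, size=(50, 2)).astype(float)
        cs = extract_credible_sets(self._fit_like(alpha, prior_var=0.0), X)
        assert cs == []


class TestMergeAndLead:
    def _cs(self, set_id, variants, pips, gene="g1"):
        return CredibleSet("f", gene, set_id, variants, np.array(pips), 0.95,
                           1.0, variants[int(np.argmax(pips))])

    def test_transitive_closure(self):
        merged = merge_intron_sets_to_gene([
            self._cs("s1", ["A", "B"], [0.6, 0.4]),
            self._cs("s2", ["B", "C"], [0.5, 0.5]),
        ])
        assert len(merged) == 1
        assert merged[0].variant_ids == ["A", "B", "C"]
        # PIP per variant = max over merged sets
        pip = dict(zip(merged[0].variant_ids, merged[0].pips))
        assert pip["B"] == pytest.approx(0.5)

    def test_disjoint_sets_stay_separate(self):
        merged = merge_intron_sets_to_gene([
            self._cs("s1", ["A"], [0.99]),
            self._cs("s2", ["C"], [0.98]),
        ])
        assert len(merged) == 2

    def test_chain_of_three(self):
        merged = merge_intron_sets_to_gene([
            self._cs("s1", ["A", "B"], [0.9, 0.1]),
            self._cs("s2", ["C", "D"], [0.9, 0.1]),
            self._cs("s3", ["B", "C"], [0.5, 0.5]),
        ])
        assert len(merged) == 1 and len(merged[0].variant_ids) == 4

    def test_select_lead_rules(self):
        ids = np.array(["vB", "vA"])
        assert select_lead(ids, np.array([0.6, 0.3])) == "vB"  # argmax
        assert select_lead(ids, np.array([0.5, 0.5]),
                           np.array([1000.0, 100.0])) == "vA"  # nearer
        assert select_lead(ids, np.array([0.5, 0.5]),
                           np.array([100.0, 100.0])) == "vA"  # lexicographic

    def test_one_causal_driving_three_introns_merges_to_one_set(self):
        rng = np.random.default_rng(11)
        ok = 0
        for rep in range(10):
            X = rng.binomial(2, rng.uniform(0.2, 0.5, 60),
                             size=(300, 60)).astype(float)
            ci = 30
            sets = []
            for intron in range(3):
                y = X[:, ci] * 0.9 + rng.normal(0, 1, 300)
                fit = ibss_fit(y, X, L=5,
                               variant_ids=np.array([f"v{j}" for j in range(60)]))
                sets.extend(extract_credible_sets(fit, X, gene_id="g",
                                                  feature_id=f"intron{intron}"))
            merged = merge_intron_sets_to_gene(sets)
            ok += (len(merged) == 1 and "v30" in merged[0].variant_ids)
        assert ok >= 9
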