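"""Effect-size heterogeneity (he-QTL) tests.

A genotype-by-continental-group interaction F-test compares a full model
``y ~ g + group + g:group (+ covariates)`` against the reduced model without
the interaction block. The single-causal variant tests one focal variant per
gene; the multi-causal variant additionally conditions on the additive effects
of every lead QTL of the gene and tests the interaction of one lead at a time
— the contrast that shows most apparent interactions are unmodelled additive
signals rather than true heterogeneity. A genotype-by-genotype-PC variant
replaces the categorical interaction with ``g:PC_j`` terms.

P-values are one-tailed (upper tail of the F distribution). Interaction terms
are only included for groups where the focal variant is polymorphic and that
retain at least 5 samples. Eligibility requires MAF >= 0.05 in at least two
continental groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_GROUP_SAMPLES = 5


@dataclass
class InteractionResult:
    gene_id: str
    focal_variant: str
    model: str  # single | multi | pcs
    n_leads_in_model: int
    f_stat: float
    df1: int
    df2: int
    p_value: float
    groups_tested: list[str]


def eligibility_filter(maf_by_group: pd.DataFrame,
                       maf_min: float = 0.05, min_groups: int = 2) -> pd.Series:
    """Eligible iff MAF >= maf_min in at least ``min_groups`` groups."""
    return (maf_by_group >= maf_min).sum(axis=1) >= min_groups


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def _f_test(y, X_full, X_reduced, gene_id, focal, model, n_leads, groups_tested):
    rss_f, rank_f = _rss(y, X_full)
    rss_r, rank_r = _rss(y, X_reduced)
    df1 = rank_f - rank_r
    df2 = y.size - rank_f
    if df1 <= 0:
        raise ValueError("full and reduced models are identical "
                         "(no estimable interaction terms)")
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(max(f, 0.0), df1, df2))
    return InteractionResult(gene_id, focal, model, n_leads, float(f),
                             df1, df2, p, groups_tested)


def _group_blocks(g_focal: np.ndarray, groups: np.ndarray):
    """Group dummies (drop first) and the interaction-eligible group list."""
    codes = list(dict.fromkeys(groups))
    dummies = np.column_stack([(groups == c).astype(float) for c in codes[1:]])
    inter_groups = []
    for c in codes[1:]:
        mask = groups == c
        if mask.sum() >= MIN_GROUP_SAMPLES and g_focal[mask].std() > 0:
            inter_groups.append(c)
    return codes, dummies, inter_groups


def interaction_test_single(y: np.ndarray, g_focal: np.ndarray,
                            groups: np.ndarray,
                            covariates: np.ndarray | None = None,
                            gene_id: str = "", variant_id: str = ""
                            ) -> InteractionResult:
    """F-test of the genotype-by-group interaction for one focal variant."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_focal, dtype=float)
    codes, dummies, inter_groups = _group_blocks(g, groups)
    base = [np.ones_like(y), g]
    if dummies.size:
        base.append(dummies)
    if covariates is not None and np.size(covariates):
        base.append(np.atleast_2d(covariates).T
                    if np.atleast_2d(covariates).shape[0] != y.size
                    else np.atleast_2d(covariates))
    X_reduced = np.column_stack(base)
    inter = [g * (groups == c) for c in inter_groups]
    if not inter:
        raise ValueError("no group with estimable interaction term")
    X_full = np.column_stack([X_reduced] + inter)
    return _f_test(y, X_full, X_reduced, gene_id, variant_id, "single", 1,
                   inter_groups)


def interaction_test_multi(y: np.ndarray, lead_dosages: np.ndarray,
                           focal_index: int, groups: np.ndarray,
                           covariates: np.ndarray | None = None,
                           gene_id: str = "", variant_id: str = ""
                           ) -> InteractionResult:
    """Interaction F-test for one lead, conditioning on all leads' additive effects.

    ``lead_dosages`` is samples x K; the focal lead is ``lead_dosages[:,
    focal_index]``. Later leads perfectly collinear with earlier ones are
    dropped from the additive block.
    """
    y = np.asarray(y, dtype=float)
    G = np.atleast_2d(np.asarray(lead_dosages, dtype=float))
    if G.shape[0] != y.size:
        G = G.T
    K = G.shape[1]
    keep = [0]
    for k in range(1, K):
        r = np.corrcoef(G[:, k], G[:, keep].T)[0, 1:]
        if np.any(np.abs(np.atleast_1d(r)) > 1 - 1e-12):
            continue
        keep.append(k)
    if focal_index not in keep:
        raise ValueError("focal lead is collinear with an earlier lead")
    g = G[:, focal_index]
    codes, dummies, inter_groups = _group_blocks(g, groups)
    base = [np.ones_like(y), G[:, keep]]
    if dummies.size:
        base.append(dummies)
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(covariates)
        base.append(cov if cov.shape[0] == y.size else cov.T)
    X_reduced = np.column_stack(base)
    inter = [g * (groups == c) for c in inter_groups]
    if not inter:
        raise ValueError("no group with estimable interaction term")
    X_full = np.column_stack([X_reduced] + inter)
    return _f_test(y, X_full, X_reduced, gene_id, variant_id, "multi",
                   len(keep), inter_groups)


def interaction_test_pcs(y: np.ndarray, g_focal: np.ndarray,
                         genotype_pcs: np.ndarray,
                         covariates: np.ndarray | None = None,
                         gene_id: str = "", variant_id: str = ""
                         ) -> InteractionResult:
    """Genotype-by-genotype-PC interaction F-test (continuous ancestry axes)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_focal, dtype=float)
    P = np.atleast_2d(np.asarray(genotype_pcs, dtype=float))
    if P.shape[0] != y.size:
        P = P.T
    base = [np.ones_like(y), g, P]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(covariates)
        base.append(cov if cov.shape[0] == y.size else cov.T)
    X_reduced = np.column_stack(base)
    X_full = np.column_stack([X_reduced] + [g * P[:, j]
                                            for j in range(P.shape[1])])
    return _f_test(y, X_full, X_reduced, gene_id, variant_id, "pcs", 1,
                   [f"PC{j+1}" for j in range(P.shape[1])])


def bonferroni_summary(results: pd.DataFrame, alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of Bonferroni-significant interactions per model family.

    ``results`` columns: gene_id, model, p_value and optionally
    n_credible_sets for the per-stratum table. The threshold is
    ``alpha / n_tests`` within each model family.
    """
    t = results.copy()
    t["significant"] = False
    for model, sub in t.groupby("model"):
        thr = alpha / len(sub)
        t.loc[sub.index, "significant"] = sub["p_value"] < thr
    per_model = (t.groupby("model")["significant"]
                 .agg(n_significant="sum", n_tests="count").reset_index())
    if "n_credible_sets" in t.columns:
        strat = (t.groupby(["model", "n_credible_sets"])["significant"]
                 .agg(n_significant="sum", n_tests="count").reset_index())
    else:
        strat = pd.DataFrame()
    return per_model, strat
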