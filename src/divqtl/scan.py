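"""Nominal cis association scanning and permutation-based eGene calling.

Candidates are the variants within 1 Mb of the feature TSS (inclusive on both
ends) above a MAF floor. The nominal scan is per-variant simple linear
regression of the prepared phenotype on dosage; the gene-level empirical p
comes from the FastQTL-style scheme: permute the phenotype, record the best
nominal p per permutation, fit a Beta(a, b) to the permutation minima by
maximum likelihood, and evaluate its CDF at the observed best p. eGenes are
called by Benjamini–Hochberg on the empirical p-values at 5% FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

CIS_WINDOW = 1_000_000


@dataclass
class NominalResult:
    table: pd.DataFrame  # variant_id, slope, slope_se, t_stat, p_value, maf, tss_distance


@dataclass
class GeneLevelResult:
    table: pd.DataFrame
    # columns: feature_id, best_p, best_variant, empirical_p, direct_empirical_p,
    #          q_value, is_egene, nominal_threshold


def cis_candidates(tss: int, genotypes: GenotypeMatrix,
                   maf_min: float = 0.01, chrom: str | None = None) -> np.ndarray:
    """Indices of candidate variants: |pos - tss| <= 1 Mb (inclusive), MAF >= floor."""
    v = genotypes.variants
    mask = (v["pos"] >= tss - CIS_WINDOW) & (v["pos"] <= tss + CIS_WINDOW)
    if chrom is not None:
        mask &= v["chrom"] == chrom
    maf = genotypes.maf()
    mask &= maf >= maf_min
    return np.where(mask.to_numpy())[0]


def _corr_with(y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Pearson r of y (n,) against each row of G (p, n)."""
    yc = y - y.mean()
    Gc = G - G.mean(axis=1, keepdims=True)
    denom = np.sqrt((Gc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Gc @ yc / denom, 0.0)


def nominal_scan(y: np.ndarray, genotypes: GenotypeMatrix,
                 candidate_idx: np.ndarray, tss: int,
                 n_covariates: int = 0) -> NominalResult:
    """Per-variant simple linear regression on centred dosage.

    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - n_covariates`` to
    account for covariates removed upstream by residualisation.
    """
    G = genotypes.dosages[candidate_idx].astype(float)
    if (G.std(axis=1) == 0).any():
        raise ValueError("monomorphic candidate passed to nominal_scan")
    n = y.size
    df = n - 2 - n_covariates
    r = _corr_with(y, G)
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df)
    Gc = G - G.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    slope = Gc @ yc / (Gc ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope_se = np.where(t != 0, slope / t, np.nan)
    af = G.mean(axis=1) / 2
    v = genotypes.variants.iloc[candidate_idx]
    table = pd.DataFrame({
        "variant_id": v["variant_id"].to_numpy(),
        "slope": slope, "slope_se": np.abs(slope_se), "t_stat": t, "p_value": p,
        "maf": np.minimum(af, 1 - af),
        "tss_distance": v["pos"].to_numpy() - tss,
    })
    return NominalResult(table)


def _best_p_from_r2(r2max: np.ndarray, df: int) -> np.ndarray:
    t2 = r2max * df / (1 - r2max)
    return 2 * stats.t.sf(np.sqrt(t2), df)


def permutation_pass(y: np.ndarray, genotypes: GenotypeMatrix,
                     candidate_idx: np.ndarray, n_perm: int = 1000,
                     seed: int = 0, n_covariates: int = 0
                     ) -> tuple[float, float, float, tuple[float, float]]:
    """Gene-level empirical p by phenotype permutation with Beta approximation.

    Returns ``(empirical_p, direct_empirical_p, best_nominal_p, (a, b))`` where
    (a, b) are the fitted Beta parameters (direct p is used and flagged with
    a = b = nan if the ML fit fails).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    G = genotypes.dosages[candidate_idx].astype(float)
    n = y.size
    df = n - 2 - n_covariates
    Gc = G - G.mean(axis=1, keepdims=True)
    Gn = Gc / np.sqrt((Gc ** 2).sum(axis=1, keepdims=True))
    yc = y - y.mean()
    yn = yc / np.sqrt((yc ** 2).sum())
    obs_r2 = (Gn @ yn) ** 2
    best_p_obs = float(_best_p_from_r2(obs_r2.max(), df))

    # all permutations in one matmul: (p, n) @ (n, n_perm)
    P = np.empty((n, n_perm))
    for j in range(n_perm):
        P[:, j] = yn[rng.permutation(n)]
    r2_perm = (Gn @ P) ** 2
    best_p_perm = _best_p_from_r2(r2_perm.max(axis=0), df)

    direct = (1 + np.sum(best_p_perm <= best_p_obs)) / (1 + n_perm)
    try:
        a, b, *_ = stats.beta.fit(np.clip(best_p_perm, 1e-300, 1 - 1e-12),
                                  floc=0, fscale=1)
        emp = float(stats.beta.cdf(best_p_obs, a, b))
        emp = max(emp, np.finfo(float).tiny)
    except Exception:
        a = b = float("nan")
        emp = direct
    return emp, float(direct), best_p_obs, (float(a), float(b))


def call_egenes(gene_table: pd.DataFrame, fdr: float = 0.05) -> GeneLevelResult:
    """Benjamini–Hochberg over gene-level empirical p-values; eGene iff q <= fdr.

    ``gene_table`` needs columns ``feature_id, empirical_p`` and optionally
    ``beta_a, beta_b`` (used to convert the significance cutoff back to a
    per-gene nominal p threshold for counting significant pairs).
    """
    from statsmodels.stats.multitest import multipletests

    if gene_table.empty:
        raise ValueError("no genes to call")
    t = gene_table.copy()
    rej, q, *_ = multipletests(t["empirical_p"], alpha=fdr, method="fdr_bh")
    t["q_value"] = q
    t["is_egene"] = rej
    # empirical-p cutoff: the largest accepted empirical p (BH step-up)
    accepted = t.loc[t["is_egene"], "empirical_p"]
    cutoff = float(accepted.max()) if len(accepted) else float("nan")
    if {"beta_a", "beta_b"}.issubset(t.columns) and np.isfinite(cutoff):
        with np.errstate(invalid="ignore"):
            t["nominal_threshold"] = stats.beta.ppf(cutoff, t["beta_a"], t["beta_b"])
    else:
        t["nominal_threshold"] = np.nan
    return GeneLevelResult(t)
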