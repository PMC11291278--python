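"""Variance partitioning of expression between vs within population labels.

For each feature a one-way linear model on continental-group labels and,
separately, on population labels yields eta-squared (the between-label share
of total variance, reported in percent). Because populations refine groups,
``R2_population >= R2_group`` holds feature-by-feature.

A single global permutation test per label level permutes sample labels
jointly (population and group together, preserving the nesting) and compares
the across-feature mean R2 with its permutation null. A Gamma GLM on the
per-feature per-group sample variances (log link, analysis-of-deviance LRT,
df = n_groups - 1) tests whether within-group variance differs between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable


@dataclass
class VarPartResult:
    per_feature: pd.DataFrame  # feature index, pct_var_group, pct_var_population
    mean_pct_group: float
    sd_pct_group: float
    mean_pct_population: float
    sd_pct_population: float
    p_group: float | None = None
    p_population: float | None = None


@dataclass
class GroupVarianceResult:
    variances: pd.DataFrame  # feature x group within-group variance estimates
    deviance_stat: float  # chi-square, df = n_groups - 1
    df: int
    p_value: float  # one-tailed


def _eta_squared_matrix(Y: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised eta-squared per row of Y for a single categorical factor."""
    Y = np.atleast_2d(Y)
    codes, idx = np.unique(labels, return_inverse=True)
    counts = np.bincount(idx).astype(float)
    if (counts < 2).any():
        raise ValueError("every label level needs >= 2 samples")
    grand = Y.mean(axis=1, keepdims=True)
    ss_tot = ((Y - grand) ** 2).sum(axis=1)
    # group sums via one matmul
    G = np.zeros((Y.shape[1], len(codes)))
    G[np.arange(Y.shape[1]), idx] = 1.0
    means = (Y @ G) / counts[None, :]
    ss_b = (counts[None, :] * (means - grand) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_b / ss_tot, 0.0)
    return r2


def partition_variance(residual_values: np.ndarray,
                       samples: SampleTable) -> VarPartResult:
    """Point estimates of percent variance between groups and populations."""
    Y = np.atleast_2d(residual_values)
    r2g = 100 * _eta_squared_matrix(Y, samples.groups)
    r2p = 100 * _eta_squared_matrix(Y, samples.populations)
    per = pd.DataFrame({"pct_var_group": r2g, "pct_var_population": r2p})
    return VarPartResult(per, float(r2g.mean()), float(r2g.std(ddof=1)) if len(r2g) > 1 else 0.0,
                         float(r2p.mean()), float(r2p.std(ddof=1)) if len(r2p) > 1 else 0.0)


def permutation_null(residual_values: np.ndarray, samples: SampleTable,
                     n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """One-tailed permutation p for mean R2 at each label level.

    Sample columns are permuted, carrying population and group labels together
    so the nesting is preserved. ``p = (1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    Y = np.atleast_2d(residual_values)
    groups, pops = samples.groups, samples.populations
    obs_g = _eta_squared_matrix(Y, groups).mean()
    obs_p = _eta_squared_matrix(Y, pops).mean()
    ge = pe = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[1])
        ge += _eta_squared_matrix(Y, groups[perm]).mean() >= obs_g
        pe += _eta_squared_matrix(Y, pops[perm]).mean() >= obs_p
    return (1 + ge) / (1 + n_perm), (1 + pe) / (1 + n_perm)


def group_variance_test(residual_values: np.ndarray,
                        samples: SampleTable) -> GroupVarianceResult:
    """Analysis-of-deviance test for group-heteroskedastic expression variance.

    Per-feature per-group sample variances (N = features x groups observations)
    are modelled with a Gamma GLM with log link; the LRT against the
    intercept-only model is a chi-square with df = n_groups - 1 (one-tailed).
    """
    import statsmodels.api as sm

    Y = np.atleast_2d(residual_values)
    groups = samples.groups
    codes = np.unique(groups)
    var_mat = np.empty((Y.shape[0], len(codes)))
    for j, g in enumerate(codes):
        sub = Y[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g} has < 2 samples")
        var_mat[:, j] = sub.var(axis=1, ddof=1)
    flagged = var_mat <= 0
    var_mat = np.where(flagged, 1e-12, var_mat)

    y = var_mat.ravel(order="F")
    glab = np.repeat(np.arange(len(codes)), Y.shape[0])
    X_full = np.zeros((y.size, len(codes)))
    X_full[np.arange(y.size), glab] = 1.0
    X_null = np.ones((y.size, 1))
    fam = sm.families.Gamma(link=sm.families.links.Log())
    fit_full = sm.GLM(y, X_full, family=fam).fit()
    fit_null = sm.GLM(y, X_null, family=fam).fit()
    # scaled deviance difference, dispersion from the full model
    scale = fit_full.scale
    stat = (fit_null.deviance - fit_full.deviance) / scale
    df = len(codes) - 1
    p = float(stats.chi2.sf(stat, df))
    variances = pd.DataFrame(var_mat, columns=list(codes))
    return GroupVarianceResult(variances, float(stat), df, p)
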