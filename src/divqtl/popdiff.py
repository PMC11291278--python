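"""Allele-frequency differentiation of lead QTLs and its link to expression.

Per continental group: allele frequencies, U/R/C classes (unobserved MAF = 0,
rare MAF < 0.05, common MAF >= 0.05) and the frequency-differentiated-QTL
flags built from them; Hudson's F_ST between a focal group and the pooled
complement; negative-binomial GLM differential expression contrasting each
group with all other samples; and the F_ST-by-DE-decile intersection with a
two-tailed Mann–Whitney U comparing DE vs non-DE genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, SampleTable

RARE_MAF = 0.05


@dataclass
class AfClassTable:
    af: pd.DataFrame  # variant_id x group AF
    maf: pd.DataFrame
    classes: pd.DataFrame  # U / R / C per group
    flags: pd.DataFrame  # globally_common, unobserved_in_<g> composites


def classify_maf(maf: np.ndarray) -> np.ndarray:
    out = np.where(maf == 0, "U", np.where(maf < RARE_MAF, "R", "C"))
    return out


def group_af(genotypes: GenotypeMatrix, samples: SampleTable,
             ref_group: str = "EUR", second_group: str = "AFR") -> AfClassTable:
    """Per-group AFs, U/R/C classes and fd-QTL flags.

    Flags mirror the headline classes: globally common (class C in every
    group), unobserved in the reference group but present elsewhere, and
    unobserved in both the reference and the second group.
    """
    groups = samples.groups
    codes = list(dict.fromkeys(groups))
    vids = genotypes.variants["variant_id"]
    af = pd.DataFrame(index=vids)
    for g in codes:
        cols = groups == g
        if cols.sum() < 2:
            raise ValueError(f"group {g} has < 2 samples")
        af[g] = genotypes.dosages[:, cols].mean(axis=1) / 2.0
    maf = af.apply(lambda c: np.minimum(c, 1 - c))
    classes = maf.apply(lambda c: pd.Series(classify_maf(c.to_numpy()),
                                            index=maf.index))
    flags = pd.DataFrame(index=vids)
    flags["globally_common"] = (classes == "C").all(axis=1)
    if ref_group in classes.columns:
        unobs_ref = classes[ref_group] == "U"
        present_elsewhere = (classes.drop(columns=[ref_group]) != "U").any(axis=1)
        flags[f"unobserved_in_{ref_group}"] = unobs_ref & present_elsewhere
        if second_group in classes.columns:
            both = unobs_ref & (classes[second_group] == "U")
            others = classes.drop(columns=[ref_group, second_group])
            flags[f"unobserved_in_{ref_group}_and_{second_group}"] = \
                both & (others != "U").any(axis=1)
    return AfClassTable(af, maf, classes, flags)


def hudson_fst(p1: float | np.ndarray, n1: float, p2: float | np.ndarray,
               n2: float):
    """Hudson's F_ST estimator for two samples of haploid size n1, n2.

    numerator = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    Negative estimates are legitimate sampling noise and are returned as-is;
    a zero denominator (both samples fixed for the same allele) yields NaN.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2 haploid samples")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return fst if fst.ndim else float(fst)


def hudson_fst_aggregate(p1: np.ndarray, n1: float, p2: np.ndarray,
                         n2: float) -> float:
    """Ratio-of-averages Hudson F_ST over many variants (the convention for
    aggregate differentiation summaries; less biased than averaging ratios)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def focal_group_fst(genotypes: GenotypeMatrix, samples: SampleTable,
                    focal_group: str) -> pd.DataFrame:
    """Per-variant Hudson F_ST of the focal group vs the pooled complement."""
    groups = samples.groups
    in_focal = groups == focal_group
    if in_focal.sum() < 1 or (~in_focal).sum() < 1:
        raise ValueError(f"focal group {focal_group} empty or exhaustive")
    d = genotypes.dosages
    p1 = d[:, in_focal].mean(axis=1) / 2
    p2 = d[:, ~in_focal].mean(axis=1) / 2
    fst = hudson_fst(p1, 2 * in_focal.sum(), p2, 2 * (~in_focal).sum())
    return pd.DataFrame({"variant_id": genotypes.variants["variant_id"],
                         "focal_group": focal_group, "fst": fst})


def pairwise_fst_matrix(genotypes: GenotypeMatrix,
                        samples: SampleTable) -> dict[tuple[str, str], np.ndarray]:
    groups = samples.groups
    codes = list(dict.fromkeys(groups))
    out = {}
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            da, db = genotypes.dosages[:, groups == a], genotypes.dosages[:, groups == b]
            out[(a, b)] = hudson_fst(da.mean(axis=1) / 2, 2 * da.shape[1],
                                     db.mean(axis=1) / 2, 2 * db.shape[1])
    return out


# ---------------------------------------------------------------------------
# negative-binomial differential expression
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    r = 1.0 / alpha
    from scipy.special import gammaln
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def nb_de(counts: np.ndarray, size_factors: np.ndarray, samples: SampleTable,
          focal_group: str, gene_ids: list[str] | None = None,
          fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene NB GLM LRT of a focal-group-vs-rest indicator.

    Log link with ``log(size_factor)`` offset; the per-gene dispersion is
    estimated by maximum likelihood under the full model (method-of-moments
    start) and held fixed for the reduced fit, giving a 1-df chi-square LRT.
    """
    import statsmodels.api as sm
    from scipy.optimize import minimize_scalar
    from statsmodels.stats.multitest import multipletests

    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    groups = samples.groups
    indicator = (groups == focal_group).astype(float)
    if indicator.sum() == 0:
        raise ValueError(f"no samples in focal group {focal_group}")
    n = counts.shape[1]
    offset = np.log(size_factors)
    X_full = np.column_stack([np.ones(n), indicator])
    X_null = np.ones((n, 1))
    gene_ids = gene_ids or [f"gene{i}" for i in range(counts.shape[0])]

    rows = []
    for i, y in enumerate(counts):
        if y.sum() == 0:
            continue
        # Poisson start for the mean structure
        pois = sm.GLM(y, X_full, family=sm.families.Poisson(),
                      offset=offset).fit()
        mu = pois.fittedvalues
        # method-of-moments dispersion, then 1-D ML refinement
        mom = max(((y - mu) ** 2 - mu).sum() / (mu ** 2).sum(), 1e-8)

        def nll(loga, _mu=mu, _y=y):
            return -_nb_loglik(_y, _mu, np.exp(loga))

        alpha = float(np.exp(minimize_scalar(
            nll, bounds=(np.log(1e-8), np.log(10.0)), method="bounded").x))
        fam = sm.families.NegativeBinomial(alpha=alpha)
        fit_full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
        fit_null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
        lrt = 2 * (fit_full.llf - fit_null.llf)
        p = float(stats.chi2.sf(max(lrt, 0.0), 1))
        rows.append((gene_ids[i], focal_group, float(fit_full.params[1]),
                     float(max(lrt, 0.0)), p, alpha))
    out = pd.DataFrame(rows, columns=["gene_id", "focal_group", "log_fc",
                                      "lrt_stat", "p_value", "dispersion"])
    if len(out):
        rej, q, *_ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
        out["q_value"], out["is_de"] = q, rej
        # deciles by p rank: 10th decile = most significant
        ranks = out["p_value"].rank(method="first", ascending=False)
        out["de_decile"] = np.ceil(10 * ranks / len(out)).astype(int)
    return out


def fst_by_de_decile(lead_table: pd.DataFrame, fst_records: pd.DataFrame,
                     de_results: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Mean lead-QTL F_ST per DE decile + Mann–Whitney U of DE vs non-DE genes.

    ``lead_table`` maps gene_id -> lead variant_id (one per gene-level set);
    returns (decile table, U statistic, two-tailed p).
    """
    merged = (lead_table.merge(de_results, on="gene_id")
              .merge(fst_records, on="variant_id"))
    if len(merged) < 10:
        raise ValueError("need >= 10 genes for decile stratification")
    decile = (merged.groupby("de_decile")["fst"]
              .agg(["mean", "count"]).reset_index()
              .rename(columns={"mean": "mean_fst", "count": "n_genes"}))
    de_f = merged.loc[merged["is_de"], "fst"].dropna()
    non_f = merged.loc[~merged["is_de"], "fst"].dropna()
    if len(de_f) and len(non_f):
        u, p = stats.mannwhitneyu(de_f, non_f, alternative="two-sided")
    else:
        u, p = float("nan"), 1.0
    return decile, float(u), float(p)
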