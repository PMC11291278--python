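"""Allelic-fold-change (aFC) effect sizes, marginal and conditional.

The aFC model treats expression as multiplicative in the causal alleles: an
individual with dosage g at a variant whose alternative haplotype is expressed
k-fold relative to the reference contributes ``((2 - g) + g k) / 2`` of the
reference diploid level, so ``log2(aFC) = log2 k``. The joint (conditional)
model multiplies these factors over all lead QTLs of a gene:

    E[y | g_1..g_K] = C * prod_k ((2 - g_k) + g_k k_k) / 2

fitted by box-constrained least squares on the log2 scale, with each k capped
to [1/100, 100] (the convention of reference aFC implementations). Standard
errors come from a nonparametric bootstrap over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

LOG2_AFC_CAP = np.log2(100.0)


@dataclass
class AfcEstimate:
    gene_id: str
    lead_variant_id: str
    log2_afc: float
    se: float | None
    capped: bool
    n_leads_conditioned: int


def _log2_genotype_factor(g: np.ndarray, beta: float) -> np.ndarray:
    """log2(((2 - g) + g * 2^beta) / 2), computed stably."""
    return np.log2((2.0 - g) + g * np.exp2(beta)) - 1.0


def _fit_joint(z: np.ndarray, G: np.ndarray, beta0: np.ndarray) -> np.ndarray:
    """Least squares of z (log2 expression) on the joint aFC model.

    G is samples x K dosages; returns (intercept, beta_1..K). The intercept is
    profiled out analytically so the optimiser only sees the betas.
    """
    K = G.shape[1]

    def resid(beta):
        pred = np.zeros_like(z)
        for k in range(K):
            pred += _log2_genotype_factor(G[:, k], beta[k])
        r = z - pred
        return r - r.mean()  # intercept profiled out

    sol = least_squares(resid, np.clip(beta0, -LOG2_AFC_CAP, LOG2_AFC_CAP),
                        bounds=(-LOG2_AFC_CAP, LOG2_AFC_CAP),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return sol.x


def afc_single(expression_linear: np.ndarray, dosage: np.ndarray,
               gene_id: str = "", variant_id: str = "",
               n_boot: int = 0, seed: int = 0) -> AfcEstimate:
    """Marginal log2 aFC of one variant from strictly positive expression."""
    return afc_conditional(expression_linear, np.asarray(dosage)[:, None],
                           gene_id=gene_id, lead_variant_ids=[variant_id],
                           n_boot=n_boot, seed=seed)[0]


def afc_conditional(expression_linear: np.ndarray, lead_dosages: np.ndarray,
                    gene_id: str = "", lead_variant_ids: list[str] | None = None,
                    n_boot: int = 200, seed: int = 0) -> list[AfcEstimate]:
    """Joint multiplicative fit; one log2 aFC per lead, conditional on the rest.

    ``lead_dosages`` is samples x K. Perfectly collinear leads (|r| = 1 with an
    earlier one) are dropped and reported with NaN effect. Bootstrap SEs use
    ``n_boot`` resamples of individuals (0 skips the bootstrap).
    """
    y = np.asarray(expression_linear, dtype=float)
    if (y <= 0).any():
        raise ValueError("expression must be strictly positive (add pseudocount)")
    G = np.atleast_2d(np.asarray(lead_dosages, dtype=float))
    if G.shape[0] == y.size and G.ndim == 2 and G.shape[1] != y.size:
        pass
    elif G.shape[1] == y.size:
        G = G.T
    K = G.shape[1]
    ids = lead_variant_ids or [f"lead{k}" for k in range(K)]
    if (G.std(axis=0) == 0).any():
        mono = [ids[k] for k in range(K) if G[:, k].std() == 0]
        raise ValueError(f"monomorphic lead variant(s): {mono}")

    # drop later perfectly collinear leads
    keep = [0]
    for k in range(1, K):
        r = np.corrcoef(G[:, k], G[:, keep].T)[0, 1:]
        if np.any(np.abs(r) > 1 - 1e-12):
            continue
        keep.append(k)
    dropped = sorted(set(range(K)) - set(keep))

    z = np.log2(y)
    Gk = G[:, keep]
    beta0 = np.array([np.polyfit(Gk[:, j], z, 1)[0] for j in range(len(keep))])
    beta = _fit_joint(z, Gk, beta0)

    ses = [None] * len(keep)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = y.size
        boots = np.empty((n_boot, len(keep)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Gb = Gk[idx]
            if (Gb.std(axis=0) == 0).any():
                boots[b] = np.nan
                continue
            boots[b] = _fit_joint(z[idx], Gb, beta)
        ses = list(np.nanstd(boots, axis=0, ddof=1))

    out: list[AfcEstimate] = []
    for j, k in enumerate(keep):
        b = float(beta[j])
        capped = bool(abs(abs(b) - LOG2_AFC_CAP) < 1e-9)
        out.append(AfcEstimate(gene_id, ids[k], b, ses[j], capped, len(keep)))
    for k in dropped:
        out.append(AfcEstimate(gene_id, ids[k], float("nan"), None, False,
                               len(keep)))
    out.sort(key=lambda e: ids.index(e.lead_variant_id))
    return out
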