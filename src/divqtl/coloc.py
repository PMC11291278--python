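"""Colocalization posteriors between two association signals.

The five-hypothesis framework compares, over a shared variant universe, the
evidence that neither signal (H0), only A (H1), only B (H2), both at distinct
variants (H3) or both at one shared variant (H4) are causal. Per-variant
evidence enters as log Bayes factors — Wakefield's approximate Bayes factor
from (beta, se) summaries, or per-effect log BFs from a sum-of-single-effects
fit, in which case every pair of effects is tested separately so multiple
causal variants at each signal are handled. Classification follows the
posterior-probability thresholds: moderate PP4 >= 0.5, strong PP4 >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .finemap import SusieFit


@dataclass
class ColocResult:
    pair_id: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    classification: str  # none | moderate | strong

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_abf(beta: np.ndarray, se: np.ndarray,
                  prior_sd: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor for association from an effect and its SE.

    ``z = beta/se``, ``r = prior_sd^2 / (prior_sd^2 + se^2)``,
    ``log ABF = 0.5 (log(1 - r) + r z^2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    z = beta / se
    r = prior_sd ** 2 / (prior_sd ** 2 + se ** 2)
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return out if out.ndim else float(out)


def _classify(pp4: float) -> str:
    if pp4 >= 0.8:
        return "strong"
    if pp4 >= 0.5:
        return "moderate"
    return "none"


def coloc_posteriors(lbf_a: np.ndarray, lbf_b: np.ndarray,
                     p1: float = 1e-4, p2: float = 1e-4, p12: float = 5e-6,
                     pair_id: str = "") -> ColocResult:
    """Five-hypothesis posteriors from aligned per-variant log Bayes factors.

    H3 sums BF products over ordered pairs of distinct variants; all sums are
    log-sum-exp stabilised. Posteriors are normalised to 1.
    """
    lbf_a = np.asarray(lbf_a, dtype=float)
    lbf_b = np.asarray(lbf_b, dtype=float)
    if lbf_a.shape != lbf_b.shape or lbf_a.ndim != 1:
        raise ValueError("need aligned per-variant log BF vectors")
    if lbf_a.size < 1:
        raise ValueError("empty signal")
    ls_a = logsumexp(lbf_a)
    ls_b = logsumexp(lbf_b)
    ls_ab_same = logsumexp(lbf_a + lbf_b)
    # sum over i != j of BFa_i * BFb_j  =  (sum_i BFa_i)(sum_j BFb_j) - sum_i BFa_i BFb_i
    total = ls_a + ls_b
    with np.errstate(invalid="ignore"):
        diff = 1.0 - np.exp(ls_ab_same - total)
    ls_ab_diff = total + np.log(max(diff, 1e-300))

    lh = np.array([
        0.0,
        np.log(p1) + ls_a,
        np.log(p2) + ls_b,
        np.log(p1) + np.log(p2) + ls_ab_diff,
        np.log(p12) + ls_ab_same,
    ])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocResult(pair_id, *map(float, post), _classify(float(post[4])))


def susie_coloc(fit_a: SusieFit, fit_b: SusieFit,
                p1: float = 1e-4, p2: float = 1e-4, p12: float = 5e-6,
                pair_prefix: str = "") -> list[ColocResult]:
    """Coloc posteriors for every pair of active effects of two fits.

    Both fits must share the same variant universe (aligned columns). Effects
    with prior variance ~0 are inactive and skipped.
    """
    if fit_a.alpha.shape[1] != fit_b.alpha.shape[1]:
        raise ValueError("fits must share the variant universe")
    act_a = [l for l in range(fit_a.L) if fit_a.prior_var[l] > 1e-9]
    act_b = [l for l in range(fit_b.L) if fit_b.prior_var[l] > 1e-9]
    out = []
    for la in act_a:
        for lb in act_b:
            res = coloc_posteriors(fit_a.lbf_variant[la], fit_b.lbf_variant[lb],
                                   p1, p2, p12,
                                   pair_id=f"{pair_prefix}A{la}_B{lb}")
            out.append(res)
    return out
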