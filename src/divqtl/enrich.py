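"""Functional enrichment of lead QTLs against matched background variants.

Backgrounds are matched on MAF and absolute TSS distance: the candidate pool
is binned into a 10 x 10 grid of MAF deciles by |TSS distance| deciles
(deciles computed on the pool), and each background draw samples, per lead,
one pool variant uniformly from the lead's joint bin without replacement
within a draw. Enrichment is the lead proportion inside an annotation over the
mean background proportion, with 95% percentile confidence intervals across
draws (zero-proportion draws get a 0.5/n_leads pseudo-count). Categories with
fewer than 5 lead variants are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN_LEADS_PER_CATEGORY = 5


@dataclass
class AnnotationSet:
    """Either BED intervals (0-based half-open) or per-variant category labels."""

    name: str
    intervals: pd.DataFrame | None = None  # columns: chrom, start, end
    labels: pd.Series | None = None  # index variant_id -> category string

    def __post_init__(self) -> None:
        if (self.intervals is None) == (self.labels is None):
            raise ValueError("provide exactly one of intervals or labels")
        if self.intervals is not None:
            iv = self.intervals
            if (iv["end"] <= iv["start"]).any() or (iv["start"] < 0).any():
                raise ValueError("malformed interval (end <= start or negative)")


def annotate_variants(variants: pd.DataFrame, annotation: AnnotationSet,
                      category: str | None = None) -> np.ndarray:
    """Boolean membership per variant.

    Interval membership tests the 0-based position (``pos - 1``) against
    [start, end) per chromosome with a sorted-interval binary search; label
    membership is exact string match on the given category.
    """
    if annotation.labels is not None:
        lab = annotation.labels.reindex(variants["variant_id"])
        return (lab == (category or annotation.name)).to_numpy()
    member = np.zeros(len(variants), dtype=bool)
    for chrom, iv in annotation.intervals.groupby("chrom"):
        mask = (variants["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        iv = iv.sort_values("start")
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        # max end seen so far handles overlapping intervals
        max_end = np.maximum.accumulate(ends)
        pos0 = variants.loc[mask, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        hit = np.zeros(pos0.size, dtype=bool)
        valid = j >= 0
        # walk back while a previous interval may still span pos (overlaps)
        jj = j.copy()
        pending = valid.copy()
        while pending.any():
            idx = np.where(pending)[0]
            cur = jj[idx]
            hit[idx] |= (starts[cur] <= pos0[idx]) & (pos0[idx] < ends[cur])
            can_step = (cur > 0)
            if not can_step.any():
                break
            step_idx = idx[can_step]
            jj[step_idx] -= 1
            # stop when even the running max end cannot reach pos
            pending[:] = False
            cont = max_end[jj[step_idx]] > pos0[step_idx]
            pending[step_idx[cont]] = True
            pending &= ~hit
        member[np.where(mask)[0]] = hit
    return member


@dataclass
class EnrichmentResult:
    annotation: str
    n_lead_in: int
    n_lead_total: int
    mean_background_proportion: float
    log2_fold_enrichment: float
    ci_low: float
    ci_high: float
    n_background_draws: int


def _decile_bins(x: np.ndarray) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, 11)[1:-1])
    return np.searchsorted(edges, x, side="right")


def matched_background(lead_maf: np.ndarray, lead_dist: np.ndarray,
                       pool_maf: np.ndarray, pool_dist: np.ndarray,
                       n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Background draws matched on MAF decile x |TSS distance| decile.

    Returns an (n_draws, n_leads) array of pool indices. Within a draw the same
    pool variant is never used twice; an exhausted or empty bin widens to the
    nearest non-empty neighbouring bin (logged).
    """
    rng = np.random.default_rng(seed)
    pm = _decile_bins(pool_maf)
    pdst = _decile_bins(np.abs(pool_dist))
    lead_mb = np.searchsorted(np.quantile(pool_maf, np.linspace(0, 1, 11)[1:-1]),
                              lead_maf, side="right")
    lead_db = np.searchsorted(
        np.quantile(np.abs(pool_dist), np.linspace(0, 1, 11)[1:-1]),
        np.abs(lead_dist), side="right")
    bins: dict[tuple[int, int], np.ndarray] = {}
    for key in set(zip(pm, pdst)):
        bins[key] = np.where((pm == key[0]) & (pdst == key[1]))[0]
    n_leads = lead_maf.size
    draws = np.empty((n_draws, n_leads), dtype=int)
    widened = 0
    for t in range(n_draws):
        used: set[int] = set()
        for i in range(n_leads):
            key = (int(lead_mb[i]), int(lead_db[i]))
            cand = bins.get(key, np.empty(0, dtype=int))
            cand = cand[~np.isin(cand, list(used))] if used else cand
            radius = 1
            while cand.size == 0:
                widened += 1
                near = [k for k in bins
                        if abs(k[0] - key[0]) <= radius and abs(k[1] - key[1]) <= radius]
                cand = np.concatenate([bins[k] for k in near]) if near else \
                    np.arange(pool_maf.size)
                cand = cand[~np.isin(cand, list(used))] if used else cand
                radius += 1
                if radius > 10:
                    cand = np.setdiff1d(np.arange(pool_maf.size), list(used))
            pick = int(rng.choice(cand))
            used.add(pick)
            draws[t, i] = pick
    if widened:
        log.info("matched_background: widened empty/exhausted bins %d times", widened)
    return draws


def enrichment_ci(lead_member: np.ndarray, background_member: np.ndarray,
                  annotation_name: str = "", min_leads: int = 0
                  ) -> EnrichmentResult:
    """Log2 fold enrichment of leads vs matched backgrounds with percentile CI.

    ``lead_member``: boolean membership of each lead; ``background_member``:
    (n_draws, n_leads) boolean membership of each draw's matched variants.
    The ">= 5 leads per category" reporting rule is applied when assembling a
    category table (:func:`enrichment_table`), so depletion of a category
    containing no leads is still quantifiable here.
    """
    n_leads = lead_member.size
    n_in = int(lead_member.sum())
    if n_in < min_leads:
        raise ValueError(
            f"category {annotation_name!r} has {n_in} < {min_leads} "
            "lead variants")
    lead_prop = n_in / n_leads
    draw_props = background_member.mean(axis=1)
    if (draw_props == 0).all() and lead_prop == 0:
        raise ValueError("annotation absent from leads and pool draws")
    pseudo = 0.5 / n_leads
    draw_props_pc = np.where(draw_props == 0, pseudo, draw_props)
    lead_prop_pc = lead_prop if lead_prop > 0 else pseudo
    log2_folds = np.log2(lead_prop_pc / draw_props_pc)
    mean_bg = float(draw_props.mean())
    point = float(np.log2(lead_prop_pc / max(mean_bg, pseudo)))
    lo, hi = np.percentile(log2_folds, [2.5, 97.5])
    return EnrichmentResult(annotation_name, n_in, n_leads, mean_bg, point,
                            float(lo), float(hi), background_member.shape[0])


def enrichment_table(membership: dict[str, np.ndarray],
                     background_membership: dict[str, np.ndarray]
                     ) -> pd.DataFrame:
    """Per-category enrichment table; categories with < 5 leads are excluded
    (the reporting convention for annotation enrichment panels)."""
    rows = []
    for name, lead_member in membership.items():
        if int(lead_member.sum()) < MIN_LEADS_PER_CATEGORY:
            log.info("enrichment_table: dropping %r (<%d leads)", name,
                     MIN_LEADS_PER_CATEGORY)
            continue
        res = enrichment_ci(lead_member, background_membership[name], name)
        rows.append(vars(res))
    return pd.DataFrame(rows)
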