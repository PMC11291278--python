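"""End-to-end orchestration of the synthetic multi-ancestry QTL study.

``run_all`` executes simulate -> prep -> varpart -> scan -> finemap -> afc ->
popdiff -> hetero -> enrich -> coloc on one :class:`RunConfig`, writing a TSV
per stage plus a JSON manifest (seeds, row counts, wall times). Identical
config and seeds give bitwise-identical TSVs; wall times live only in the
manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afc as afc_mod
from . import coloc as coloc_mod
from . import enrich as enrich_mod
from . import finemap as fm
from . import hetero as het
from . import popdiff as pop
from . import scan as scan_mod
from . import varpart as vp
from .io import normalize_expression, prepare_phenotypes
from .simulate import SimConfig, simulate_study, write_study


@dataclass
class RunConfig:
    outdir: str | Path = "divqtl_run"
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_genes=200, populations_per_group=2, samples_per_population=25))
    n_perm: int = 200
    fdr: float = 0.05
    coverage: float = 0.95
    purity_min: float = 0.5
    maf_min: float = 0.01
    n_background_draws: int = 200
    n_pcs: int = 0
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "prep", "varpart", "scan", "finemap",
                               "afc", "popdiff", "hetero", "enrich", "coloc")


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "sim_seed": config.sim.seed,
                      "stages": {}}
    state: dict = {}

    def record(name, t0, **counts):
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3),
                                    **counts}

    for stage in config.stages:
        t0 = time.time()
        try:
            counts = _STAGES[stage](config, state, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, t0, **counts)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = simulate_study(cfg.sim, with_splicing=False)
    st["study"] = study
    write_study(study, outdir / "sim")
    return {"n_genes": study.counts.n_features,
            "n_variants": study.genotypes.n_variants,
            "n_samples": len(study.samples.sample_ids)}


def _stage_prep(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = st["study"]
    st["norm"] = normalize_expression(study.counts)
    st["resid"], st["cov"] = prepare_phenotypes(study.counts, study.samples,
                                                n_pcs=cfg.n_pcs)
    pd.DataFrame(st["cov"].values.T, columns=st["cov"].names).to_csv(
        outdir / "covariates.tsv", sep="\t", index=False, float_format="%.10g")
    return {"n_covariates": len(st["cov"].names)}


def _stage_varpart(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = st["study"]
    res = vp.partition_variance(st["resid"], study.samples)
    pg, pp = vp.permutation_null(st["resid"], study.samples,
                                 n_perm=max(cfg.n_perm, 100), seed=cfg.seed)
    res.p_group, res.p_population = pg, pp
    tab = res.per_feature.copy()
    tab.insert(0, "feature_id", study.counts.features["feature_id"].to_numpy())
    tab.to_csv(outdir / "varpart.tsv", sep="\t", index=False,
               float_format="%.6g")
    gv = vp.group_variance_test(st["resid"], study.samples)
    summary = {"mean_pct_group": res.mean_pct_group,
               "mean_pct_population": res.mean_pct_population,
               "p_group": pg, "p_population": pp,
               "group_variance_chi2": gv.deviance_stat,
               "group_variance_df": gv.df, "group_variance_p": gv.p_value}
    (outdir / "varpart_summary.json").write_text(json.dumps(summary, indent=2))
    st["varpart"] = summary
    return {"n_features": len(tab)}


def _stage_scan(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study, resid = st["study"], st["resid"]
    k = len(st["cov"].names)
    gene_rows, nominal_best = [], []
    for gi, gm in enumerate(study.genotypes_per_gene):
        tss = int(study.counts.features["tss"].iloc[gi])
        cand = scan_mod.cis_candidates(tss, gm, maf_min=cfg.maf_min)
        if cand.size == 0:
            continue
        y = resid[gi]
        nom = scan_mod.nominal_scan(y, gm, cand, tss, n_covariates=k)
        best = nom.table.loc[nom.table["p_value"].idxmin()]
        emp, direct, best_p, (a, b) = scan_mod.permutation_pass(
            y, gm, cand, n_perm=max(cfg.n_perm, 100),
            seed=cfg.seed + 1000 + gi, n_covariates=k)
        gid = study.counts.features["feature_id"].iloc[gi]
        gene_rows.append((gid, best_p, best["variant_id"], emp, direct, a, b))
        nominal_best.append((gid, best["variant_id"], best["slope"],
                             best["p_value"]))
    gene_table = pd.DataFrame(gene_rows, columns=[
        "feature_id", "best_p", "best_variant", "empirical_p",
        "direct_empirical_p", "beta_a", "beta_b"])
    st["egenes"] = scan_mod.call_egenes(gene_table, fdr=cfg.fdr).table
    st["top_nominal"] = pd.DataFrame(
        nominal_best, columns=["gene_id", "variant_id", "slope", "p_value"])
    st["egenes"].to_csv(outdir / "egenes.tsv", sep="\t", index=False,
                        float_format="%.6g")
    return {"n_tested": len(gene_table),
            "n_egenes": int(st["egenes"]["is_egene"].sum())}


def _stage_finemap(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study, resid = st["study"], st["resid"]
    features = study.counts.features
    egene_ids = set(st["egenes"].loc[st["egenes"]["is_egene"], "feature_id"])
    sets, leads = [], []
    st["fits"] = {}
    for gi, gm in enumerate(study.genotypes_per_gene):
        gid = features["feature_id"].iloc[gi]
        if gid not in egene_ids:
            continue
        tss = int(features["tss"].iloc[gi])
        cand = scan_mod.cis_candidates(tss, gm, maf_min=cfg.maf_min)
        if cand.size == 0:
            continue
        X = gm.dosages[cand].T.astype(float)
        vids = gm.variants["variant_id"].to_numpy()[cand]
        dist = gm.variants["pos"].to_numpy()[cand] - tss
        fit = fm.ibss_fit(resid[gi], X, L=10, variant_ids=vids)
        cs = fm.extract_credible_sets(fit, X, coverage=cfg.coverage,
                                      purity_min=cfg.purity_min,
                                      feature_id=gid, gene_id=gid,
                                      tss_distances=dist)
        dist_of = dict(zip(vids, (dist).astype(float)))
        gene_sets = fm.merge_intron_sets_to_gene(cs, dist_of)
        st["fits"][gid] = (fit, cand, gm)
        for s in gene_sets:
            sets.append(s)
            leads.append((gid, s.set_id, s.lead_variant_id))
    st["credible_sets"] = sets
    st["leads"] = pd.DataFrame(leads, columns=["gene_id", "set_id",
                                               "variant_id"])
    rows = [(s.gene_id, s.set_id, v, p, v == s.lead_variant_id, s.purity)
            for s in sets for v, p in zip(s.variant_ids, s.pips)]
    pd.DataFrame(rows, columns=["gene_id", "set_id", "variant_id", "pip",
                                "is_lead", "purity"]).to_csv(
        outdir / "credible_sets.tsv", sep="\t", index=False,
        float_format="%.6g")
    return {"n_credible_sets": len(sets),
            "n_finemapped_genes": st["leads"]["gene_id"].nunique()}


def _stage_afc(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = st["study"]
    norm = st["norm"]
    sf = norm.size_factors
    rows = []
    for gid, sub in st["leads"].groupby("gene_id"):
        gi = study.counts.features.index[
            study.counts.features["feature_id"] == gid][0]
        gm = study.genotypes_per_gene[gi]
        vmap = {v: i for i, v in enumerate(gm.variants["variant_id"])}
        lead_ids = sub["variant_id"].drop_duplicates().tolist()
        G = np.column_stack([gm.dosages[vmap[v]].astype(float)
                             for v in lead_ids])
        ylin = study.counts.values[gi] / sf + 1.0
        try:
            ests = afc_mod.afc_conditional(ylin, G, gene_id=gid,
                                           lead_variant_ids=lead_ids,
                                           n_boot=0)
        except ValueError:
            continue
        for e in ests:
            rows.append((gid, e.lead_variant_id, e.log2_afc, e.capped,
                         e.n_leads_conditioned))
    st["afc"] = pd.DataFrame(rows, columns=["gene_id", "lead_variant",
                                            "log2_afc", "capped", "n_leads"])
    st["afc"].to_csv(outdir / "afc.tsv", sep="\t", index=False,
                     float_format="%.6g")
    return {"n_estimates": len(rows)}


def _stage_popdiff(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = st["study"]
    leads = st["leads"]
    if leads.empty:
        return {"n_lead_variants": 0}
    vset = leads["variant_id"].unique()
    all_ids = study.genotypes.variants["variant_id"]
    idx = np.where(all_ids.isin(vset))[0]
    sub = study.genotypes.subset_variants(idx)
    classes = pop.group_af(sub, study.samples)
    classes.classes.to_csv(outdir / "lead_af_classes.tsv", sep="\t")
    classes.flags.to_csv(outdir / "lead_fd_flags.tsv", sep="\t")
    groups = list(dict.fromkeys(study.samples.groups))
    focal = groups[0]
    fst = pop.focal_group_fst(sub, study.samples, focal)
    norm = st["norm"]
    de = pop.nb_de(study.counts.values, norm.size_factors, study.samples,
                   focal, gene_ids=list(study.counts.features["feature_id"]))
    lead_one = leads.drop_duplicates("gene_id")[["gene_id", "variant_id"]]
    try:
        decile, u, p = pop.fst_by_de_decile(lead_one, fst, de)
        decile.to_csv(outdir / "fst_by_de_decile.tsv", sep="\t", index=False)
        st["fst_de"] = {"mwu": u, "p": p}
    except ValueError:
        st["fst_de"] = None
    fst.to_csv(outdir / "lead_fst.tsv", sep="\t", index=False,
               float_format="%.6g")
    de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format="%.6g")
    st["af_classes"] = classes
    return {"n_lead_variants": len(vset),
            "n_globally_common": int(classes.flags["globally_common"].sum())}


def _stage_hetero(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study, resid = st["study"], st["resid"]
    groups = study.samples.groups
    features = study.counts.features
    rows = []
    classes = st.get("af_classes")
    n_sets = st["leads"].groupby("gene_id").size()
    for gid, sub in st["leads"].groupby("gene_id"):
        gi = features.index[features["feature_id"] == gid][0]
        gm = study.genotypes_per_gene[gi]
        vmap = {v: i for i, v in enumerate(gm.variants["variant_id"])}
        lead_ids = sub["variant_id"].drop_duplicates().tolist()
        G = np.column_stack([gm.dosages[vmap[v]].astype(float)
                             for v in lead_ids])
        y = resid[gi]
        # single-causal test on the top nominal variant
        top = st["top_nominal"].loc[st["top_nominal"]["gene_id"] == gid]
        if len(top):
            tv = top["variant_id"].iloc[0]
            g_top = gm.dosages[vmap[tv]].astype(float)
            if _eligible(g_top, groups):
                try:
                    r = het.interaction_test_single(y, g_top, groups,
                                                    gene_id=gid, variant_id=tv)
                    rows.append((gid, tv, "single", r.p_value, n_sets[gid]))
                except ValueError:
                    pass
        for k, v in enumerate(lead_ids):
            if not _eligible(G[:, k], groups):
                continue
            try:
                r = het.interaction_test_multi(y, G, k, groups, gene_id=gid,
                                               variant_id=v)
                rows.append((gid, v, "multi", r.p_value, n_sets[gid]))
            except ValueError:
                continue
    res = pd.DataFrame(rows, columns=["gene_id", "variant_id", "model",
                                      "p_value", "n_credible_sets"])
    per_model, strat = het.bonferroni_summary(res)
    res.to_csv(outdir / "interactions.tsv", sep="\t", index=False,
               float_format="%.6g")
    per_model.to_csv(outdir / "interactions_summary.tsv", sep="\t",
                     index=False)
    st["interactions"] = res
    return {"n_tests": len(res)}


def _eligible(g: np.ndarray, groups: np.ndarray) -> bool:
    mafs = []
    for c in np.unique(groups):
        af = g[groups == c].mean() / 2
        mafs.append(min(af, 1 - af))
    return int(np.sum(np.asarray(mafs) >= 0.05)) >= 2


def _stage_enrich(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    study = st["study"]
    leads = st["leads"].drop_duplicates("gene_id")
    if len(leads) < enrich_mod.MIN_LEADS_PER_CATEGORY:
        return {"n_leads": len(leads)}
    v = study.genotypes.variants.set_index("variant_id")
    features = study.counts.features.set_index("feature_id")
    lead_pos = v.loc[leads["variant_id"], "pos"].to_numpy()
    tss = features.loc[leads["gene_id"], "tss"].to_numpy()
    lead_dist = lead_pos - tss
    maf_all = pd.Series(study.genotypes.maf(), index=v.index)
    lead_maf = maf_all.loc[leads["variant_id"]].to_numpy()
    pool_mask = ~v.index.isin(leads["variant_id"])
    pool = v[pool_mask]
    pool_maf = maf_all[pool_mask].to_numpy()
    # pool TSS distance relative to each variant's own gene window centre
    gene_of_variant = pool.index.str.split("_").str[0]
    pool_tss = features["tss"].reindex(gene_of_variant).to_numpy()
    pool_dist = pool["pos"].to_numpy() - pool_tss
    draws = enrich_mod.matched_background(
        lead_maf, lead_dist, pool_maf, pool_dist,
        n_draws=cfg.n_background_draws, seed=cfg.seed + 7)
    # demo annotation: promoter-proximal windows around every TSS
    promoter = pd.DataFrame({
        "chrom": features["chrom"].to_numpy(),
        "start": np.maximum(features["tss"].to_numpy() - 1 - 10_000, 0),
        "end": features["tss"].to_numpy() - 1 + 10_000,
    })
    ann = enrich_mod.AnnotationSet("promoter_proximal", intervals=promoter)
    lead_df = v.loc[leads["variant_id"]].reset_index()
    lead_member = enrich_mod.annotate_variants(lead_df, ann)
    pool_df = pool.reset_index()
    pool_member = enrich_mod.annotate_variants(pool_df, ann)
    bg_member = pool_member[draws]
    try:
        res = enrich_mod.enrichment_ci(lead_member, bg_member,
                                       "promoter_proximal")
        pd.DataFrame([vars(res)]).to_csv(outdir / "enrichment.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        st["enrichment"] = res
    except ValueError:
        st["enrichment"] = None
    return {"n_leads": len(leads)}


def _stage_coloc(cfg: RunConfig, st: dict, outdir: Path) -> dict:
    """Colocalize each fine-mapped eQTL against a synthetic second trait
    sharing (or not sharing) its causal variant, from the same genotypes."""
    study = st["study"]
    rng = np.random.default_rng(cfg.seed + 99)
    rows = []
    for gid, (fit, cand, gm) in st["fits"].items():
        truth = study.truth.causal_of(gid)
        if truth.empty:
            continue
        vmap = {v: i for i, v in enumerate(gm.variants["variant_id"])}
        X = gm.dosages[cand].T.astype(float)
        shared = bool(rng.random() < 0.5)
        if shared:
            ci = vmap[truth["variant_id"].iloc[0]]
        else:
            ci = int(rng.choice(np.setdiff1d(
                cand, [vmap[v] for v in truth["variant_id"]])))
        g = gm.dosages[ci].astype(float)
        y2 = 0.5 * g + rng.normal(0, 1, size=g.size)
        fit2 = fm.ibss_fit(y2, X, L=5,
                           variant_ids=gm.variants["variant_id"].to_numpy()[cand])
        for res in coloc_mod.susie_coloc(fit, fit2, pair_prefix=f"{gid}_"):
            rows.append((gid, res.pair_id, shared, res.pp0, res.pp1, res.pp2,
                         res.pp3, res.pp4, res.classification))
    out = pd.DataFrame(rows, columns=["gene_id", "pair_id", "truth_shared",
                                      "pp0", "pp1", "pp2", "pp3", "pp4",
                                      "classification"])
    out.to_csv(outdir / "coloc.tsv", sep="\t", index=False,
               float_format="%.6g")
    st["coloc"] = out
    return {"n_pairs": len(out)}


_STAGES = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "varpart": _stage_varpart,
    "scan": _stage_scan,
    "finemap": _stage_finemap,
    "afc": _stage_afc,
    "popdiff": _stage_popdiff,
    "hetero": _stage_hetero,
    "enrich": _stage_enrich,
    "coloc": _stage_coloc,
}
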