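"""Enrichment of lead QTLs in genomic annotations vs matched backgrounds.

Two annotations act as controls of the machinery. A "regulatory element"
annotation built as 2 kb windows around the simulator's true causal variants
is a positive control: lead QTLs (mostly causal variants) should be strongly
enriched relative to backgrounds matched on MAF decile x |TSS distance|
decile. A promoter-proximal annotation (TSS +- 50 kb) is a negative control:
causal variants are placed uniformly in the cis window, so after distance
matching its CI should cover zero.
"""

import numpy as np
import pandas as pd
from common import RESULTS, SEED, load_inputs, load_truth

from divqtl import enrich


def main():
    genotypes, counts, samples = load_inputs()
    causal, _ = load_truth()
    leads = pd.read_csv(RESULTS / "leads.tsv", sep="\t").drop_duplicates(
        "gene_id")
    v = genotypes.variants.set_index("variant_id")
    features = counts.features.set_index("feature_id")
    lead_pos = v.loc[leads["variant_id"], "pos"].to_numpy()
    tss = features.loc[leads["gene_id"], "tss"].to_numpy()
    lead_dist = lead_pos - tss

    maf_all = pd.Series(genotypes.maf(), index=v.index)
    pool_mask = ~v.index.isin(leads["variant_id"])
    pool = v[pool_mask]
    gene_of = pool.index.str.split("_").str[0]
    pool_tss = features["tss"].reindex(gene_of).to_numpy()
    pool_dist = pool["pos"].to_numpy() - pool_tss

    draws = enrich.matched_background(
        maf_all.loc[leads["variant_id"]].to_numpy(), lead_dist,
        maf_all[pool_mask].to_numpy(), pool_dist, n_draws=500, seed=SEED)

    causal_pos = v.loc[causal["variant_id"].unique(), "pos"].to_numpy()
    annotations = {
        "regulatory_element": pd.DataFrame({
            "chrom": "chr1",
            "start": np.maximum(causal_pos - 1 - 1000, 0),
            "end": causal_pos - 1 + 1000}),
        "promoter_proximal": pd.DataFrame({
            "chrom": features["chrom"].to_numpy(),
            "start": np.maximum(features["tss"].to_numpy() - 1 - 50_000, 0),
            "end": features["tss"].to_numpy() - 1 + 50_000}),
    }
    results = []
    for name, intervals in annotations.items():
        ann = enrich.AnnotationSet(name, intervals=intervals)
        lead_member = enrich.annotate_variants(
            v.loc[leads["variant_id"]].reset_index(), ann)
        pool_member = enrich.annotate_variants(pool.reset_index(), ann)
        res = enrich.enrichment_ci(lead_member, pool_member[draws], name)
        results.append(vars(res))
        kind = ("positive control" if name == "regulatory_element"
                else "negative control")
        print(f"{name} ({kind}): {res.n_lead_in}/{res.n_lead_total} leads, "
              f"background proportion {res.mean_background_proportion:.3f}, "
              f"log2 fold = {res.log2_fold_enrichment:.2f} "
              f"[{res.ci_low:.2f}, {res.ci_high:.2f}]")
    pd.DataFrame(results).to_csv(RESULTS / "enrichment.tsv", sep="\t",
                                 index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
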