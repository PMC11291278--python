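"""Genotype-by-ancestry effect-size heterogeneity tests.

For each fine-mapped eGene: the single-causal model tests its top nominal
eQTL for a genotype-by-continental-group interaction; the multi-causal model
conditions on every lead QTL's additive effect and tests one lead at a time.
Eligibility requires MAF >= 0.05 in at least two groups. Counts of
Bonferroni-significant interactions are stratified by credible-set count.
"""

import numpy as np
import pandas as pd
from common import RESULTS, load_inputs, load_prepared

from divqtl import hetero, popdiff


def main():
    genotypes, counts, samples = load_inputs()
    resid, _ = load_prepared()
    Y = resid.to_numpy()
    leads = pd.read_csv(RESULTS / "leads.tsv", sep="\t")
    top = pd.read_csv(RESULTS / "top_nominal.tsv", sep="\t")
    groups = samples.groups
    vmap = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    fmap = {f: i for i, f in enumerate(counts.features["feature_id"])}

    cls = popdiff.group_af(genotypes, samples)
    eligible = hetero.eligibility_filter(cls.maf)
    n_sets = leads.groupby("gene_id").size()

    rows = []
    for gid, sub in leads.groupby("gene_id"):
        y = Y[fmap[gid]]
        trow = top[top["gene_id"] == gid]
        if len(trow):
            tv = trow["variant_id"].iloc[0]
            if eligible.loc[tv]:
                try:
                    r = hetero.interaction_test_single(
                        y, genotypes.dosages[vmap[tv]].astype(float), groups,
                        gene_id=gid, variant_id=tv)
                    rows.append((gid, tv, "single", r.p_value, n_sets[gid]))
                except ValueError:
                    pass
        lead_ids = sub["variant_id"].drop_duplicates().tolist()
        G = np.column_stack([genotypes.dosages[vmap[v]].astype(float)
                             for v in lead_ids])
        for k, v in enumerate(lead_ids):
            if not eligible.loc[v]:
                continue
            try:
                r = hetero.interaction_test_multi(y, G, k, groups,
                                                  gene_id=gid, variant_id=v)
                rows.append((gid, v, "multi", r.p_value, n_sets[gid]))
            except ValueError:
                continue
    res = pd.DataFrame(rows, columns=["gene_id", "variant_id", "model",
                                      "p_value", "n_credible_sets"])
    per_model, strat = hetero.bonferroni_summary(res)
    res.to_csv(RESULTS / "interactions.tsv", sep="\t", index=False,
               float_format="%.6g")
    per_model.to_csv(RESULTS / "interactions_summary.tsv", sep="\t",
                     index=False)
    if len(strat):
        strat.to_csv(RESULTS / "interactions_by_stratum.tsv", sep="\t",
                     index=False)
    for _, row in per_model.iterrows():
        print(f"{row['model']} model: {row['n_significant']} of "
              f"{row['n_tests']} tests Bonferroni-significant")


if __name__ == "__main__":
    main()
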