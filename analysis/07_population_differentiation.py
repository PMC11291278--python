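"""Frequency differentiation of lead QTLs and its link to expression.

Per-group allele-frequency classes (unobserved / rare / common) and fd-QTL
flags for every lead variant; Hudson F_ST of each lead against the pooled
complement of its focal group; negative-binomial differential expression per
group; and the F_ST-by-DE-decile intersection with a Mann-Whitney U test.
"""

import numpy as np
import pandas as pd
from common import RESULTS, load_inputs

from divqtl import popdiff
from divqtl.io import normalize_expression


def main():
    genotypes, counts, samples = load_inputs()
    norm = normalize_expression(counts)
    leads = pd.read_csv(RESULTS / "leads.tsv", sep="\t")
    vset = leads["variant_id"].unique()
    idx = np.where(genotypes.variants["variant_id"].isin(vset))[0]
    sub = genotypes.subset_variants(idx)

    cls = popdiff.group_af(sub, samples)
    cls.classes.to_csv(RESULTS / "lead_af_classes.tsv", sep="\t")
    cls.flags.to_csv(RESULTS / "lead_fd_flags.tsv", sep="\t")
    n = len(cls.flags)
    print(f"{n} unique lead variants: "
          f"{cls.flags['globally_common'].mean():.0%} globally common; "
          f"{cls.flags.filter(like='unobserved_in_EUR').iloc[:, 0].sum()} "
          f"unobserved in EUR but present elsewhere")

    groups = list(dict.fromkeys(samples.groups))
    fst_all, de_all = [], []
    for focal in groups:
        fst = popdiff.focal_group_fst(sub, samples, focal)
        de = popdiff.nb_de(counts.values, norm.size_factors, samples, focal,
                           gene_ids=list(counts.features["feature_id"]))
        fst_all.append(fst)
        de_all.append(de)
    fst_all = pd.concat(fst_all, ignore_index=True)
    de_all = pd.concat(de_all, ignore_index=True)
    fst_all.to_csv(RESULTS / "lead_fst.tsv", sep="\t", index=False,
                   float_format="%.6g")
    de_all.to_csv(RESULTS / "de.tsv", sep="\t", index=False,
                  float_format="%.6g")

    lead_one = leads.drop_duplicates("gene_id")[["gene_id", "variant_id"]]
    decile_rows = []
    for focal in groups:
        fst = fst_all[fst_all["focal_group"] == focal]
        de = de_all[de_all["focal_group"] == focal]
        try:
            decile, u, p = popdiff.fst_by_de_decile(lead_one, fst, de)
        except ValueError:
            continue
        decile["focal_group"] = focal
        decile_rows.append(decile)
        print(f"{focal}: DE vs non-DE eGene lead F_ST Mann-Whitney "
              f"two-tailed p = {p:.3g}")
    if decile_rows:
        pd.concat(decile_rows, ignore_index=True).to_csv(
            RESULTS / "fst_by_de_decile.tsv", sep="\t", index=False,
            float_format="%.6g")


if __name__ == "__main__":
    main()
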