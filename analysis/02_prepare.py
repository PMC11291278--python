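"""Prepare phenotypes for QTL scanning.

Median-of-ratios size factors, log2 normalisation, per-gene rank
inverse-normal transform, then residualisation against batch and sex.
Writes the residual matrix and the covariates used.
"""

import pandas as pd
from common import RESULTS, load_inputs, prepare


def main():
    genotypes, counts, samples = load_inputs()
    resid, norm, cov = prepare(counts, samples)
    out = pd.DataFrame(resid, index=counts.features["feature_id"],
                       columns=counts.sample_ids)
    out.to_csv(RESULTS / "residuals.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(cov.values.T, columns=cov.names).to_csv(
        RESULTS / "covariates.tsv", sep="\t", index=False,
        float_format="%.10g")
    pd.DataFrame({"sample_id": counts.sample_ids,
                  "size_factor": norm.size_factors}).to_csv(
        RESULTS / "size_factors.tsv", sep="\t", index=False,
        float_format="%.10g")
    print(f"residualised {out.shape[0]} genes x {out.shape[1]} samples "
          f"against {len(cov.names)} covariates ({', '.join(cov.names)})")
    print(f"size factors span "
          f"{norm.size_factors.min():.2f}-{norm.size_factors.max():.2f}")


if __name__ == "__main__":
    main()
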