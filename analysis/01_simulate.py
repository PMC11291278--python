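"""Simulate the synthetic multi-ancestry cohort and write it to disk.

Emits VCF genotypes (phased, nested Balding-Nichols, template-block LD),
expression counts generated from the allelic-fold-change model, sample
metadata and the ground-truth tables that later scripts score against.
"""

from common import RESULTS, SIM_CONFIG, SIM_DIR

from divqtl.simulate import simulate_study, write_study


def main():
    study = simulate_study(SIM_CONFIG)
    RESULTS.mkdir(parents=True, exist_ok=True)
    paths = write_study(study, SIM_DIR)
    n_causal = len(study.truth.causal)
    print(f"simulated {study.counts.n_features} genes, "
          f"{study.genotypes.n_variants} variants, "
          f"{len(study.samples.sample_ids)} samples "
          f"({study.samples.table['population'].nunique()} populations, "
          f"{study.samples.table['continental_group'].nunique()} groups)")
    print(f"ground truth: {n_causal} causal variants across "
          f"{study.truth.causal['gene_id'].nunique()} genes")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
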