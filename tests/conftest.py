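import numpy as np
import pytest

from divqtl import simulate


@pytest.fixture(scope="session")
def small_samples():
    """5 groups x 2 populations x 20 samples = 200 samples."""
    cfg = simulate.SimConfig(n_genes=1, populations_per_group=2,
                             samples_per_population=20, seed=11)
    rng = np.random.default_rng(11)
    return simulate.make_sample_table(cfg, rng)


@pytest.fixture(scope="session")
def small_genotypes(small_samples):
    """500 Balding-Nichols variants on the small cohort (phased)."""
    cfg = simulate.SimConfig(n_genes=1, populations_per_group=2,
                             samples_per_population=20, seed=11)
    rng = np.random.default_rng(12)
    gm, af = simulate.simulate_genotypes(cfg, small_samples, 500, rng=rng)
    return gm, af


@pytest.fixture(scope="session")
def small_study():
    """Tiny end-to-end study: 12 genes, 60 variants per window, 150 samples."""
    cfg = simulate.SimConfig(
        n_genes=12, populations_per_group=2, samples_per_population=15,
        variants_per_cis_window=60, causal_per_gene_probs=(0.25, 0.5, 0.25, 0.0),
        seed=21)
    return simulate.simulate_study(cfg, with_splicing=True)
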