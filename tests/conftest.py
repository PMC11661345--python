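import numpy as np
import pandas as pd
import pytest

from popsloci.ld import LDPanel
from popsloci.synthetic_data import Ancestry, SimConfig, simulate_scenario


def tiny_config(**overrides) -> SimConfig:
    """A seconds-scale scenario: 4 chromosomes, 2 ancestries, 2 causal loci."""
    base = dict(
        n_variants=2_000,
        n_genes=40,
        n_chromosomes=4,
        n_features=60,
        n_causal_loci=2,
        ancestries=(Ancestry("EAS", 300, 15_886.0), Ancestry("EUR", 500, 127_626.0)),
        ld_block_size=50,
        causal_min_separation_bp=400_000,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_scenario():
    """Moderate scenario shared by integration-style tests."""
    cfg = SimConfig(
        n_variants=8_000,
        n_genes=80,
        n_chromosomes=4,
        n_features=100,
        n_causal_loci=6,
        ancestries=(Ancestry("EAS", 400, 15_886.0), Ancestry("EUR", 800, 127_626.0)),
        causal_min_separation_bp=800_000,
        seed=1,
    )
    return simulate_scenario(cfg)


def make_panel(genotypes, chrom=1, positions=None, a1="A", a2="G", ancestry="TEST"):
    """LDPanel from a raw genotype matrix, with a minimal variant map."""
    genotypes = np.asarray(genotypes)
    m = genotypes.shape[1]
    if positions is None:
        positions = (np.arange(m) + 1) * 1_000
    variants = pd.DataFrame(
        {
            "CHR": chrom,
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CM": 0.0,
            "POS": positions,
            "A1": a1,
            "A2": a2,
            "BLOCK": 0,
        }
    )
    return LDPanel(ancestry, genotypes, variants)


def correlated_genotypes(rng, n_samples, r_matrix, freq=0.5):
    """Genotypes whose empirical correlation approximates ``r_matrix``.

    Gaussian-copula haplotypes: attenuates r for extreme frequencies, so
    use it only where tests recompute LD empirically from the panel.
    """
    m = r_matrix.shape[0]
    L = np.linalg.cholesky(r_matrix + 1e-9 * np.eye(m))
    thresh = np.quantile(rng.standard_normal(10_000), freq)
    haps = []
    for _ in range(2):
        u = rng.standard_normal((n_samples, m)) @ L.T
        haps.append((u < thresh).astype(np.int8))
    return haps[0] + haps[1]
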