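import numpy as np
import pytest

from sparsetc.genome import (
    GenomeParams,
    LocusMap,
    assign_loci,
    simulate_founder_haplotypes,
)
from sparsetc.trait import TraitArchitecture, sample_trait

SMALL_GENOME = GenomeParams(
    n_chromosomes=2,
    chr_length_bp=5e7,
    chr_length_cM=100.0,
    n_founders=20,
    n_qtn_per_chr=50,
    n_snp_per_chr=50,
)


@pytest.fixture(scope="session")
def small_founders():
    """A 20-founder, 2-chromosome population with QTN/SNP assigned."""
    pop = simulate_founder_haplotypes(SMALL_GENOME, seed=11)
    return assign_loci(pop, SMALL_GENOME, seed=12)


@pytest.fixture(scope="session")
def small_trait(small_founders):
    return sample_trait(
        small_founders, mu_delta=0.5, var_delta=0.2, target_var_A=20.0, seed=13
    )


def toy_map(n_loci: int, chr_length_cM: float = 100.0) -> LocusMap:
    """A single-chromosome locus map with evenly spaced loci."""
    pos = np.linspace(1, chr_length_cM * 1e6 - 1, n_loci).astype(np.int64)
    return LocusMap(
        chrom=np.zeros(n_loci, dtype=np.int16),
        pos_bp=pos,
        pos_cM=pos / 1e6,
        role=np.zeros(n_loci, dtype=np.uint8),
        chr_length_cM=chr_length_cM,
    )


def toy_trait(a: np.ndarray, delta: np.ndarray) -> TraitArchitecture:
    """Trait with handpicked effects (no scaling applied)."""
    a = np.asarray(a, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return TraitArchitecture(
        qtn_index=np.arange(len(a)),
        a=a,
        delta=delta,
        d=delta * np.abs(a),
        mu_delta=float(delta.mean()) if len(delta) else 0.0,
        var_delta=0.0,
        scale_factor=1.0,
    )
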