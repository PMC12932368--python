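"""Founder genome simulation and locus bookkeeping.

A founder population of heterozygous genotypes is simulated per chromosome
with a coalescent model so that the sample carries realistic allele-frequency
spectra and linkage disequilibrium. Only segregating sites are stored; physical
positions matter only through the uniform bp-to-cM map. A random subset of
sites per chromosome is then designated as QTN (trait loci, invisible to the
prediction models) and a disjoint subset as SNP (the marker array).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .rng import child_rng, msprime_seed

__all__ = [
    "ROLE_NEUTRAL",
    "ROLE_QTN",
    "ROLE_SNP",
    "GenomeParams",
    "LocusMap",
    "HaplotypePopulation",
    "InsufficientPolymorphismError",
    "simulate_founder_haplotypes",
    "assign_loci",
    "register_founder_backend",
]

ROLE_NEUTRAL = 0
ROLE_QTN = 1
ROLE_SNP = 2


class InsufficientPolymorphismError(RuntimeError):
    """A chromosome carries fewer segregating sites than requested loci."""


@dataclass(frozen=True)
class GenomeParams:
    """Genome and founder-population settings (defaults mimic maize).

    The recombination rate is derived from the ratio of genetic to physical
    length; with the defaults, 1 cM corresponds to 1 Mb.
    """

    n_chromosomes: int = 10
    chr_length_bp: float = 2e8
    chr_length_cM: float = 200.0
    mutation_rate: float = 1.25e-8
    effective_pop_size: int = 100
    n_founders: int = 80
    n_qtn_per_chr: int = 500
    n_snp_per_chr: int = 500
    backend: str = "coalescent"

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "effective_pop_size", "n_founders"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_qtn_per_chr < 0 or self.n_snp_per_chr < 0:
            raise ValueError("locus counts must be non-negative")
        if min(self.chr_length_bp, self.chr_length_cM, self.mutation_rate) <= 0:
            raise ValueError("lengths and rates must be positive")

    @property
    def recombination_rate(self) -> float:
        """Per-bp per-generation recombination probability."""
        return self.chr_length_cM / 100.0 / self.chr_length_bp

    @property
    def cM_per_bp(self) -> float:
        return self.chr_length_cM / self.chr_length_bp


@dataclass(frozen=True)
class LocusMap:
    """Shared per-locus metadata: chromosome, positions, and role labels.

    Loci are stored concatenated across chromosomes, sorted by (chromosome,
    position), with genetic positions strictly increasing within a chromosome.
    """

    chrom: np.ndarray  # int16 (L,)
    pos_bp: np.ndarray  # int64 (L,)
    pos_cM: np.ndarray  # float64 (L,)
    role: np.ndarray  # uint8 (L,)
    chr_length_cM: float

    def __post_init__(self) -> None:
        L = len(self.chrom)
        if not (len(self.pos_bp) == len(self.pos_cM) == len(self.role) == L):
            raise ValueError("locus arrays must have equal length")

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slice(self, c: int) -> slice:
        lo = int(np.searchsorted(self.chrom, c, side="left"))
        hi = int(np.searchsorted(self.chrom, c, side="right"))
        return slice(lo, hi)

    @property
    def qtn_index(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_QTN)

    @property
    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_SNP)

    def subset(self, idx: np.ndarray) -> "LocusMap":
        return LocusMap(
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            pos_cM=self.pos_cM[idx],
            role=self.role[idx],
            chr_length_cM=self.chr_length_cM,
        )


@dataclass
class HaplotypePopulation:
    """Phased diploid individuals over a shared locus map.

    ``haplotypes`` has shape ``(n_individuals, 2, n_loci)`` with alleles in
    {0, 1}; both haplotypes of an individual cover the same locus set.
    """

    haplotypes: np.ndarray
    loci: LocusMap
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != self.loci.n_loci:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if h.size and h.max() > 1:
            raise ValueError("alleles must be 0/1")
        self.haplotypes = h
        if not self.individual_ids:
            self.individual_ids = [f"F{i:03d}" for i in range(h.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        """Allele-count matrix (n, loci) in {0, 1, 2} at the selected loci."""
        return self.haplotypes[:, 0, idx].astype(np.int8) + self.haplotypes[:, 1, idx]

    def allele_frequencies(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        return self.haplotypes[:, :, idx].mean(axis=(0, 1))

    def drop_neutral(self) -> "HaplotypePopulation":
        """Compact to QTN+SNP loci only (meiosis and genetics are unchanged
        because the genetic map positions of the kept loci are preserved)."""
        keep = np.flatnonzero(self.loci.role != ROLE_NEUTRAL)
        return HaplotypePopulation(
            haplotypes=self.haplotypes[:, :, keep],
            loci=self.loci.subset(keep),
            individual_ids=list(self.individual_ids),
        )


# ---------------------------------------------------------------------------
# founder-LD backends

FounderBackend = Callable[[GenomeParams, int], HaplotypePopulation]
_BACKENDS: dict[str, FounderBackend] = {}


def register_founder_backend(name: str, fn: FounderBackend) -> None:
    """Register an alternative founder-LD generator under ``name``."""
    _BACKENDS[name] = fn


def _coalescent_founders(params: GenomeParams, seed: int) -> HaplotypePopulation:
    import msprime

    chroms, pos_bp = [], []
    haps = []
    for c in range(params.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=params.n_founders,
            population_size=params.effective_pop_size,
            recombination_rate=params.recombination_rate,
            sequence_length=params.chr_length_bp,
            random_seed=msprime_seed(seed, "ancestry", c),
            record_provenance=False,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=params.mutation_rate,
            random_seed=msprime_seed(seed, "mutations", c),
            model=msprime.BinaryMutationModel(),
            record_provenance=False,
        )
        G = mts.genotype_matrix()  # (sites, 2*n) with alleles 0/1
        pos = np.array([s.position for s in mts.sites()])
        freq = G.mean(axis=1)
        seg = (freq > 0) & (freq < 1) & (G.max(axis=1) <= 1)
        # collapse duplicate integer positions to keep the map strictly increasing
        ipos = np.floor(pos[seg]).astype(np.int64)
        _, first = np.unique(ipos, return_index=True)
        G = G[seg][first]
        ipos = ipos[first]
        n_req = params.n_qtn_per_chr + params.n_snp_per_chr
        if G.shape[0] < max(n_req, 1):
            raise InsufficientPolymorphismError(
                f"chromosome {c}: {G.shape[0]} segregating sites < {n_req} requested"
            )
        chroms.append(np.full(G.shape[0], c, dtype=np.int16))
        pos_bp.append(ipos)
        haps.append(G.T.astype(np.uint8))  # (2n, sites)

    chrom = np.concatenate(chroms)
    pos_bp_all = np.concatenate(pos_bp)
    H = np.concatenate(haps, axis=1)  # (2n, L)
    n = params.n_founders
    haplotypes = H.reshape(n, 2, -1)
    loci = LocusMap(
        chrom=chrom,
        pos_bp=pos_bp_all,
        pos_cM=pos_bp_all * params.cM_per_bp,
        role=np.zeros(len(chrom), dtype=np.uint8),
        chr_length_cM=params.chr_length_cM,
    )
    return HaplotypePopulation(haplotypes=haplotypes, loci=loci)


register_founder_backend("coalescent", _coalescent_founders)


def simulate_founder_haplotypes(params: GenomeParams, seed: int) -> HaplotypePopulation:
    """Simulate the heterozygous founder population with LD.

    Deterministic given ``seed``. Raises :class:`InsufficientPolymorphismError`
    if any chromosome segregates at fewer sites than the requested QTN+SNP
    count (retry with a longer genome or higher mutation rate).
    """
    try:
        backend = _BACKENDS[params.backend]
    except KeyError:
        raise ValueError(f"unknown founder backend {params.backend!r}") from None
    return backend(params, int(seed))


def assign_loci(
    pop: HaplotypePopulation, params: GenomeParams, seed: int
) -> HaplotypePopulation:
    """Designate QTN and SNP loci, uniformly without replacement per chromosome.

    The two sets are disjoint within each chromosome; all remaining loci stay
    neutral. Returns a new population sharing the haplotype array.
    """
    rng = child_rng(seed, "assign_loci")
    role = np.zeros(pop.n_loci, dtype=np.uint8)
    n_req = params.n_qtn_per_chr + params.n_snp_per_chr
    for c in range(params.n_chromosomes):
        sl = pop.loci.chrom_slice(c)
        n_avail = sl.stop - sl.start
        if n_avail < n_req:
            raise InsufficientPolymorphismError(
                f"chromosome {c}: {n_avail} sites < {n_req} requested QTN+SNP"
            )
        pick = rng.choice(n_avail, size=n_req, replace=False) + sl.start
        role[pick[: params.n_qtn_per_chr]] = ROLE_QTN
        role[pick[params.n_qtn_per_chr :]] = ROLE_SNP
    loci = replace(pop.loci, role=role)
    return HaplotypePopulation(
        haplotypes=pop.haplotypes, loci=loci, individual_ids=list(pop.individual_ids)
    )
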