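"""Genetic operations of the breeding scheme.

Covers conversion of founders to inbred lines, half-diallel cross sampling,
meiosis (Poisson crossovers on the genetic map, no interference), doubled
haploid (DH) line derivation, initial heterotic pool formation by random
crossing, testcross construction between inbreds, error-variance calibration
to a target broad-sense heritability, and phenotype simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb

import numpy as np

from .genome import HaplotypePopulation, LocusMap
from .rng import child_rng
from .trait import TraitArchitecture

__all__ = [
    "LinePopulation",
    "CrossPlan",
    "TestcrossSet",
    "InitialPools",
    "sample_half_diallel",
    "meiose",
    "recombine",
    "derive_dh_lines",
    "advance_generation",
    "form_initial_pools",
    "make_testcross",
    "calibrate_error_variance",
    "simulate_phenotypes",
]


@dataclass
class LinePopulation:
    """Fully homozygous inbred lines over a shared locus map.

    Because every line is homozygous at every locus, a single haplotype per
    line suffices: ``geno`` is ``(n_lines, n_loci)`` with alleles in {0, 1};
    the diploid dosage is ``2 * geno``.
    """

    geno: np.ndarray
    loci: LocusMap
    pool: str = ""
    cycle: int = 0
    family: np.ndarray | None = None  # cross-of-origin label per line
    parents: np.ndarray | None = None  # (n_lines, 2) parental line indices
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.geno, dtype=np.uint8)
        if g.ndim != 2 or g.shape[1] != self.loci.n_loci:
            raise ValueError("geno must be (n_lines, n_loci)")
        if g.size and g.max() > 1:
            raise ValueError("alleles must be 0/1")
        self.geno = g
        if self.family is None:
            self.family = np.arange(g.shape[0])

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    def qtn_alleles(self, trait: TraitArchitecture) -> np.ndarray:
        return self.geno[:, trait.qtn_index]

    def snp_alleles(self) -> np.ndarray:
        return self.geno[:, self.loci.snp_index]

    def snp_dosages(self) -> np.ndarray:
        """Marker dosages coded 0/2 (homozygous lines carry no heterozygotes)."""
        return 2 * self.snp_alleles().astype(np.int8)

    def allele_frequencies(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        return self.geno[:, idx].mean(axis=0)

    def take(self, idx: np.ndarray) -> "LinePopulation":
        return LinePopulation(
            geno=self.geno[idx],
            loci=self.loci,
            pool=self.pool,
            cycle=self.cycle,
            family=None if self.family is None else self.family[idx],
            parents=None if self.parents is None else self.parents[idx],
            ids=[self.ids[i] for i in np.atleast_1d(idx)] if self.ids else [],
        )


@dataclass(frozen=True)
class CrossPlan:
    """Unordered bi-parental cross pairs (no selfing, no duplicates)."""

    pairs: np.ndarray  # (n_crosses, 2) parent indices, pair[0] < pair[1]

    @property
    def n_crosses(self) -> int:
        return self.pairs.shape[0]


@dataclass
class TestcrossSet:
    """Hybrids of candidate lines with testers, with optional phenotypes."""

    line_idx: np.ndarray
    tester_idx: np.ndarray
    genetic_values: np.ndarray
    phenotypes: np.ndarray | None = None
    error_variance: float | None = None

    @property
    def n_hybrids(self) -> int:
        return len(self.line_idx)


@dataclass
class InitialPools:
    """The two heterotic pools after formation, with their random parents."""

    pool_f: LinePopulation
    pool_m: LinePopulation
    parents_f: np.ndarray  # line indices within pool_f serving as parents
    parents_m: np.ndarray


def sample_half_diallel(n_parents: int, n_crosses: int, seed: int) -> CrossPlan:
    """Sample ``n_crosses`` distinct pairs from the half diallel of
    ``n_parents`` parents, rejecting plans that leave any parent unused.
    """
    total = comb(n_parents, 2)
    if n_crosses > total:
        raise ValueError(f"{n_crosses} crosses exceed the half diallel of {total}")
    if n_crosses < -(-n_parents // 2):
        raise ValueError("too few crosses to use every parent at least once")
    iu = np.triu_indices(n_parents, k=1)
    all_pairs = np.column_stack(iu)
    rng = child_rng(seed, "half_diallel")
    used = np.empty(n_parents, dtype=bool)
    for _ in range(100_000):
        pick = rng.choice(total, size=n_crosses, replace=False)
        pairs = all_pairs[pick]
        used[:] = False
        used[pairs.ravel()] = True
        if used.all():
            return CrossPlan(pairs=pairs)
    raise RuntimeError("could not sample a covering half-diallel plan")


def recombine(
    hapA: np.ndarray, hapB: np.ndarray, loci: LocusMap, rng: np.random.Generator
) -> np.ndarray:
    """Batched meiosis: one gamete per row pair of ``hapA``/``hapB``.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans, crossover positions are uniform on the genetic map, and
    there is no interference; the starting haplotype is random per chromosome.
    """
    hapA = np.atleast_2d(hapA)
    hapB = np.atleast_2d(hapB)
    n = hapA.shape[0]
    gam = np.empty_like(hapA)
    mean_xo = loci.chr_length_cM / 100.0
    for c in loci.chromosomes:
        sl = loci.chrom_slice(int(c))
        pos = loci.pos_cM[sl]
        counts = rng.poisson(mean_xo, size=n)
        starts = rng.integers(0, 2, size=n).astype(np.int64)
        kmax = int(counts.max()) if n else 0
        if kmax == 0:
            par = np.broadcast_to(starts[:, None], (n, len(pos)))
        else:
            # one uniform per potential crossover; each gamete uses its first
            # `count` draws, the rest are pushed off the end of the map. The
            # parental source at a locus flips with every crossover before it.
            U = rng.uniform(0.0, loci.chr_length_cM, size=(n, kmax))
            live = np.arange(kmax)[None, :] < counts[:, None]
            X = np.where(live, U, np.inf)
            par = starts[:, None] + (X[:, :, None] < pos[None, None, :]).sum(axis=1)
        par = par & 1
        gam[:, sl] = np.where(par == 0, hapA[:, sl], hapB[:, sl])
    return gam


def meiose(parent: np.ndarray, loci: LocusMap, seed: int) -> np.ndarray:
    """One gamete from a phased diploid parent of shape ``(2, n_loci)``."""
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2:
        raise ValueError("parent must be a phased diploid of shape (2, n_loci)")
    rng = child_rng(seed, "meiosis")
    return recombine(parent[0][None, :], parent[1][None, :], loci, rng)[0]


def derive_dh_lines(
    f1: np.ndarray, loci: LocusMap, n: int, seed: int
) -> np.ndarray:
    """``n`` doubled-haploid genotypes from a phased F1 ``(2, n_loci)``.

    Each DH line is a single gamete of the F1 doubled, hence exactly
    homozygous; the returned array holds one haplotype per line.
    """
    f1 = np.asarray(f1)
    rng = child_rng(seed, "dh")
    hapA = np.repeat(f1[0][None, :], n, axis=0)
    hapB = np.repeat(f1[1][None, :], n, axis=0)
    return recombine(hapA, hapB, loci, rng)


def advance_generation(
    parents_geno: np.ndarray,
    loci: LocusMap,
    n_crosses: int,
    dh_per_cross: int,
    rng: np.random.Generator,
    pool: str = "",
    cycle: int = 0,
) -> LinePopulation:
    """One generation: half-diallel crosses among the parents, then DH lines.

    Each cross's F1 has the two parental genotypes as its haplotypes (parents
    are inbred), so each DH line is one recombined gamete of that pair.
    """
    n_parents = parents_geno.shape[0]
    plan = sample_half_diallel(n_parents, n_crosses, int(rng.integers(2**31)))
    hapA = np.repeat(parents_geno[plan.pairs[:, 0]], dh_per_cross, axis=0)
    hapB = np.repeat(parents_geno[plan.pairs[:, 1]], dh_per_cross, axis=0)
    geno = recombine(hapA, hapB, loci, rng)
    family = np.repeat(np.arange(n_crosses), dh_per_cross)
    parents = np.repeat(plan.pairs, dh_per_cross, axis=0)
    return LinePopulation(
        geno=geno, loci=loci, pool=pool, cycle=cycle, family=family, parents=parents
    )


def form_initial_pools(
    founders: HaplotypePopulation,
    generations: int = 3,
    seed: int = 0,
    n_parents: int | None = None,
    n_crosses: int = 60,
    dh_per_cross: int = 20,
) -> InitialPools:
    """Split inbred founders into two pools and run random crossing.

    Founders are converted to homozygous lines by doubling one randomly chosen
    haplotype per chromosome, then allocated at random to the female and male
    pools. Each pool independently undergoes ``generations`` rounds of:
    half-diallel crossing among its parents, DH derivation
    (``n_crosses * dh_per_cross`` lines), and random choice of the next
    parents. No trait-based selection occurs (pure drift).
    """
    rng = child_rng(seed, "pool_formation")
    n = founders.n_individuals
    if n % 2:
        raise ValueError("need an even number of founders to split into two pools")
    half = n // 2
    if n_parents is None:
        n_parents = half

    # inbreed founders: one random haplotype per chromosome, doubled
    geno = np.empty((n, founders.n_loci), dtype=np.uint8)
    for c in founders.loci.chromosomes:
        sl = founders.loci.chrom_slice(int(c))
        which = rng.integers(0, 2, size=n)
        geno[:, sl] = founders.haplotypes[np.arange(n), which, sl]

    order = rng.permutation(n)
    pools: list[LinePopulation] = []
    parent_sets: list[np.ndarray] = []
    for name, idx in (("female", order[:half]), ("male", order[half:])):
        lines = LinePopulation(geno=geno[idx], loci=founders.loci, pool=name, cycle=0)
        parents = rng.choice(lines.n_lines, size=n_parents, replace=False)
        for g in range(generations):
            lines = advance_generation(
                lines.geno[parents], founders.loci, n_crosses, dh_per_cross,
                rng, pool=name, cycle=0,
            )
            parents = rng.choice(lines.n_lines, size=n_parents, replace=False)
        pools.append(lines)
        parent_sets.append(parents)
    return InitialPools(
        pool_f=pools[0], pool_m=pools[1],
        parents_f=parent_sets[0], parents_m=parent_sets[1],
    )


def make_testcross(line: np.ndarray, tester: np.ndarray) -> np.ndarray:
    """Hybrid dosage of an inbred line x inbred tester cross.

    Inputs are dosage-coded genotypes in {0, 2}; a dosage of 1 anywhere
    violates the inbred-only contract and raises. The hybrid receives one
    allele from each parent, so its dosage is the mean of the parental ones.
    """
    line = np.asarray(line)
    tester = np.asarray(tester)
    if line.shape != tester.shape:
        raise ValueError("line and tester must cover the same loci")
    for g, who in ((line, "line"), (tester, "tester")):
        if not np.isin(g, (0, 2)).all():
            raise ValueError(f"{who} is not fully homozygous (dosages must be 0 or 2)")
    return (line + tester) // 2


def calibrate_error_variance(
    parents_f: LinePopulation | np.ndarray,
    parents_m: LinePopulation | np.ndarray,
    trait: TraitArchitecture,
    H2: float = 0.3,
) -> float:
    """Error variance giving broad-sense heritability ``H2`` among all
    parent-by-parent hybrids: sigma2_e = sigma2_G (1 - H2) / H2, with sigma2_G
    the genetic variance over the full factorial of the two parent sets.
    """
    from .metrics import hybrid_value_matrix

    if not 0 < H2 < 1:
        raise ValueError("H2 must be in (0, 1)")
    values = hybrid_value_matrix(parents_f, parents_m, trait)
    s2g = float(np.var(values))
    if s2g <= 0:
        raise ValueError("zero genetic variance among parent hybrids")
    return s2g * (1.0 - H2) / H2


def simulate_phenotypes(
    hybrids: TestcrossSet, sigma2_e: float, seed: int
) -> TestcrossSet:
    """Phenotype = genetic value + iid N(0, sigma2_e) error per hybrid."""
    if sigma2_e < 0:
        raise ValueError("error variance must be non-negative")
    rng = child_rng(seed, "phenotypes")
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=hybrids.n_hybrids)
    return replace(
        hybrids,
        phenotypes=hybrids.genetic_values + noise,
        error_variance=float(sigma2_e),
    )
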