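"""Delimited-table and VCF exports of populations, traits and assignments."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breeding import LinePopulation
from .designs import TestcrossAssignment
from .genome import HaplotypePopulation, LocusMap
from .trait import TraitArchitecture

__all__ = [
    "trait_table",
    "assignment_table",
    "marker_effect_table",
    "export_vcf",
]


def trait_table(trait: TraitArchitecture, loci: LocusMap) -> pd.DataFrame:
    """Trait architecture as a 5-column table (chrom, pos, a, delta, d)."""
    idx = trait.qtn_index
    return pd.DataFrame({
        "chrom": loci.chrom[idx],
        "pos": loci.pos_bp[idx],
        "a": trait.a,
        "delta": trait.delta,
        "d": trait.d,
    })


def assignment_table(
    assignment: TestcrossAssignment, cycle: int = 0
) -> pd.DataFrame:
    """Line-to-tester assignment as a tidy table."""
    return pd.DataFrame({
        "line_id": np.arange(assignment.n_lines),
        "tester_id": assignment.tester_of_line,
        "design_name": assignment.design_name,
        "cycle": cycle,
    })


def marker_effect_table(
    effects: np.ndarray, model: str, pool: str, cycle: int = 0
) -> pd.DataFrame:
    """Per-marker effect estimates as a tidy table."""
    return pd.DataFrame({
        "marker_id": np.arange(len(effects)),
        "effect": np.asarray(effects, dtype=float),
        "model": model,
        "pool": pool,
        "cycle": cycle,
    })


def export_vcf(pop: HaplotypePopulation | LinePopulation, path: str) -> None:
    """Write a population's genotypes as a diploid VCF (GT field only).

    Alleles are reported as REF=A / ALT=T placeholders; positions come from
    the bp map. Inbred line populations are written as homozygous diploids.
    """
    import pysam

    loci = pop.loci
    header = pysam.VariantHeader()
    header.add_meta("source", "sparsetc")
    for c in loci.chromosomes:
        sl = loci.chrom_slice(int(c))
        header.contigs.add(str(int(c) + 1), length=int(loci.pos_bp[sl].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    if isinstance(pop, HaplotypePopulation):
        samples = pop.individual_ids
        hap = pop.haplotypes
    else:
        samples = pop.ids or [f"L{i:04d}" for i in range(pop.n_lines)]
        hap = np.repeat(pop.geno[:, None, :], 2, axis=1)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j in range(loci.n_loci):
            rec = vcf.new_record(
                contig=str(int(loci.chrom[j]) + 1),
                start=int(loci.pos_bp[j]),
                alleles=("A", "T"),
            )
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(hap[i, 0, j]), int(hap[i, 1, j]))
                rec.samples[s].phased = True
            vcf.write(rec)
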