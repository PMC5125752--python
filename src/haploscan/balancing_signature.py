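"""Shared-haplotype bipartition signature of balancing selection.

Long-term balancing selection maintains two deep lineages; linked neutral
variants accumulate on each side, so most SNPs in an affected gene split
the strain panel into the same two groups. A gene is a candidate when
more than half of its fully-called SNPs induce one identical strain
bipartition (perfect linkage disequilibrium with the balanced split).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import MISSING, GeneRecord, VariantTable, CLASS_CHEMORECEPTOR
from .window_scan import WindowStat

Bipartition = tuple[tuple[int, ...], tuple[int, ...]]


def snp_partition(row: np.ndarray) -> Bipartition | None:
    """Canonical strain bipartition induced by one genotype row.

    Returns None for rows with any missing call and for monomorphic rows.
    The split is unordered: the side containing strain 0 is listed first,
    so ref/alt labelling cannot matter.
    """
    row = np.asarray(row)
    if np.any(row == MISSING):
        return None
    zeros = tuple(int(i) for i in np.flatnonzero(row == 0))
    ones = tuple(int(i) for i in np.flatnonzero(row == 1))
    if not zeros or not ones:
        return None
    if 0 in zeros:
        return (zeros, ones)
    return (ones, zeros)


@dataclass
class PartitionSignature:
    """A gene's modal strain bipartition and its SNP support."""

    gene: str
    n_snps: int
    best_partition: Bipartition | None
    support: int
    shared_fraction: float

    @property
    def is_candidate(self) -> bool:
        return self.n_snps > 0 and self.shared_fraction > 0.5


def gene_signature(table: VariantTable, gene: GeneRecord) -> PartitionSignature:
    """Modal bipartition over the usable SNPs in a gene span.

    Usable SNPs are fully called and polymorphic. Modal ties break toward
    the more balanced split (larger minor side), then lexicographically.
    A gene with zero usable SNPs gets n_snps = 0 and NaN shared fraction.
    """
    idx = table.site_indices(gene.chrom, gene.start, gene.end)
    groups: dict[Bipartition, int] = {}
    usable = 0
    for i in idx:
        part = snp_partition(table.genotypes[i])
        if part is None:
            continue
        usable += 1
        groups[part] = groups.get(part, 0) + 1
    if usable == 0:
        return PartitionSignature(
            gene=gene.name, n_snps=0, best_partition=None, support=0,
            shared_fraction=math.nan,
        )
    partition, support = None, 0
    best_key: tuple[int, int] | None = None
    for part, count in groups.items():
        key = (count, min(len(part[0]), len(part[1])))
        if (
            best_key is None
            or key > best_key
            or (key == best_key and part < partition)  # lexicographic tie-break
        ):
            best_key, partition, support = key, part, count
    return PartitionSignature(
        gene=gene.name,
        n_snps=usable,
        best_partition=partition,
        support=support,
        shared_fraction=support / usable,
    )


@dataclass
class CandidateGene:
    """A chemoreceptor passing both the window-D and shared-haplotype filters."""

    gene: GeneRecord
    signature: PartitionSignature
    max_window_d: float


def candidate_scan(
    table: VariantTable,
    genes: Sequence[GeneRecord],
    windows: Sequence[WindowStat],
    min_d: float = 1.0,
    min_shared: float = 0.5,
) -> list[CandidateGene]:
    """Chemoreceptors in high-D windows whose SNPs share one bipartition.

    A gene qualifies when it overlaps at least one scored window with
    D > min_d and its shared-haplotype fraction exceeds min_shared.
    """
    if not windows:
        return []
    width = windows[0].width
    d_by_bin = {
        (w.chrom, w.bin_start): w.d for w in windows if w.scored
    }
    out: list[CandidateGene] = []
    for gene in genes:
        if gene.family_class != CLASS_CHEMORECEPTOR:
            continue
        first = (gene.start - 1) // width
        last = (gene.end - 1) // width
        ds = [
            d_by_bin[(gene.chrom, b * width)]
            for b in range(first, last + 1)
            if (gene.chrom, b * width) in d_by_bin
        ]
        if not ds or max(ds) <= min_d:
            continue
        sig = gene_signature(table, gene)
        if sig.n_snps > 0 and sig.shared_fraction > min_shared:
            out.append(CandidateGene(gene=gene, signature=sig, max_window_d=max(ds)))
    return out
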