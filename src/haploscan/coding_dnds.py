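"""Within-species counting dN/dS on the substitutions separating two lineages.

When balancing selection holds two alleles of a gene for long evolutionary
times, linked variation coalesces deep in the past and the SNPs that
distinguish the two haplotype groups behave like substitutions fixed on
two independent lineages. Those substitutions are classified as
synonymous or nonsynonymous against the reference codon, and normalised
by Nei-Gojobori-style potential site counts: each codon position
contributes the fraction of its three possible single-base changes that
are synonymous to S sites and the remainder to N sites, with changes
creating stop codons excluded from both. dN/dS well below 1 indicates
that both maintained alleles remain under purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .balancing_signature import PartitionSignature, snp_partition
from .variant_io import VariantTable

# Standard genetic code, written out so classification does not depend on
# any external translation machinery.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CdsConsistencyError(ValueError):
    """A variant's reference allele disagrees with the transcript sequence."""


@dataclass
class TranscriptCDS:
    """A spliced coding sequence with its genomic exon placement.

    ``exons`` are 1-based inclusive intervals in genomic order; for
    minus-strand transcripts the CDS is the reverse complement of the
    concatenated exonic sequence, so CDS offset 0 is the genomic 3' end.
    """

    transcript_id: str
    gene: str
    chrom: str
    exons: list[tuple[int, int]]
    strand: str
    cds: str
    partial: bool = False

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.cds):
            raise ValueError(
                f"{self.transcript_id}: exon span {exon_len} != CDS length {len(self.cds)}"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.partial and not self.cds.startswith("ATG"):
            self.partial = True

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def genomic_to_cds(self, pos: int) -> int | None:
        """CDS offset (0-based) of a 1-based genomic position, or None."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                fwd = offset + (pos - s)
                if self.strand == "+":
                    return fwd
                return len(self.cds) - 1 - fwd
            offset += e - s + 1
        return None

    def codon(self, codon_index: int) -> str:
        return self.cds[3 * codon_index : 3 * codon_index + 3]


@dataclass
class CodingEffect:
    """Classification of one variant against one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    classification: str
    cds_offset: int | None = None
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None


def classify_variant(
    variant: tuple[str, int, str, str], transcript: TranscriptCDS
) -> CodingEffect:
    """Synonymous/nonsynonymous/noncoding call for one SNV.

    Alleles are complemented for minus-strand transcripts. A reference
    allele that contradicts the transcript sequence raises
    CdsConsistencyError naming the site.
    """
    chrom, pos, ref, alt = variant
    base = CodingEffect(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        transcript_id=transcript.transcript_id, classification=NONCODING,
    )
    if chrom != transcript.chrom:
        return base
    offset = transcript.genomic_to_cds(pos)
    if offset is None:
        return base
    cds_ref = ref.upper() if transcript.strand == "+" else revcomp(ref.upper())
    cds_alt = alt.upper() if transcript.strand == "+" else revcomp(alt.upper())
    if transcript.cds[offset] != cds_ref:
        raise CdsConsistencyError(
            f"{chrom}:{pos} ref {ref!r} maps to CDS base "
            f"{transcript.cds[offset]!r} at offset {offset} of {transcript.transcript_id}"
        )
    ci = offset // 3
    within = offset % 3
    ref_codon = transcript.codon(ci)
    alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
    cls = SYNONYMOUS if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon] else NONSYNONYMOUS
    return CodingEffect(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        transcript_id=transcript.transcript_id, classification=cls,
        cds_offset=offset, codon_index=ci, ref_codon=ref_codon, alt_codon=alt_codon,
    )


def potential_sites(cds: str, permissive: bool = False) -> tuple[float, float]:
    """(N_sites, S_sites) by per-position fractional counting.

    Each codon position contributes syn/3 to S and nonsyn/3 to N over its
    three possible substitutions; substitutions creating stop codons are
    excluded from both, so N + S + excluded = 3 x codon count exactly.
    An internal stop in the reference is an error unless ``permissive``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_sites = 0.0
    s_sites = 0.0
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            if ci < n_codons - 1 and not permissive:
                raise ValueError(f"internal stop codon {codon} at codon index {ci}")
            continue
        aa = GENETIC_CODE[codon]
        for within in range(3):
            for b in "ACGT":
                if b == codon[within]:
                    continue
                mutant = codon[:within] + b + codon[within + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if GENETIC_CODE[mutant] == aa:
                    s_sites += 1 / 3
                else:
                    n_sites += 1 / 3
    return n_sites, s_sites


@dataclass
class DnDsResult:
    """Observed and potential substitution counts and their ratio."""

    gene: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float

    @property
    def dn(self) -> float:
        return self.n_obs / self.n_sites if self.n_sites > 0 else math.nan

    @property
    def ds(self) -> float:
        return self.s_obs / self.s_sites if self.s_sites > 0 else math.nan

    @property
    def ratio(self) -> float:
        """dN/dS; NaN when no synonymous substitutions were observed."""
        if self.s_obs == 0 or not math.isfinite(self.ds) or self.ds == 0:
            return math.nan
        return self.dn / self.ds


def lineage_dnds(
    candidate: PartitionSignature,
    table: VariantTable,
    transcript: TranscriptCDS,
    permissive: bool = False,
) -> DnDsResult:
    """Counting dN/dS over the SNPs supporting the candidate's bipartition.

    Only SNPs inducing exactly the best partition and falling in the CDS
    are counted; each is classified independently against the reference
    codon. dS = 0 leaves the ratio undefined (NaN), never zero.
    """
    if candidate.best_partition is None:
        raise ValueError(f"candidate {candidate.gene} has no best partition")
    n_obs = 0
    s_obs = 0
    lo = min(s for s, _ in transcript.exons)
    hi = max(e for _, e in transcript.exons)
    for i in table.site_indices(transcript.chrom, lo, hi):
        if snp_partition(table.genotypes[i]) != candidate.best_partition:
            continue
        effect = classify_variant(
            (str(table.chrom[i]), int(table.pos[i]), str(table.ref[i]), str(table.alt[i])),
            transcript,
        )
        if effect.classification == SYNONYMOUS:
            s_obs += 1
        elif effect.classification == NONSYNONYMOUS:
            n_obs += 1
    n_sites, s_sites = potential_sites(transcript.cds, permissive=permissive)
    return DnDsResult(
        gene=candidate.gene, n_obs=n_obs, s_obs=s_obs,
        n_sites=n_sites, s_sites=s_sites,
    )


def pairwise_divergence(a: str, b: str) -> tuple[int, int, float]:
    """(mismatches, compared length, fraction) for two aligned sequences.

    Positions where either sequence has a gap ('-') are excluded from both
    counts. Unequal lengths are an error; no alignment is attempted.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    compared = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            diff += 1
    frac = diff / compared if compared else math.nan
    return diff, compared, frac
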