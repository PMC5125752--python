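"""Readers, writers and the core data model for the scan pipeline.

The pipeline treats wild isolates as a haploid panel: the strains are
highly inbred selfers, so homozygous diploid calls collapse to a single
haploid allele and residual heterozygous calls are treated as missing
data rather than as half-alleles.

Standard formats are read through established libraries (cyvcf2 for VCF,
gffutils for GFF3, Biopython for FASTA); this module only normalises
their records into the in-memory types the statistics operate on.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: genotype code for a missing haploid call
MISSING: int = -1

NUCLEOTIDES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantTable:
    """Biallelic SNV sites x haploid strain genotypes.

    Attributes
    ----------
    strain_ids : list of str
        Ordered sample names.
    chrom, pos, ref, alt : ndarray
        Per-site chromosome id, 1-based position, reference and
        alternate allele (single nucleotides).
    genotypes : ndarray of int8, shape (n_sites, n_strains)
        0 = reference, 1 = alternate, -1 = missing.
    """

    strain_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.pos), len(self.strain_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.pos)} sites x {len(self.strain_ids)} strains"
            )
        self._sort_and_check()

    def _sort_and_check(self) -> None:
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.genotypes = self.genotypes[order]
        keys = list(zip(self.chrom, self.pos))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chromosome, position) sites in table")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def sites(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chrom, (int(p) for p in self.pos), self.ref, self.alt))

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def site_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with 1-based position in [start, end] on chrom."""
        mask = (self.chrom.astype(str) == chrom) & (self.pos >= start) & (self.pos <= end)
        return np.flatnonzero(mask)

    @classmethod
    def empty(cls, strain_ids: Sequence[str]) -> "VariantTable":
        return cls(
            strain_ids=list(strain_ids),
            chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            ref=np.empty(0, dtype=object),
            alt=np.empty(0, dtype=object),
            genotypes=np.empty((0, len(strain_ids)), dtype=np.int8),
        )

    @classmethod
    def from_records(
        cls,
        strain_ids: Sequence[str],
        records: Iterable[tuple[str, int, str, str, Sequence[int]]],
    ) -> "VariantTable":
        """Build a table from (chrom, pos, ref, alt, genotype row) tuples."""
        rows = list(records)
        if not rows:
            return cls.empty(strain_ids)
        chrom, pos, ref, alt, gts = zip(*rows)
        return cls(
            strain_ids=list(strain_ids),
            chrom=np.array(chrom, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            ref=np.array(ref, dtype=object),
            alt=np.array(alt, dtype=object),
            genotypes=np.array(gts, dtype=np.int8),
        )


@dataclass(frozen=True)
class GeneRecord:
    """A named, classed, stranded genomic interval (1-based inclusive)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    family_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")


# Chemoreceptor families are recognised by the gene-name token before the
# first hyphen. The default family lists mirror the C. elegans literature
# (serpentine-receptor families sra..srz/str; F-box, C-type lectin and
# nuclear hormone receptor families as fast-evolving controls; classical
# essential-phenotype genes as a purifying-selection proxy) and are fully
# user-overridable.
CHEMORECEPTOR_PREFIXES = (
    "sra", "srab", "srb", "srbc", "srd", "sre", "srg", "srh", "sri", "srj",
    "srm", "srn", "srr", "srsx", "srt", "sru", "srv", "srw", "srx", "srxa",
    "srz", "str",
)
FAST_EVOLVING_PREFIXES = ("fbxa", "fbxb", "fbxc", "clec", "nhr")
PURIFYING_PROXY_PREFIXES = ("unc", "bli", "let", "dpy", "rol", "egl")

CLASS_CHEMORECEPTOR = "chemoreceptor"
CLASS_FAST_EVOLVING = "fast_evolving"
CLASS_PURIFYING = "purifying_proxy"
CLASS_OTHER = "other"
GENE_CLASSES = (CLASS_CHEMORECEPTOR, CLASS_FAST_EVOLVING, CLASS_PURIFYING, CLASS_OTHER)


@dataclass(frozen=True)
class GenePrefixConfig:
    """Gene-name prefix lists used to assign family classes."""

    chemoreceptor: tuple[str, ...] = CHEMORECEPTOR_PREFIXES
    fast_evolving: tuple[str, ...] = FAST_EVOLVING_PREFIXES
    purifying_proxy: tuple[str, ...] = PURIFYING_PROXY_PREFIXES


DEFAULT_PREFIXES = GenePrefixConfig()


def classify_gene_name(name: str, config: GenePrefixConfig = DEFAULT_PREFIXES) -> str:
    """Assign a family class from the token before the first hyphen.

    Matching is case-insensitive and exact on the token, so ``srx-43``
    is a chemoreceptor while ``srxl-1`` is not.
    """
    token = name.split("-", 1)[0].lower()
    if token in {p.lower() for p in config.chemoreceptor}:
        return CLASS_CHEMORECEPTOR
    if token in {p.lower() for p in config.fast_evolving}:
        return CLASS_FAST_EVOLVING
    if token in {p.lower() for p in config.purifying_proxy}:
        return CLASS_PURIFYING
    return CLASS_OTHER


def read_vcf(path: str, max_missing_fraction: float = 0.05) -> VariantTable:
    """Read a multi-sample VCF into a haploid VariantTable.

    Only biallelic single-nucleotide variants are retained.  Diploid
    homozygous calls collapse to haploid (0/0 -> 0, 1/1 -> 1);
    heterozygous and uncalled genotypes become missing.  Sites whose
    missing fraction exceeds ``max_missing_fraction`` are dropped.
    """
    from cyvcf2 import VCF

    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path!r} contains zero samples")

    records = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types)
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 2] = 1
        missing_frac = float(np.mean(row == MISSING))
        if missing_frac > max_missing_fraction:
            continue
        records.append((var.CHROM, var.POS, var.REF, var.ALT[0], row))
    vcf.close()
    return VariantTable.from_records(samples, records)


def read_gff3_genes(
    path: str, prefix_config: GenePrefixConfig = DEFAULT_PREFIXES
) -> list[GeneRecord]:
    """Read gene features from a GFF3 file and classify them by name prefix.

    Features of type ``gene`` without a ``Name`` attribute are skipped with
    a logged warning.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        names = feat.attributes.get("Name") or feat.attributes.get("name")
        if not names:
            logger.warning("gene feature at %s:%d-%d has no Name attribute; skipped",
                           feat.seqid, feat.start, feat.end)
            continue
        name = names[0]
        genes.append(
            GeneRecord(
                name=name,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                family_class=classify_gene_name(name, prefix_config),
            )
        )
    return genes


SCAN_TSV_HEADER = ("CHROM", "BIN_START", "N_SNPS", "TajimaD")


def write_scan_tsv(windows: Iterable, path: str) -> None:
    """Write window statistics in the vcftools --TajimaD column dialect.

    Columns: CHROM, BIN_START (0-based window start), N_SNPS, TajimaD
    (4 decimal places; undefined D written as ``nan``).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCAN_TSV_HEADER)
        for w in windows:
            d = "nan" if w.d is None or math.isnan(w.d) else f"{w.d:.4f}"
            writer.writerow([w.chrom, w.bin_start, w.s, d])


def read_scan_tsv(path: str) -> list:
    """Read a scan TSV written by :func:`write_scan_tsv` back into WindowStats.

    Only the fields carried by the TSV are recovered (pi and theta_w are
    set to NaN).
    """
    from .window_scan import WindowStat

    out: list[WindowStat] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != SCAN_TSV_HEADER:
            raise ValueError(f"unexpected scan TSV header {header!r} in {path!r}")
        for row in reader:
            chrom, bin_start, s, d = row
            out.append(
                WindowStat(
                    chrom=chrom,
                    bin_start=int(bin_start),
                    width=0,
                    s=int(s),
                    pi=math.nan,
                    theta_w=math.nan,
                    d=float(d),
                )
            )
    return out


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 with diploid GTs.

    Haploid genotypes are emitted as homozygous diploid calls
    (0 -> ``0/0``, 1 -> ``1/1``, missing -> ``./.``) so the file
    round-trips through :func:`read_vcf` exactly.
    """
    gt_str = {0: "0/0", 1: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in table.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.strain_ids) + "\n")
        for i in range(table.n_sites):
            calls = "\t".join(gt_str[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{table.chrom[i]}\t{int(table.pos[i])}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_gff3(genes: Iterable[GeneRecord], path: str) -> None:
    """Write GeneRecords as a minimal GFF3 of gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            fh.write(
                f"{g.chrom}\thaploscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene{i:06d};Name={g.name}\n"
            )


def write_cds_fasta(transcripts: Iterable, path: str) -> None:
    """Write transcript CDS sequences with genomic placement in the header.

    Header convention (key=value tokens after the transcript id)::

        >T1 gene=srx-101 chrom=I strand=+ exons=5001-5900

    ``exons`` is a comma-separated list of 1-based inclusive intervals in
    genomic order.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for tx in transcripts:
        exons = ",".join(f"{s}-{e}" for s, e in tx.exons)
        desc = f"gene={tx.gene} chrom={tx.chrom} strand={tx.strand} exons={exons}"
        records.append(SeqRecord(Seq(tx.cds), id=tx.transcript_id, description=desc))
    SeqIO.write(records, path, "fasta")


def read_cds_fasta(path: str) -> list:
    """Read CDS FASTA written by :func:`write_cds_fasta` into TranscriptCDS."""
    from Bio import SeqIO

    from .coding_dnds import TranscriptCDS

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        missing = {"gene", "chrom", "strand", "exons"} - fields.keys()
        if missing:
            raise ValueError(
                f"FASTA header for {rec.id!r} lacks key=value tokens: {sorted(missing)}"
            )
        exons = []
        for span in fields["exons"].split(","):
            s, e = span.split("-")
            exons.append((int(s), int(e)))
        out.append(
            TranscriptCDS(
                transcript_id=rec.id,
                gene=fields["gene"],
                chrom=fields["chrom"],
                exons=exons,
                strand=fields["strand"],
                cds=str(rec.seq).upper(),
            )
        )
    return out
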