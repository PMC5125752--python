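"""Gene-family enrichment in the tails of the windowed D distribution.

A window "contains" a gene of a class when the gene's span overlaps the
window at all; a gene straddling a bin boundary annotates every bin it
touches. Enrichment compares the fraction of tail windows containing a
class against the genome-wide fraction over scored windows (S >= 1),
reported as a fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .variant_io import GENE_CLASSES, GeneRecord
from .window_scan import WindowStat

logger = logging.getLogger(__name__)


@dataclass
class BinAnnotation:
    """Gene content of one scan window, by family class."""

    chrom: str
    bin_start: int
    genes: dict[str, list[str]] = field(default_factory=dict)

    def names(self, family_class: str) -> list[str]:
        return self.genes.get(family_class, [])

    def contains(self, family_class: str) -> bool:
        return bool(self.genes.get(family_class))


@dataclass
class ClassEnrichment:
    """Tail-vs-genome enrichment of one gene class at one threshold."""

    family_class: str
    side: str  # "low" (D < threshold) or "high" (D > threshold)
    threshold: float
    n_tail_bins: int
    n_tail_bins_with_class: int
    tail_fraction: float
    genome_fraction: float
    fold: float


def annotate_bins(
    windows: Sequence[WindowStat], genes: Iterable[GeneRecord]
) -> dict[tuple[str, int], BinAnnotation]:
    """Map every scan window to the class-labelled genes overlapping it.

    A gene with 1-based span [s, e] overlaps the half-open windows
    covering genomic offsets [s-1, e). Genes on chromosomes absent from
    the scan are skipped with a warning.
    """
    if not windows:
        return {}
    width = windows[0].width
    keys = {(w.chrom, w.bin_start) for w in windows}
    chroms = {w.chrom for w in windows}
    annotations = {
        (w.chrom, w.bin_start): BinAnnotation(chrom=w.chrom, bin_start=w.bin_start)
        for w in windows
    }
    for gene in genes:
        if gene.chrom not in chroms:
            logger.warning(
                "gene %s on chromosome %s absent from scan; skipped", gene.name, gene.chrom
            )
            continue
        first = (gene.start - 1) // width
        last = (gene.end - 1) // width
        for b in range(first, last + 1):
            key = (gene.chrom, b * width)
            if key in keys:
                annotations[key].genes.setdefault(gene.family_class, []).append(gene.name)
    return annotations


def _scored(windows: Sequence[WindowStat]) -> list[WindowStat]:
    return [w for w in windows if w.scored]


def tail_enrichment(
    windows: Sequence[WindowStat],
    annotations: dict[tuple[str, int], BinAnnotation],
    family_class: str,
    side: str,
    threshold: float,
) -> ClassEnrichment:
    """Enrichment of a gene class in one D-distribution tail.

    The genome-wide denominator is the scored windows (S >= 1, finite D).
    Raises ValueError when no window anywhere contains the class, since
    the fold is then undefined for every threshold.
    """
    if side not in ("low", "high"):
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scored = _scored(windows)
    if not scored:
        raise ValueError("no scored windows: cannot compute enrichment")

    def has_class(w: WindowStat) -> bool:
        ann = annotations.get((w.chrom, w.bin_start))
        return ann is not None and ann.contains(family_class)

    n_genome_with = sum(1 for w in scored if has_class(w))
    if n_genome_with == 0:
        raise ValueError(
            f"no scored window contains a {family_class} gene; fold undefined"
        )
    genome_fraction = n_genome_with / len(scored)

    if side == "low":
        tail = [w for w in scored if w.d < threshold]
    else:
        tail = [w for w in scored if w.d > threshold]
    n_tail = len(tail)
    n_tail_with = sum(1 for w in tail if has_class(w))
    if n_tail == 0:
        tail_fraction = math.nan
        fold = math.nan
    else:
        tail_fraction = n_tail_with / n_tail
        fold = tail_fraction / genome_fraction
    return ClassEnrichment(
        family_class=family_class,
        side=side,
        threshold=threshold,
        n_tail_bins=n_tail,
        n_tail_bins_with_class=n_tail_with,
        tail_fraction=tail_fraction,
        genome_fraction=genome_fraction,
        fold=fold,
    )


def enrichment_report(
    windows: Sequence[WindowStat],
    annotations: dict[tuple[str, int], BinAnnotation],
    thresholds: Sequence[tuple[str, float]] = (("low", -2.5), ("high", 2.5)),
    classes: Sequence[str] = GENE_CLASSES[:3],
) -> pd.DataFrame:
    """Per-threshold, per-class enrichment table.

    Classes with no genes anywhere are reported with NaN fractions and a
    ``defined`` flag of False rather than raising.
    """
    rows = []
    for side, threshold in thresholds:
        for cls in classes:
            try:
                e = tail_enrichment(windows, annotations, cls, side, threshold)
                rows.append(
                    {
                        "class": cls, "side": side, "threshold": threshold,
                        "n_tail_bins": e.n_tail_bins,
                        "n_tail_bins_with_class": e.n_tail_bins_with_class,
                        "tail_fraction": e.tail_fraction,
                        "genome_fraction": e.genome_fraction,
                        "fold": e.fold, "defined": math.isfinite(e.fold),
                    }
                )
            except ValueError:
                rows.append(
                    {
                        "class": cls, "side": side, "threshold": threshold,
                        "n_tail_bins": 0, "n_tail_bins_with_class": 0,
                        "tail_fraction": math.nan, "genome_fraction": math.nan,
                        "fold": math.nan, "defined": False,
                    }
                )
    return pd.DataFrame(rows)


# Plot priority when a bin holds several classes: chemoreceptor wins, then
# fast-evolving, then the purifying proxy, then everything else.
_PRIORITY = GENE_CLASSES[:3]


def histogram_data(
    windows: Sequence[WindowStat],
    annotations: dict[tuple[str, int], BinAnnotation],
    bar_width: float = 0.25,
) -> pd.DataFrame:
    """Counts of scored bins per D interval, split by dominant gene class."""
    rows: dict[tuple[float, str], int] = {}
    for w in _scored(windows):
        bar = math.floor(w.d / bar_width) * bar_width
        ann = annotations.get((w.chrom, w.bin_start))
        label = "other"
        if ann is not None:
            for cls in _PRIORITY:
                if ann.contains(cls):
                    label = cls
                    break
        rows[(bar, label)] = rows.get((bar, label), 0) + 1
    df = pd.DataFrame(
        [{"d_bar": k[0], "class": k[1], "n_bins": v} for k, v in sorted(rows.items())]
    )
    return df
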