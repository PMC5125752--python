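"""Windowed diversity statistics: S, pi, Watterson's theta and Tajima's D.

Tajima's D compares two estimators of the scaled mutation rate: the mean
pairwise difference pi and Watterson's S/a1. An excess of rare variants
(selective sweep, population expansion) drives D negative; an excess of
intermediate-frequency variants (balancing selection) drives it positive.
Windows are fixed-width, 0-based half-open intervals anchored at
coordinate 0 of each chromosome, matching the conventional vcftools
binning; a 1-based site at position p falls in bin floor((p-1)/width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .variant_io import MISSING, VariantTable

DEFAULT_WINDOW = 5000


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of the D statistic's variance normalisation."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def harmonic_constants(n: int) -> TajimaConstants:
    """Compute the variance-normalisation constants for a panel of n haploids.

    Raises
    ------
    ValueError
        If n < 2 (the statistic is undefined for fewer than two sequences).
    """
    if int(n) != n or n < 2:
        raise ValueError(f"panel size must be an integer >= 2, got {n!r}")
    n = int(n)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass
class WindowStat:
    """Per-window summary: segregating sites, pi, theta_W and Tajima's D.

    ``d`` is NaN when undefined (S = 0 or zero variance term).
    """

    chrom: str
    bin_start: int
    width: int
    s: int
    pi: float
    theta_w: float
    d: float

    @property
    def scored(self) -> bool:
        return self.s > 0 and not math.isnan(self.d)


def site_frequencies(
    table: VariantTable, indices: np.ndarray, require_complete: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele count j and called-allele count m for each site index.

    In strict mode (``require_complete``) sites with any missing call get
    m = 0 and drop out of all downstream sums.
    """
    gt = table.genotypes[indices]
    j = (gt == 1).sum(axis=1)
    m = (gt != MISSING).sum(axis=1)
    if require_complete:
        incomplete = m < table.n_strains
        j = np.where(incomplete, 0, j)
        m = np.where(incomplete, 0, m)
    return j.astype(np.int64), m.astype(np.int64)


def window_diversity(
    table: VariantTable,
    chrom: str,
    bin_start: int,
    width: int = DEFAULT_WINDOW,
    require_complete: bool = False,
) -> tuple[int, float]:
    """(S, pi) over the half-open window [bin_start, bin_start + width).

    A site is segregating when its alternate allele count j among the m
    called strains satisfies 0 < j < m; its contribution to pi is
    2 j (m - j) / (m (m - 1)), the per-site mean pairwise difference over
    called alleles.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    idx = table.site_indices(chrom, bin_start + 1, bin_start + width)
    return _diversity_from_counts(*site_frequencies(table, idx, require_complete))


def _diversity_from_counts(j: np.ndarray, m: np.ndarray) -> tuple[int, float]:
    seg = (j > 0) & (j < m)
    s = int(seg.sum())
    if s == 0:
        return 0, 0.0
    js, ms = j[seg], m[seg]
    pi = float(np.sum(2.0 * js * (ms - js) / (ms * (ms - 1.0))))
    return s, pi


def tajimas_d(s: int, pi: float, constants: TajimaConstants) -> float:
    """Tajima's D from window totals; NaN when undefined.

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1)).
    """
    if s < 0:
        raise ValueError("segregating-site count cannot be negative")
    if s == 0:
        return math.nan
    var = constants.e1 * s + constants.e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi - s / constants.a1) / math.sqrt(var)


def scan_genome(
    table: VariantTable,
    width: int = DEFAULT_WINDOW,
    chrom_lengths: Mapping[str, int] | None = None,
    require_complete: bool = False,
) -> list[WindowStat]:
    """Per-window statistics across the whole table.

    With ``chrom_lengths`` supplied, every window from 0 to the chromosome
    end is reported (including S = 0 windows); otherwise only windows
    overlapping at least one site are emitted. Constants always use the
    full panel size, while per-site pi uses called alleles only.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    constants = harmonic_constants(table.n_strains) if table.n_strains >= 2 else None
    out: list[WindowStat] = []

    chroms = table.chromosomes()
    if chrom_lengths is not None:
        chroms = list(chrom_lengths)
    for chrom in chroms:
        idx = np.flatnonzero(table.chrom.astype(str) == chrom)
        bins = ((table.pos[idx] - 1) // width).astype(np.int64)
        if chrom_lengths is not None:
            n_windows = max(1, -(-int(chrom_lengths[chrom]) // width))
            window_ids: Sequence[int] = range(n_windows)
        else:
            window_ids = sorted(set(int(b) for b in bins))
        by_bin: dict[int, list[int]] = {}
        for site_i, b in zip(idx, bins):
            by_bin.setdefault(int(b), []).append(int(site_i))
        for b in window_ids:
            sites = np.array(by_bin.get(b, []), dtype=np.int64)
            j, m = site_frequencies(table, sites, require_complete)
            s, pi = _diversity_from_counts(j, m)
            theta_w = s / constants.a1 if constants else math.nan
            d = tajimas_d(s, pi, constants) if constants else math.nan
            out.append(
                WindowStat(
                    chrom=chrom, bin_start=b * width, width=width,
                    s=s, pi=pi, theta_w=theta_w, d=d,
                )
            )
    return out
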