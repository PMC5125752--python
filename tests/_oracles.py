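"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, third-party translation tables) and shares no code with the
implementation paths it checks.
"""

import itertools
import math

import numpy as np


def naive_tajimas_d(matrix):
    """Tajima's D from a complete 0/1 sites x strains matrix.

    pi by explicit pairwise haplotype comparison, constants by direct
    harmonic summation. Returns NaN when undefined.
    """
    matrix = np.asarray(matrix)
    n_sites, n = matrix.shape
    s = 0
    for row in matrix:
        j = int(row.sum())
        if 0 < j < n:
            s += 1
    if s == 0:
        return math.nan
    total_diff = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        n_pairs += 1
        total_diff += int(np.sum(matrix[:, i] != matrix[:, j]))
    pi = total_diff / n_pairs

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi - s / a1) / math.sqrt(var)


def exhaustive_best_partition_support(matrix):
    """Max, over all 2^(n-1)-1 strain bipartitions, of SNPs matching it.

    A SNP matches a bipartition when its carrier set equals one side.
    Only complete polymorphic rows are considered; returns (support,
    n_usable_snps).
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[1]
    usable = []
    for row in matrix:
        if np.any(row < 0):
            continue
        j = int(row.sum())
        if 0 < j < n:
            usable.append(frozenset(int(i) for i in np.flatnonzero(row == 1)))
    best = 0
    all_strains = frozenset(range(n))
    # every bipartition is identified by its side not containing strain 0
    for r in range(1, n):
        for side in itertools.combinations(range(1, n), r):
            side_set = frozenset(side)
            other = all_strains - side_set
            support = sum(1 for cs in usable if cs == side_set or cs == other)
            best = max(best, support)
    return best, len(usable)


def biopython_codon_class(ref_codon, alt_codon):
    """synonymous/nonsynonymous via Biopython's translation machinery."""
    from Bio.Seq import Seq

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"
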