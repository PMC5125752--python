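"""Synthetic panels, annotations and coding genes with known ground truth.

The generator emulates the structure of a wild-isolate resequencing
study: a haploid multi-strain SNV panel over fixed-width windows, a toy
gene annotation with family-class labels, and coding sequences carrying
planted synonymous/nonsynonymous between-lineage substitutions.

Three per-window models are provided:

``neutral``
    A standard n-sample coalescent (exponentially distributed waiting
    times, uniformly random pair merges) with infinite-sites mutations at
    rate theta/2 per unit branch length, so E[S] = theta * a1(n).
``sweep``
    The same genealogy with every external (leaf) branch stretched by a
    singleton-excess factor, approximating the star-like trees left by a
    recent selective sweep; factor 1 recovers the neutral model exactly.
``balanced``
    Two fixed strain groups separated by k diagnostic sites (all inducing
    one shared bipartition) on top of independent within-group neutral
    variation — the deep two-lineage structure balancing selection
    maintains.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coding_dnds import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    NONSYNONYMOUS,
    SYNONYMOUS,
    TranscriptCDS,
)
from .variant_io import (
    CLASS_CHEMORECEPTOR,
    CLASS_FAST_EVOLVING,
    CLASS_OTHER,
    CLASS_PURIFYING,
    GeneRecord,
    VariantTable,
)
from .window_scan import WindowStat

_NUC = np.array(list("ACGT"))

#: default gene-name prefixes used for generated annotations, one per class
CLASS_NAME_PREFIX = {
    CLASS_CHEMORECEPTOR: "srx",
    CLASS_FAST_EVOLVING: "clec",
    CLASS_PURIFYING: "dpy",
    CLASS_OTHER: "gen",
}


@dataclass(frozen=True)
class SimPanelConfig:
    """Configuration for the per-window haplotype panel generators."""

    model: str = "neutral"  # neutral | sweep | balanced
    n: int = 20
    theta: float = 10.0
    n_windows: int = 1
    width: int = 5000
    chrom: str = "I"
    seed: int = 0
    # sweep model
    singleton_excess: float = 10.0
    # balanced model
    n1: int = 10
    n2: int = 10
    k_inter: int = 50
    theta_within: float = 0.0

    def __post_init__(self) -> None:
        if self.n_windows <= 0 or self.width <= 0:
            raise ValueError("n_windows and width must be positive")
        if self.theta < 0 or self.theta_within < 0 or self.k_inter < 0:
            raise ValueError("rates and site counts must be non-negative")
        if self.singleton_excess <= 0:
            raise ValueError("singleton excess factor must be positive")


def _strain_ids(n: int) -> list[str]:
    return [f"WI{i:03d}" for i in range(n)]


def _coalescent_carrier_sets(
    n: int, theta: float, rng: np.random.Generator, external_scale: float = 1.0
) -> list[frozenset[int]]:
    """Derived-allele carrier set for each infinite-sites mutation.

    Simulates one genealogy by random pair merges with Exp(k(k-1)/2)
    waiting times; each surviving lineage accrues branch length on which
    mutations fall as Poisson(theta/2 * length). External branches are
    scaled by ``external_scale``.
    """
    if n < 2 or theta == 0:
        return []
    active: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    sites: list[frozenset[int]] = []
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(2.0 / (k * (k - 1)))
        for leaf_set in active:
            length = t * (external_scale if len(leaf_set) == 1 else 1.0)
            for _ in range(rng.poisson(theta / 2.0 * length)):
                sites.append(leaf_set)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        merged = active[i] | active[j]
        active = [ls for idx, ls in enumerate(active) if idx not in (i, j)]
        active.append(merged)
    return sites


def _window_records(
    carrier_sets: Sequence[frozenset[int]],
    n: int,
    window_index: int,
    width: int,
    chrom: str,
    rng: np.random.Generator,
) -> list[tuple[str, int, str, str, np.ndarray]]:
    """Place mutations at distinct positions in the window with random alleles."""
    s = len(carrier_sets)
    if s == 0:
        return []
    if s > width:
        raise ValueError(f"more sites ({s}) than positions in a {width} bp window")
    offsets = np.sort(rng.choice(width, size=s, replace=False))
    records = []
    for offset, carriers in zip(offsets, carrier_sets):
        pos = window_index * width + int(offset) + 1
        ref_i = rng.integers(4)
        alt_i = (ref_i + 1 + rng.integers(3)) % 4
        row = np.zeros(n, dtype=np.int8)
        row[list(carriers)] = 1
        records.append((chrom, pos, str(_NUC[ref_i]), str(_NUC[alt_i]), row))
    return records


def simulate_neutral(config: SimPanelConfig) -> VariantTable:
    """Neutral coalescent panel; one independent genealogy per window."""
    rng = np.random.default_rng(config.seed)
    records = []
    for w in range(config.n_windows):
        sets = _coalescent_carrier_sets(config.n, config.theta, rng)
        records.extend(
            _window_records(sets, config.n, w, config.width, config.chrom, rng)
        )
    return VariantTable.from_records(_strain_ids(config.n), records)


def simulate_sweep(config: SimPanelConfig) -> VariantTable:
    """Sweep-like panel: external branches stretched, singleton excess."""
    rng = np.random.default_rng(config.seed)
    records = []
    for w in range(config.n_windows):
        sets = _coalescent_carrier_sets(
            config.n, config.theta, rng, external_scale=config.singleton_excess
        )
        records.extend(
            _window_records(sets, config.n, w, config.width, config.chrom, rng)
        )
    return VariantTable.from_records(_strain_ids(config.n), records)


def simulate_balanced(config: SimPanelConfig) -> VariantTable:
    """Two-lineage panel: k shared-bipartition sites plus within-group noise.

    Strains 0..n1-1 form lineage A, the rest lineage B; the k diagnostic
    sites carry the derived allele in lineage B.
    """
    if config.n1 < 2 or config.n2 < 2:
        raise ValueError("balanced model needs at least two strains per lineage")
    n = config.n1 + config.n2
    rng = np.random.default_rng(config.seed)
    records = []
    for w in range(config.n_windows):
        sets: list[frozenset[int]] = [
            frozenset(range(config.n1, n)) for _ in range(config.k_inter)
        ]
        for group_offset, group_n in ((0, config.n1), (config.n1, config.n2)):
            for carriers in _coalescent_carrier_sets(group_n, config.theta_within, rng):
                sets.append(frozenset(i + group_offset for i in carriers))
        records.extend(_window_records(sets, n, w, config.width, config.chrom, rng))
    return VariantTable.from_records(_strain_ids(n), records)


def balanced_config_for_proportion(
    p: float, k_inter: int = 14, n1: int = 10, n2: int = 10, **kwargs
) -> SimPanelConfig:
    """Balanced config whose expected inter-lineage SNP proportion is p.

    Within-group theta is set so the expected within-group site count is
    k_inter * (1 - p) / p split over the two groups.
    """
    if not 0 < p <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    expected_within = k_inter * (1 - p) / p
    a1_1 = sum(1.0 / i for i in range(1, n1))
    a1_2 = sum(1.0 / i for i in range(1, n2))
    theta_w = expected_within / (a1_1 + a1_2) if expected_within else 0.0
    return SimPanelConfig(
        model="balanced", n1=n1, n2=n2, k_inter=k_inter, theta_within=theta_w, **kwargs
    )


def simulate_panel(config: SimPanelConfig) -> VariantTable:
    """Dispatch on ``config.model``."""
    fn = {
        "neutral": simulate_neutral,
        "sweep": simulate_sweep,
        "balanced": simulate_balanced,
    }.get(config.model)
    if fn is None:
        raise ValueError(f"unknown panel model {config.model!r}")
    return fn(config)


# ---------------------------------------------------------------------------
# annotation generator


@dataclass(frozen=True)
class SimGenomeConfig:
    """Configuration for placing class-labelled toy genes onto a scan."""

    genes_per_class: int = 40
    enrichment: float = 1.0  # chemoreceptor propensity for extreme windows
    extreme_threshold: float = 2.0  # |D| beyond this marks a window "extreme"
    gene_length: tuple[int, int] = (600, 2400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment <= 0:
            raise ValueError("enrichment factor must be positive")
        if self.genes_per_class < 0:
            raise ValueError("genes_per_class must be non-negative")


def simulate_genome_annotation(
    config: SimGenomeConfig, windows: Sequence[WindowStat]
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Place class-labelled genes into scan windows with known enrichment.

    Chemoreceptor-class genes choose among scored windows with weight
    ``enrichment`` for extreme windows (|D| > threshold) and 1 elsewhere;
    the other classes place uniformly. Each gene falls wholly inside one
    window. The returned truth table records, per class, the exact
    expected fraction of extreme and non-extreme windows containing the
    class and the expected bin-level enrichment fold they imply.
    """
    rng = np.random.default_rng(config.seed)
    scored = [w for w in windows if w.scored]
    if not scored:
        raise ValueError("annotation generator needs at least one scored window")
    width = scored[0].width
    extreme = np.array([abs(w.d) > config.extreme_threshold for w in scored])
    t_count = int(extreme.sum())
    w_count = len(scored)

    genes: list[GeneRecord] = []
    truth_rows = []
    for cls in (CLASS_CHEMORECEPTOR, CLASS_FAST_EVOLVING, CLASS_PURIFYING, CLASS_OTHER):
        e = config.enrichment if cls == CLASS_CHEMORECEPTOR else 1.0
        weights = np.where(extreme, e, 1.0)
        probs = weights / weights.sum()
        g = config.genes_per_class
        lo, hi = config.gene_length
        hi = min(hi, width)
        for i in range(g):
            win = scored[int(rng.choice(w_count, p=probs))]
            length = int(rng.integers(lo, hi + 1))
            start = win.bin_start + 1 + int(rng.integers(0, width - length + 1))
            name = f"{CLASS_NAME_PREFIX[cls]}-{i + 1}"
            genes.append(
                GeneRecord(
                    name=name, chrom=win.chrom, start=start,
                    end=start + length - 1, strand="+", family_class=cls,
                )
            )
        denom = e * t_count + (w_count - t_count)
        q_ext = e / denom
        q_oth = 1.0 / denom
        p_tail = 1.0 - (1.0 - q_ext) ** g
        p_other = 1.0 - (1.0 - q_oth) ** g
        genome_fraction = (t_count * p_tail + (w_count - t_count) * p_other) / w_count
        truth_rows.append(
            {
                "class": cls,
                "enrichment_factor": e,
                "n_genes": g,
                "n_extreme_windows": t_count,
                "n_scored_windows": w_count,
                "p_extreme_with_class": p_tail,
                "p_other_with_class": p_other,
                "expected_genome_fraction": genome_fraction,
                "expected_fold": p_tail / genome_fraction if genome_fraction else math.nan,
            }
        )
    return genes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# coding-gene generator


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    if n_codons < 2:
        raise ValueError("CDS needs at least 2 codons")
    codons = ["ATG"]
    codons += [SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 1)]
    return "".join(codons)


def _single_base_changes(cds: str) -> list[tuple[int, str, str]]:
    """(offset, alt base, classification) for every stop-free change."""
    out = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        aa = GENETIC_CODE[codon]
        for within in range(3):
            for b in "ACGT":
                if b == codon[within]:
                    continue
                mutant = codon[:within] + b + codon[within + 1 :]
                if mutant in STOP_CODONS:
                    continue
                cls = SYNONYMOUS if GENETIC_CODE[mutant] == aa else NONSYNONYMOUS
                out.append((3 * ci + within, b, cls))
    return out


def simulate_coding_gene(
    n_plant: int,
    s_plant: int,
    n_codons: int = 300,
    seed: int = 0,
    n1: int = 8,
    n2: int = 8,
    chrom: str = "I",
    gene_start: int = 1001,
    gene_name: str = "srx-900",
) -> tuple[TranscriptCDS, VariantTable, dict]:
    """A stop-free random CDS with planted inter-lineage substitutions.

    ``n_plant`` nonsynonymous and ``s_plant`` synonymous changes are
    placed at distinct CDS offsets and emitted as SNVs fixed between two
    strain lineages (all inducing one bipartition). The truth dict
    records every planted offset and class.
    """
    rng = np.random.default_rng(seed)
    cds = _random_cds(n_codons, rng)
    candidates = _single_base_changes(cds)
    rng.shuffle(candidates)

    used_offsets: set[int] = set()
    planted: list[tuple[int, str, str]] = []
    for want_cls, want_n in ((NONSYNONYMOUS, n_plant), (SYNONYMOUS, s_plant)):
        got = 0
        for offset, alt, cls in candidates:
            if got == want_n:
                break
            if cls != want_cls or offset in used_offsets:
                continue
            used_offsets.add(offset)
            planted.append((offset, alt, cls))
            got += 1
        if got < want_n:
            raise ValueError(
                f"cannot plant {want_n} {want_cls} changes in {n_codons} codons; "
                "increase the CDS length"
            )

    transcript = TranscriptCDS(
        transcript_id=f"{gene_name}.t1",
        gene=gene_name,
        chrom=chrom,
        exons=[(gene_start, gene_start + len(cds) - 1)],
        strand="+",
        cds=cds,
    )
    n = n1 + n2
    records = []
    for offset, alt, _cls in sorted(planted):
        row = np.zeros(n, dtype=np.int8)
        row[n1:] = 1
        records.append((chrom, gene_start + offset, cds[offset], alt, row))
    table = VariantTable.from_records(_strain_ids(n), records)
    truth = {
        "n_planted": n_plant,
        "s_planted": s_plant,
        "planted": sorted(planted),
        "lineage_split": (tuple(range(n1)), tuple(range(n1, n))),
    }
    return transcript, table, truth


# ---------------------------------------------------------------------------
# whole-study generator


@dataclass(frozen=True)
class StudyConfig:
    """A full synthetic study: mixed windows, genes, and coding candidates.

    Window counts and rates set the mixture of neutral background,
    sweep-like troughs and balanced two-lineage peaks; coding windows
    each host one chemoreceptor gene whose inter-lineage substitutions
    are planted with known synonymous/nonsynonymous counts.
    """

    n_strains: int = 20
    width: int = 5000
    n_neutral: int = 120
    n_sweep: int = 15
    n_balanced: int = 15
    n_coding: int = 10
    theta: float = 10.0
    singleton_excess: float = 10.0
    k_inter: int = 40
    theta_within: float = 1.0
    cds_codons: int = 300
    flank_inter_sites: int = 15
    n_plant_range: tuple[int, int] = (0, 10)
    s_plant_range: tuple[int, int] = (5, 25)
    genes_per_class: int = 30
    chrom: str = "I"
    seed: int = 0

    @property
    def n_windows(self) -> int:
        return self.n_neutral + self.n_sweep + self.n_balanced + self.n_coding

    @property
    def chrom_length(self) -> int:
        return self.n_windows * self.width


@dataclass
class StudyData:
    """Everything one synthetic study run produces, with ground truth."""

    config: StudyConfig
    table: VariantTable
    genes: list[GeneRecord]
    transcripts: list[TranscriptCDS]
    window_models: list[str]
    coding_truth: pd.DataFrame
    annotation_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_study(config: StudyConfig) -> StudyData:
    """Assemble a mixed synthetic chromosome with full ground truth.

    Balanced and coding windows share one fixed strain bipartition (the
    two deep lineages run genome-wide, as in a long-balanced region);
    neutral and sweep windows draw independent genealogies. Coding
    windows carry a chemoreceptor gene with planted CDS substitutions
    plus flanking inter-lineage sites, so they score high D, pass the
    shared-haplotype filter and have known dN/dS counts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    if n < 4 or n % 2:
        raise ValueError("study generator needs an even panel of >= 4 strains")
    n1 = n // 2
    models = (
        ["neutral"] * config.n_neutral
        + ["sweep"] * config.n_sweep
        + ["balanced"] * config.n_balanced
        + ["coding"] * config.n_coding
    )
    rng.shuffle(models)

    records: list = []
    genes: list[GeneRecord] = []
    transcripts: list[TranscriptCDS] = []
    coding_rows = []
    coding_idx = 0
    for w, model in enumerate(models):
        if model == "neutral":
            sets = _coalescent_carrier_sets(n, config.theta, rng)
        elif model == "sweep":
            sets = _coalescent_carrier_sets(
                n, config.theta, rng, external_scale=config.singleton_excess
            )
        elif model == "balanced":
            sets = [frozenset(range(n1, n)) for _ in range(config.k_inter)]
            for off, gn in ((0, n1), (n1, n - n1)):
                for carriers in _coalescent_carrier_sets(gn, config.theta_within, rng):
                    sets.append(frozenset(i + off for i in carriers))
        else:  # coding
            coding_idx += 1
            name = f"srx-{100 + coding_idx}"
            n_plant = int(rng.integers(config.n_plant_range[0], config.n_plant_range[1] + 1))
            s_plant = int(rng.integers(config.s_plant_range[0], config.s_plant_range[1] + 1))
            gene_start = w * config.width + 501
            tx, gene_table, truth = simulate_coding_gene(
                n_plant, s_plant, config.cds_codons,
                seed=int(rng.integers(2**31)), n1=n1, n2=n - n1,
                chrom=config.chrom, gene_start=gene_start, gene_name=name,
            )
            transcripts.append(tx)
            gene_end = gene_start + len(tx.cds) - 1
            genes.append(
                GeneRecord(
                    name=name, chrom=config.chrom, start=gene_start, end=gene_end,
                    strand="+", family_class=CLASS_CHEMORECEPTOR,
                )
            )
            for site_chrom, pos, ref, alt, row in zip(
                gene_table.chrom, gene_table.pos, gene_table.ref,
                gene_table.alt, gene_table.genotypes,
            ):
                records.append((str(site_chrom), int(pos), str(ref), str(alt), row))
            # flanking inter-lineage sites outside the gene keep window D high
            flank_positions = rng.choice(
                np.concatenate(
                    [
                        np.arange(w * config.width + 1, gene_start),
                        np.arange(gene_end + 1, (w + 1) * config.width + 1),
                    ]
                ),
                size=config.flank_inter_sites,
                replace=False,
            )
            for pos in sorted(int(p) for p in flank_positions):
                ref_i = rng.integers(4)
                alt_i = (ref_i + 1 + rng.integers(3)) % 4
                row = np.zeros(n, dtype=np.int8)
                row[n1:] = 1
                records.append(
                    (config.chrom, pos, str(_NUC[ref_i]), str(_NUC[alt_i]), row)
                )
            coding_rows.append(
                {
                    "gene": name, "window": w, "n_planted": n_plant,
                    "s_planted": s_plant, "cds_len": len(tx.cds),
                }
            )
            continue
        records.extend(
            _window_records(sets, n, w, config.width, config.chrom, rng)
        )

    table = VariantTable.from_records(_strain_ids(n), records)
    # background genes of the three control classes plus extra chemoreceptors,
    # placed uniformly over windows so class fractions are realistic
    for cls in (CLASS_FAST_EVOLVING, CLASS_PURIFYING, CLASS_OTHER, CLASS_CHEMORECEPTOR):
        for i in range(config.genes_per_class):
            w = int(rng.integers(config.n_windows))
            length = int(rng.integers(600, min(2400, config.width) + 1))
            start = w * config.width + 1 + int(rng.integers(0, config.width - length + 1))
            genes.append(
                GeneRecord(
                    name=f"{CLASS_NAME_PREFIX[cls]}-{1000 + i}",
                    chrom=config.chrom, start=start, end=start + length - 1,
                    strand="+", family_class=cls,
                )
            )
    return StudyData(
        config=config,
        table=table,
        genes=genes,
        transcripts=transcripts,
        window_models=models,
        coding_truth=pd.DataFrame(coding_rows),
    )
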