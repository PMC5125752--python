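"""End-to-end orchestration: scan -> enrich -> signature -> dnds -> report.

A run is fully described by a RunConfig; the manifest written alongside
the outputs carries the package version, the seed and a hash of the
serialized config, so identical configs reproduce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .balancing_signature import candidate_scan
from .coding_dnds import lineage_dnds
from .gene_classes import annotate_bins, enrichment_report
from .synthetic_data import StudyConfig, simulate_study
from .variant_io import (
    read_cds_fasta,
    read_gff3_genes,
    read_vcf,
    write_cds_fasta,
    write_gff3,
    write_scan_tsv,
    write_vcf,
)
from .window_scan import scan_genome

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration, detected before any compute."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    Either the three input paths are given, or ``simulate`` is set and a
    synthetic study is generated in their place.
    """

    vcf: str | None = None
    gff3: str | None = None
    cds_fasta: str | None = None
    simulate: bool = False
    study: StudyConfig = field(default_factory=StudyConfig)
    window_width: int = 5000
    max_missing_fraction: float = 0.05
    tail_low: float = -2.5
    tail_high: float = 2.5
    candidate_min_d: float = 1.0
    min_shared_fraction: float = 0.5
    low_dnds_cutoff: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.min_shared_fraction <= 1.0:
            raise ConfigError(
                f"min_shared_fraction must lie in [0, 1], got {self.min_shared_fraction}"
            )
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigError("max_missing_fraction must lie in [0, 1]")
        if self.window_width <= 0:
            raise ConfigError("window_width must be positive")
        if self.tail_low >= self.tail_high:
            raise ConfigError("tail_low must be below tail_high")
        if not self.simulate and not (self.vcf and self.gff3):
            raise ConfigError("either set simulate=True or provide vcf and gff3 paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Writes scan.tsv, enrichment.tsv, candidates.tsv, dnds.tsv,
    summary.json and manifest.json (plus the generated inputs when
    simulating). Returns the summary dict.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)

    chrom_lengths = None
    if config.simulate:
        stage = "simulate"
        try:
            study = dataclasses.replace(
                config.study, seed=config.seed, width=config.window_width
            )
            data = simulate_study(study)
            table, genes, transcripts = data.table, data.genes, data.transcripts
            chrom_lengths = {study.chrom: study.chrom_length}
            write_vcf(table, os.path.join(outdir, "panel.vcf"))
            write_gff3(genes, os.path.join(outdir, "genes.gff3"))
            write_cds_fasta(transcripts, os.path.join(outdir, "cds.fasta"))
            data.coding_truth.to_csv(
                os.path.join(outdir, "coding_truth.tsv"), sep="\t", index=False
            )
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
    else:
        stage = "ingest"
        try:
            table = read_vcf(config.vcf, config.max_missing_fraction)
            genes = read_gff3_genes(config.gff3)
            transcripts = read_cds_fasta(config.cds_fasta) if config.cds_fasta else []
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc

    try:
        stage = "scan"
        windows = scan_genome(table, config.window_width, chrom_lengths)
        write_scan_tsv(windows, os.path.join(outdir, "scan.tsv"))

        stage = "enrich"
        annotations = annotate_bins(windows, genes)
        report = enrichment_report(
            windows,
            annotations,
            thresholds=(("low", config.tail_low), ("high", config.tail_high)),
        )
        report.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)

        stage = "signature"
        candidates = candidate_scan(
            table, genes, windows,
            min_d=config.candidate_min_d, min_shared=config.min_shared_fraction,
        )
        cand_df = pd.DataFrame(
            [
                {
                    "gene": c.gene.name, "chrom": c.gene.chrom,
                    "start": c.gene.start, "end": c.gene.end,
                    "n_snps": c.signature.n_snps, "support": c.signature.support,
                    "shared_fraction": round(c.signature.shared_fraction, 6),
                    "max_window_d": round(c.max_window_d, 4),
                }
                for c in candidates
            ],
            columns=[
                "gene", "chrom", "start", "end", "n_snps", "support",
                "shared_fraction", "max_window_d",
            ],
        )
        cand_df.to_csv(os.path.join(outdir, "candidates.tsv"), sep="\t", index=False)

        stage = "dnds"
        tx_by_gene: dict[str, list] = {}
        for tx in transcripts:
            tx_by_gene.setdefault(tx.gene, []).append(tx)
        dnds_rows = []
        for c in candidates:
            txs = tx_by_gene.get(c.gene.name)
            if not txs:
                continue
            tx = max(txs, key=lambda t: len(t.cds))  # longest CDS by default
            res = lineage_dnds(c.signature, table, tx)
            dnds_rows.append(
                {
                    "gene": res.gene, "transcript": tx.transcript_id,
                    "n_obs": res.n_obs, "s_obs": res.s_obs,
                    "N_sites": round(res.n_sites, 4), "S_sites": round(res.s_sites, 4),
                    "dN": round(res.dn, 6), "dS": round(res.ds, 6),
                    "dnds": round(res.ratio, 6) if math.isfinite(res.ratio) else "nan",
                }
            )
        dnds_df = pd.DataFrame(
            dnds_rows,
            columns=[
                "gene", "transcript", "n_obs", "s_obs", "N_sites", "S_sites",
                "dN", "dS", "dnds",
            ],
        )
        dnds_df.to_csv(os.path.join(outdir, "dnds.tsv"), sep="\t", index=False)

        stage = "report"
        scored = [w for w in windows if w.scored]
        defined = [
            r for r in dnds_rows if isinstance(r["dnds"], float) and math.isfinite(r["dnds"])
        ]
        low = [r for r in defined if r["dnds"] < config.low_dnds_cutoff]
        summary = {
            "n_windows": len(windows),
            "n_scored_windows": len(scored),
            "n_tail_low": sum(1 for w in scored if w.d < config.tail_low),
            "n_tail_high": sum(1 for w in scored if w.d > config.tail_high),
            "n_candidates": len(candidates),
            "n_candidates_with_dnds": len(dnds_rows),
            "n_dnds_defined": len(defined),
            "n_dnds_undefined": len(dnds_rows) - len(defined),
            "fraction_low_dnds": (len(low) / len(defined)) if defined else None,
        }
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "package": "haploscan",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc
    return summary
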