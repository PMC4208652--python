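"""End-to-end orchestration: scan -> classify -> enrich, with file reports.

A run consumes a genome FASTA and a gene table, scans the configured
upstream window of every gene under a criteria preset, joins islands to
genes, and writes an islands BED, a per-gene TSV and an aggregate JSON
(zone partition, window percentages, enrichment rows).  Configs are flat
``key = value`` text mirrored by CLI flags; identical config and inputs
give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from cpgprom import genome_io
from cpgprom.core import CpgPromError, EmptyWindowError, GeneModel
from cpgprom.enrichment_stats import enrichment_report
from cpgprom.island_scanner import (
    IslandCriteria,
    relaxed_criteria,
    scan_islands,
    stringent_criteria,
)
from cpgprom.promoter_analysis import (
    DISTAL_BP,
    MID_BP,
    PROXIMAL_BP,
    IslandCall,
    concordance_proximal,
    make_call,
    summarize_genes,
    summary_table,
)

logger = logging.getLogger("cpgprom")

PRESETS = {"stringent": stringent_criteria, "relaxed": relaxed_criteria}


@dataclass
class PipelineConfig:
    fasta: str = ""
    gene_table: str = ""
    out_prefix: str = "cpgprom_run"
    preset: str = "stringent"
    near_offset: int = 0
    far_offset: int = DISTAL_BP
    proximal_bp: int = PROXIMAL_BP
    mid_bp: int = MID_BP
    baselines: List[Tuple[str, float]] = field(default_factory=list)
    seed: int = 0
    overlap_promotes: bool = True
    criteria_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.near_offset < self.far_offset):
            raise ValueError("offsets must satisfy 0 <= near < far")
        if not (self.proximal_bp < self.mid_bp <= self.far_offset):
            raise ValueError("zone edges must be ascending and within the window")

    def criteria(self) -> IslandCriteria:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown criteria preset {self.preset!r}")
        base = PRESETS[self.preset]()
        return replace(base, **self.criteria_overrides) if self.criteria_overrides else base


def load_config(path: str) -> PipelineConfig:
    """Parse a flat key=value config file (``#`` comments, blank lines ok)."""
    cfg = PipelineConfig()
    baselines: List[Tuple[str, float]] = []
    overrides: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise CpgPromError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("baseline."):
            baselines.append((key.split(".", 1)[1], float(value)))
        elif key.startswith("criteria."):
            field_name = key.split(".", 1)[1]
            overrides[field_name] = (
                value.lower() == "true"
                if field_name.endswith("strict")
                else type(getattr(stringent_criteria(), field_name))(float(value))
            )
        elif key in ("near_offset", "far_offset", "proximal_bp", "mid_bp", "seed"):
            setattr(cfg, key, int(value))
        elif key == "overlap_promotes":
            cfg.overlap_promotes = value.lower() == "true"
        elif key in ("fasta", "gene_table", "out_prefix", "preset"):
            setattr(cfg, key, value)
        else:
            raise CpgPromError(f"{path}:{lineno}: unknown config key {key!r}")
    cfg.baselines = baselines
    cfg.criteria_overrides = overrides
    cfg.__post_init__()
    return cfg


def scan_gene_set(
    genome, genes: Sequence[GeneModel], config: PipelineConfig
) -> List[IslandCall]:
    """Scan each gene's upstream window and join islands back to the gene."""
    criteria = config.criteria()
    calls: List[IslandCall] = []
    for gene in genes:
        try:
            window, interval = genome_io.extract_upstream_window(
                gene, config.near_offset, config.far_offset, genome
            )
        except EmptyWindowError:
            logger.debug("gene %s: empty upstream window, skipped", gene.gene_id)
            continue
        for island in scan_islands(window, criteria, origin=interval):
            calls.append(
                make_call(island, gene, overlap_promotes=config.overlap_promotes)
            )
        logger.debug("gene %s: scanned %d nt", gene.gene_id, interval.length())
    return calls


def run_pipeline(config: PipelineConfig) -> dict:
    """Full run; returns the aggregate block and writes the report files."""
    try:
        genome = genome_io.read_fasta(config.fasta)
    except (OSError, CpgPromError) as exc:
        raise CpgPromError(f"genome_io: cannot read FASTA {config.fasta!r}: {exc}") from exc
    try:
        genes = genome_io.read_gene_table(config.gene_table)
    except (OSError, CpgPromError) as exc:
        raise CpgPromError(
            f"genome_io: cannot read gene table {config.gene_table!r}: {exc}"
        ) from exc
    logger.info(
        "run: %d genes, preset=%s, window=[%d, %d), seed=%d",
        len(genes),
        config.preset,
        config.near_offset,
        config.far_offset,
        config.seed,
    )
    calls = scan_gene_set(genome, genes, config)
    summary = summarize_genes(calls, genes)
    report = enrichment_report(summary, config.baselines)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    genome_io.write_bed(calls, f"{prefix}.islands.bed")
    summary_table(calls, genes).to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    aggregate = {
        "n_genes": summary.n_genes,
        "n_islands": len(calls),
        "n_genes_proximal": summary.n_genes_proximal,
        "n_genes_mid_only": summary.n_genes_mid_only,
        "n_genes_distal_only": summary.n_genes_distal_only,
        "n_genes_none": summary.n_genes_none,
        "proximal_percent": summary.percent_within("proximal"),
        "mid_window_percent": summary.percent_within("mid"),
        "distal_window_percent": summary.percent_within("distal"),
        "enrichment": report.to_dict(orient="records"),
        "preset": config.preset,
        "seed": config.seed,
    }
    with open(f"{prefix}.aggregate.json", "w") as fh:
        json.dump(aggregate, fh, indent=2)
        fh.write("\n")
    logger.info(
        "run: %d islands; gene partition %d/%d/%d/%d",
        len(calls),
        summary.n_genes_proximal,
        summary.n_genes_mid_only,
        summary.n_genes_distal_only,
        summary.n_genes_none,
    )
    return aggregate


def compare_criteria(config: PipelineConfig) -> dict:
    """Run both presets and report per-gene agreement on proximal islands."""
    genome = genome_io.read_fasta(config.fasta)
    genes = genome_io.read_gene_table(config.gene_table)
    results = {}
    for preset in ("stringent", "relaxed"):
        cfg = replace(config, preset=preset, criteria_overrides={})
        results[preset] = scan_gene_set(genome, genes, cfg)
    concordance = concordance_proximal(results["stringent"], results["relaxed"], genes)
    prox = {
        preset: {c.gene_id for c in calls if c.zone == "proximal"}
        for preset, calls in results.items()
    }
    per_gene = [
        {
            "gene": g.gene_id,
            "stringent_proximal": g.gene_id in prox["stringent"],
            "relaxed_proximal": g.gene_id in prox["relaxed"],
            "agree": (g.gene_id in prox["stringent"]) == (g.gene_id in prox["relaxed"]),
        }
        for g in genes
    ]
    out = {"proximal_concordance": concordance, "per_gene": per_gene}
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.concordance.json", "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    return out


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
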