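"""Join islands to genes: TSS distance, overlap, zone and gene-level summaries.

The distance of an island to a TSS is measured from the TSS to the island
boundary that lies farther upstream in gene orientation (the island's 5'
boundary), floored at 0 for islands entirely downstream.  Zones bin that
distance: proximal (<= 2000 nt), mid (2000-4000 nt) and distal
(4000-10000 nt), each closed on its far edge.  By default an island that
physically overlaps the TSS is classified proximal regardless of where its
upstream boundary falls; pass ``overlap_promotes=False`` to bin strictly by
distance (the counting convention behind published window tallies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

from cpgprom.core import CpgPromError, GeneModel
from cpgprom.island_scanner import CpGIsland

ZONES = ("proximal", "mid", "distal", "none")
_ZONE_RANK = {z: i for i, z in enumerate(ZONES)}

PROXIMAL_BP = 2000
MID_BP = 4000
DISTAL_BP = 10000


class ChromosomeMismatchError(CpgPromError):
    pass


@dataclass(frozen=True)
class IslandCall:
    """An island joined to a gene."""

    gene_id: str
    island: CpGIsland
    distance_to_tss: int
    overlaps_tss: bool
    zone: str


@dataclass
class GeneIslandSummary:
    """Gene-level zone assignment and the four-way gene partition."""

    gene_zones: Dict[str, str] = field(default_factory=dict)
    islands_per_zone: Dict[str, int] = field(
        default_factory=lambda: {z: 0 for z in ZONES}
    )
    n_genes_proximal: int = 0
    n_genes_mid_only: int = 0
    n_genes_distal_only: int = 0
    n_genes_none: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_zones)

    def percent_within(self, zone: str) -> float:
        """Percent of genes whose best island is in `zone` or nearer, 1 decimal."""
        cum = 0
        for z in ZONES[: _ZONE_RANK[zone] + 1]:
            cum += sum(1 for v in self.gene_zones.values() if v == z)
        return round(100.0 * cum / self.n_genes, 1) if self.n_genes else 0.0


def distance_to_tss(island: CpGIsland, gene: GeneModel) -> int:
    """Distance from the TSS to the island's upstream (5') boundary, floored at 0."""
    if island.interval.chrom != gene.chrom:
        raise ChromosomeMismatchError(
            f"island on {island.interval.chrom!r} vs gene {gene.gene_id!r} "
            f"on {gene.chrom!r}"
        )
    if gene.strand == "+":
        return max(0, gene.tss - island.interval.start)
    return max(0, (island.interval.end - 1) - gene.tss)


def overlaps_tss(island: CpGIsland, gene: GeneModel) -> bool:
    """True iff the TSS base lies inside the island interval."""
    if island.interval.chrom != gene.chrom:
        raise ChromosomeMismatchError(
            f"island on {island.interval.chrom!r} vs gene {gene.gene_id!r} "
            f"on {gene.chrom!r}"
        )
    return island.interval.contains(gene.tss)


def classify_zone(
    distance: int,
    overlaps: bool,
    *,
    proximal_bp: int = PROXIMAL_BP,
    mid_bp: int = MID_BP,
    distal_bp: int = DISTAL_BP,
    overlap_promotes: bool = True,
) -> str:
    if overlap_promotes and overlaps:
        return "proximal"
    if distance <= proximal_bp:
        return "proximal"
    if distance <= mid_bp:
        return "mid"
    if distance <= distal_bp:
        return "distal"
    return "none"


def make_call(
    island: CpGIsland, gene: GeneModel, *, overlap_promotes: bool = True
) -> IslandCall:
    dist = distance_to_tss(island, gene)
    over = overlaps_tss(island, gene)
    return IslandCall(
        gene_id=gene.gene_id,
        island=island,
        distance_to_tss=dist,
        overlaps_tss=over,
        zone=classify_zone(dist, over, overlap_promotes=overlap_promotes),
    )


def summarize_genes(
    calls: Iterable[IslandCall], genes: Sequence[GeneModel]
) -> GeneIslandSummary:
    """Assign each gene its best (most proximal) zone and tally the partition.

    Island multiplicity is counted per zone but a gene contributes once, by
    its best island; genes with no calls (or only out-of-range calls) land
    in the "none" class.  The four gene counts partition the gene set.
    """
    known = {g.gene_id for g in genes}
    summary = GeneIslandSummary()
    best: Dict[str, str] = {g.gene_id: "none" for g in genes}
    for call in calls:
        if call.gene_id not in known:
            raise KeyError(f"call references unknown gene {call.gene_id!r}")
        summary.islands_per_zone[call.zone] += 1
        if _ZONE_RANK[call.zone] < _ZONE_RANK[best[call.gene_id]]:
            best[call.gene_id] = call.zone
    summary.gene_zones = best
    summary.n_genes_proximal = sum(1 for z in best.values() if z == "proximal")
    summary.n_genes_mid_only = sum(1 for z in best.values() if z == "mid")
    summary.n_genes_distal_only = sum(1 for z in best.values() if z == "distal")
    summary.n_genes_none = sum(1 for z in best.values() if z == "none")
    return summary


def concordance_proximal(
    calls_a: Iterable[IslandCall],
    calls_b: Iterable[IslandCall],
    genes: Sequence[GeneModel],
) -> float:
    """Fraction of genes on which two call sets agree about a proximal island."""
    if not genes:
        return 1.0
    prox_a = {c.gene_id for c in calls_a if c.zone == "proximal"}
    prox_b = {c.gene_id for c in calls_b if c.zone == "proximal"}
    unknown = (prox_a | prox_b) - {g.gene_id for g in genes}
    if unknown:
        raise KeyError(f"calls reference genes outside the gene set: {sorted(unknown)}")
    agree = sum(1 for g in genes if (g.gene_id in prox_a) == (g.gene_id in prox_b))
    return agree / len(genes)


def summary_table(calls: Iterable[IslandCall], genes: Sequence[GeneModel]):
    """Per-gene report rows (gene, zone, n_islands, min_distance, overlaps_tss)."""
    import pandas as pd

    calls = list(calls)
    summary = summarize_genes(calls, genes)
    by_gene: Mapping[str, List[IslandCall]] = {g.gene_id: [] for g in genes}
    for c in calls:
        by_gene[c.gene_id].append(c)
    rows = []
    for g in genes:
        gcalls = by_gene[g.gene_id]
        rows.append(
            {
                "gene": g.gene_id,
                "zone": summary.gene_zones[g.gene_id],
                "n_islands": len(gcalls),
                "min_distance": min((c.distance_to_tss for c in gcalls), default=-1),
                "overlaps_tss": any(c.overlaps_tss for c in gcalls),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "zone", "n_islands", "min_distance", "overlaps_tss"])
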