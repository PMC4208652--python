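"""Curated table of 87 height-associated genes and their promoter CpG islands.

The packaged data transcribe a published survey of promoter CpG islands in
the genes most strongly associated with adult human height across four
GWAS cohorts.  Per gene: RefSeq accession, chromosome, 1-based TSS,
citation flags for the four source studies, housekeeping status,
methylation-regulated / methylation-regulator annotations, and a flag for
the five genes with no recorded methylation evidence.  Per island: %G+C,
observed/expected CpG, length, printed 5'/3' coordinates, distance
upstream of the TSS, a TSS-overlap flag and a far-window (4-10 kb) flag.

Printed distances and flags are authoritative.  Several coordinate cells
in the source table are typographically corrupt; rows are flagged by
:func:`validate_fixture`, never silently corrected.

Aggregate counts that the source prints without per-gene detail are kept
as documented module constants rather than fabricated per-gene flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Tuple

import pandas as pd

from cpgprom.core import CpgPromError
from cpgprom.promoter_analysis import DISTAL_BP, MID_BP, PROXIMAL_BP

#: Genes carrying a promoter DNA-hypermethylation module (Polycomb-marked
#: bivalent chromatin), printed only as an aggregate; the per-gene list is
#: in unavailable supplementary material.
HYPERMETHYLATION_MODULE_GENES = 42

#: Fraction of control (H3K4Me3-marked) genes carrying such modules.
CONTROL_HYPERMETHYLATION_FRACTION = 0.015

#: The source prints 23/87 genes (26.4%) found by more than one study; a
#: naive recount of the citation flags of the main table gives 22.  Both
#: are reported by :func:`multi_study_counts`; equality is not asserted.
PRINTED_MULTI_STUDY_COUNT = 23

STUDY_CODES = ("G2008", "L2008", "W2008", "C2009")
REPLICATION_STUDY = "C2009"

N_GENES = 87


class FixtureIntegrityError(CpgPromError):
    """Packaged fixture data failed an integrity or curation check."""


@dataclass(frozen=True)
class FixtureIsland:
    """One curated island row (printed values, 1-based coordinates)."""

    five_prime: int
    three_prime: int
    gc_percent: float
    obs_exp: float
    length: int
    distance_printed: int
    overlaps_tss_flag: bool
    far_flag: bool
    provenance: str = "printed"

    @property
    def row_consistent(self) -> bool:
        """Printed length within +-1 of the coordinate span (the source mixes
        inclusive and exclusive length conventions)."""
        return abs((abs(self.three_prime - self.five_prime) + 1) - self.length) <= 1

    def distance_consistent(self, tss: int) -> bool:
        """Printed distance reproducible from the TSS and either printed
        coordinate (+-1), under any boundary convention."""
        candidates = {
            abs(tss - self.five_prime),
            abs(tss - self.three_prime),
        }
        return any(abs(c - self.distance_printed) <= 1 for c in candidates)


@dataclass(frozen=True)
class FixtureGene:
    """One curated gene row with its islands and annotation flags."""

    gene_id: str
    refseq: str
    chrom: str
    tss_printed: int
    islands: Tuple[FixtureIsland, ...]
    studies: Tuple[str, ...]
    housekeeping: bool
    methylation_regulated: bool
    methylation_regulator: bool
    no_methylation_evidence: bool

    @property
    def min_distance(self) -> Optional[int]:
        if not self.islands:
            return None
        return min(i.distance_printed for i in self.islands)

    def zone(self) -> str:
        """Distance-window zone of the gene's most proximal island.

        The published window tallies bin genes purely by printed distance
        (<=2 kb / 2-4 kb / 4-10 kb); TSS-overlap flags are annotations and
        do not promote (two flagged islands have upstream boundaries beyond
        2 kb yet are counted in the outer windows by the source).
        """
        d = self.min_distance
        if d is None:
            return "none"
        if d <= PROXIMAL_BP:
            return "proximal"
        if d <= MID_BP:
            return "mid"
        if d <= DISTAL_BP:
            return "distal"
        return "none"


def _data_path(name: str):
    return resources.files("cpgprom.data").joinpath(name)


def load_fixture() -> List[FixtureGene]:
    """Load the packaged 87-gene table; raises on corrupted data."""
    genes_df = pd.read_csv(_data_path("height_genes.tsv"), sep="\t", dtype=str)
    islands_df = pd.read_csv(_data_path("height_islands.tsv"), sep="\t", dtype=str)

    islands_by_gene: dict[str, list[FixtureIsland]] = {}
    for row in islands_df.itertuples(index=False):
        islands_by_gene.setdefault(str(row.gene), []).append(
            FixtureIsland(
                five_prime=int(row.five_prime),
                three_prime=int(row.three_prime),
                gc_percent=float(row.gc_percent),
                obs_exp=float(row.obs_exp),
                length=int(row.length),
                distance_printed=int(row.distance),
                overlaps_tss_flag=row.overlaps_tss_flag == "1",
                far_flag=row.far_flag == "1",
                provenance=str(row.provenance),
            )
        )

    genes: List[FixtureGene] = []
    for row in genes_df.itertuples(index=False):
        gene_id = str(row.gene)
        studies = tuple(s for s in str(row.studies).split(";") if s)
        if not studies or any(s not in STUDY_CODES for s in studies):
            raise FixtureIntegrityError(f"gene {gene_id!r}: bad study flags {studies}")
        genes.append(
            FixtureGene(
                gene_id=gene_id,
                refseq=str(row.refseq),
                chrom=str(row.chrom),
                tss_printed=int(row.tss),
                islands=tuple(islands_by_gene.pop(gene_id, ())),
                studies=studies,
                housekeeping=row.housekeeping == "1",
                methylation_regulated=row.methylation_regulated == "1",
                methylation_regulator=row.methylation_regulator == "1",
                no_methylation_evidence=row.no_methylation_evidence == "1",
            )
        )
    if islands_by_gene:
        raise FixtureIntegrityError(
            f"island rows reference unknown genes: {sorted(islands_by_gene)}"
        )
    if len(genes) != N_GENES:
        raise FixtureIntegrityError(f"expected {N_GENES} genes, found {len(genes)}")
    if len({g.gene_id for g in genes}) != N_GENES:
        raise FixtureIntegrityError("duplicate gene symbols in fixture")
    return genes


def count_zone_partition(fixture: List[FixtureGene]) -> Tuple[int, int, int, int]:
    """(proximal, mid-only, distal-only, no-island) gene counts."""
    zones = [g.zone() for g in fixture]
    return (
        zones.count("proximal"),
        zones.count("mid"),
        zones.count("distal"),
        zones.count("none"),
    )


def percent_with_island(fixture: List[FixtureGene], max_window: int) -> float:
    """Percent of genes with an island within ``max_window`` nt of the TSS."""
    if max_window not in (PROXIMAL_BP, MID_BP, DISTAL_BP):
        raise ValueError(
            f"max_window must be one of {PROXIMAL_BP}/{MID_BP}/{DISTAL_BP}, "
            f"got {max_window}"
        )
    n = sum(
        1
        for g in fixture
        if g.min_distance is not None and g.min_distance <= max_window
    )
    return round(100.0 * n / len(fixture), 1)


def count_cho_replicated(fixture: List[FixtureGene]) -> int:
    """Genes found by the Korean-cohort study and at least one earlier study."""
    return sum(
        1
        for g in fixture
        if REPLICATION_STUDY in g.studies
        and any(s != REPLICATION_STUDY for s in g.studies)
    )


def multi_study_counts(fixture: List[FixtureGene]) -> Tuple[int, int]:
    """(recomputed, printed) counts of genes identified by more than one study."""
    recomputed = sum(1 for g in fixture if len(g.studies) >= 2)
    return recomputed, PRINTED_MULTI_STUDY_COUNT


def percent_methylation_dynamics(fixture: List[FixtureGene]) -> float:
    """Percent of genes with recorded dynamic DNA-methylation evidence."""
    if not fixture:
        return 0.0
    n = sum(1 for g in fixture if not g.no_methylation_evidence)
    return round(100.0 * n / len(fixture), 1)


def nonhousekeeping_subset(fixture: List[FixtureGene]) -> List[FixtureGene]:
    return [g for g in fixture if not g.housekeeping]


@dataclass
class FixtureValidationReport:
    n_genes: int
    partition: Tuple[int, int, int, int]
    inconsistent_coordinate_rows: List[str] = field(default_factory=list)
    inconsistent_distance_rows: List[str] = field(default_factory=list)
    tss_flag_nonproximal_genes: List[str] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(
            set(self.inconsistent_coordinate_rows)
            | set(self.inconsistent_distance_rows)
        )


def validate_fixture(fixture: List[FixtureGene]) -> FixtureValidationReport:
    """Per-row consistency checks plus the aggregate curation gate.

    Rows whose printed length or distance cannot be reproduced from their
    printed coordinates are flagged (the printed values stay authoritative).
    The aggregate partition must equal (72, 3, 4, 8) or a
    :class:`FixtureIntegrityError` is raised.
    """
    report = FixtureValidationReport(
        n_genes=len(fixture), partition=count_zone_partition(fixture)
    )
    for g in fixture:
        for idx, isl in enumerate(g.islands, start=1):
            label = f"{g.gene_id}#{idx}"
            if not isl.row_consistent:
                report.inconsistent_coordinate_rows.append(label)
            if not isl.distance_consistent(g.tss_printed):
                report.inconsistent_distance_rows.append(label)
        if (
            any(i.overlaps_tss_flag for i in g.islands)
            and g.zone() != "proximal"
        ):
            report.tss_flag_nonproximal_genes.append(g.gene_id)
    if report.n_genes != N_GENES or report.partition != (72, 3, 4, 8):
        raise FixtureIntegrityError(
            f"curation error: partition {report.partition} over {report.n_genes} "
            "genes does not reproduce the printed (72, 3, 4, 8)"
        )
    return report


def fixture_report(fixture: Optional[List[FixtureGene]] = None) -> dict:
    """All printed aggregates recomputed from the packaged rows."""
    if fixture is None:
        fixture = load_fixture()
    proximal, mid_only, distal_only, none = count_zone_partition(fixture)
    recomputed_multi, printed_multi = multi_study_counts(fixture)
    return {
        "n_genes": len(fixture),
        "n_islands": sum(len(g.islands) for g in fixture),
        "proximal_genes": proximal,
        "mid_only_genes": mid_only,
        "distal_only_genes": distal_only,
        "no_island_genes": none,
        "proximal_percent": percent_with_island(fixture, PROXIMAL_BP),
        "mid_window_percent": percent_with_island(fixture, MID_BP),
        "distal_window_percent": percent_with_island(fixture, DISTAL_BP),
        "cho_replicated_genes": count_cho_replicated(fixture),
        "multi_study_genes_recomputed": recomputed_multi,
        "multi_study_genes_printed": printed_multi,
        "methylation_dynamics_percent": percent_methylation_dynamics(fixture),
        "nonhousekeeping_genes": len(nonhousekeeping_subset(fixture)),
        "hypermethylation_module_genes": HYPERMETHYLATION_MODULE_GENES,
    }
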