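"""Sequence, gene-table and interval I/O plus strand-aware region extraction.

Upstream windows are defined in gene orientation: offsets count away from
the TSS on the 5' side, the window excludes the TSS base itself, and minus
strand windows are reverse-complemented so the returned sequence reads
5'->3' toward the TSS.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from cpgprom.core import (
    ALPHABET,
    ConfigurationError,
    EmptyWindowError,
    GeneModel,
    GenomicInterval,
    ParseError,
    SequenceRecord,
    reverse_complement,
)

GENE_TABLE_COLUMNS = ["gene", "refseq", "chrom", "strand", "tss"]

Genome = Mapping[str, SequenceRecord]


def read_fasta(path: Union[str, Path]) -> dict[str, SequenceRecord]:
    """Read a (multi-record) FASTA file into {id: SequenceRecord}.

    Sequences are uppercased; N is preserved; any character outside
    A/C/G/T/N raises :class:`ParseError` naming the record.
    """
    path = Path(path)
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = SequenceRecord(id=rec.id, seq=seq)
    return records


def write_fasta(genome: Genome, path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in genome.values():
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gene_table(path: Union[str, Path]) -> list[GeneModel]:
    """Read a TSV gene table (columns gene/refseq/chrom/strand/tss, 1-based TSS).

    The TSS is converted to the internal 0-based convention; duplicate gene
    symbols are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty gene table (no header)") from exc
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: gene table missing column(s) {missing}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gene = str(row.gene)
        if gene in seen:
            raise ParseError(f"{path}: duplicate gene symbol {gene!r}")
        seen.add(gene)
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {gene!r} has invalid strand {strand!r}")
        try:
            tss_1based = int(row.tss)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: gene {gene!r} has non-integer tss {row.tss!r}") from exc
        if tss_1based < 1:
            raise ParseError(f"{path}: gene {gene!r} has non-positive tss {tss_1based}")
        genes.append(
            GeneModel(
                gene_id=gene,
                refseq=str(row.refseq),
                chrom=str(row.chrom),
                strand=strand,
                tss=tss_1based - 1,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: Union[str, Path]) -> None:
    """Inverse of :func:`read_gene_table` (TSS written back as 1-based)."""
    rows = [
        {
            "gene": g.gene_id,
            "refseq": g.refseq,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss + 1,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def extract_upstream_window(
    gene: GeneModel,
    near_offset: int,
    far_offset: int,
    genome: Genome,
) -> Tuple[SequenceRecord, GenomicInterval]:
    """Extract the [near, far) bp window upstream of the gene's TSS.

    For a + strand gene this is genome interval [tss - far, tss - near); for
    a - strand gene the mirrored interval downstream in genome coordinates,
    reverse-complemented so the sequence reads 5'->3' toward the TSS.  The
    window is clipped at sequence boundaries; the realized genome-frame
    interval is returned alongside the sequence.
    """
    if not (0 <= near_offset < far_offset):
        raise ValueError(
            f"need 0 <= near_offset < far_offset, got ({near_offset}, {far_offset})"
        )
    if gene.chrom not in genome:
        raise KeyError(f"gene {gene.gene_id!r}: chromosome {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    if gene.strand == "+":
        start, end = gene.tss - far_offset, gene.tss - near_offset
    else:
        start, end = gene.tss + 1 + near_offset, gene.tss + 1 + far_offset
    start = max(start, 0)
    end = min(end, len(contig))
    if start >= end:
        raise EmptyWindowError(
            f"gene {gene.gene_id!r}: upstream window ({near_offset}, {far_offset}) "
            f"lies entirely outside sequence {gene.chrom!r}"
        )
    interval = GenomicInterval(gene.chrom, start, end, gene.strand)
    seq = contig.seq[start:end]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=f"{gene.gene_id}_upstream", seq=seq), interval


def extract_transcribed_region(gene: GeneModel, genome: Genome) -> SequenceRecord:
    """Sequence of the gene's transcribed span, oriented 5'->3'."""
    if gene.span is None:
        raise ConfigurationError(
            f"gene {gene.gene_id!r} has no transcribed-region span configured"
        )
    if gene.chrom not in genome:
        raise KeyError(f"gene {gene.gene_id!r}: chromosome {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    if gene.span.end > len(contig):
        raise IndexError(
            f"gene {gene.gene_id!r}: span {gene.span.start}-{gene.span.end} extends "
            f"beyond sequence {gene.chrom!r} of length {len(contig)}"
        )
    seq = contig.seq[gene.span.start : gene.span.end]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=f"{gene.gene_id}_transcribed", seq=seq)


def write_bed(items: Sequence, path: Union[str, Path]) -> None:
    """Write islands or island calls as BED6.

    The name column carries the gene id where known (else the sequence
    name), the score column the obs/exp CpG ratio x1000 rounded.
    """
    with open(path, "w") as fh:
        for item in items:
            gene_id = getattr(item, "gene_id", None)
            island = getattr(item, "island", item)
            iv = island.interval
            name = gene_id if gene_id is not None else iv.chrom
            score = int(round(island.obs_exp * 1000))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t"
                f"{iv.strand if iv.strand != '.' else '+'}\n"
            )
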