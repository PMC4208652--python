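"""Core domain types: sequences, intervals and gene models.

All coordinates are 0-based, half-open.  File formats that use 1-based
inclusive coordinates (gene tables, the curated fixture) are converted at
the parse boundary, never inside interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CpgPromError(Exception):
    """Base class for package errors."""


class ParseError(CpgPromError):
    """Malformed input file."""


class EmptyWindowError(CpgPromError):
    """A requested genomic window lies entirely outside its sequence."""


class ConfigurationError(CpgPromError):
    """An operation was invoked without a required model attribute."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record has an empty id")
        if not self.seq:
            raise ParseError(f"sequence record {self.id!r} has an empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ParseError(
                f"sequence record {self.id!r} contains characters outside "
                f"A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """A located, optionally stranded span: 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def jaccard(self, other: "GenomicInterval") -> float:
        """Intersection over union of two intervals (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union


@dataclass(frozen=True)
class GeneModel:
    """Gene identity anchored at one TSS; optional transcribed-region span.

    ``tss`` is the 0-based position of the first transcribed base.  When a
    span is present the TSS must sit at its strand-appropriate 5' end.
    """

    gene_id: str
    refseq: str
    chrom: str
    strand: str
    tss: int
    span: Optional[GenomicInterval] = field(default=None)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS {self.tss}")
        if self.span is not None:
            five_prime = self.span.start if self.strand == "+" else self.span.end - 1
            if self.tss != five_prime:
                raise ValueError(
                    f"gene {self.gene_id!r}: TSS {self.tss} is not the 5' end "
                    f"of span {self.span.start}-{self.span.end} ({self.strand})"
                )
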