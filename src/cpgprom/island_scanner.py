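"""Sliding-window CpG-island detection with merging and trimming.

An island is a region whose G+C content and observed/expected CpG ratio
exceed configurable bounds over a minimum length.  The search is a
deterministic reconstruction of the classic window-based island finders:

1. slide a ``window``-nt window by ``step`` and collect windows whose
   statistics satisfy the bounds (windows with >10% N are disqualified);
2. merge qualifying windows separated by at most ``merge_gap`` nt into
   candidate regions;
3. refine each candidate into islands: emit the longest sub-span that
   begins and ends with a CpG (the standard island-finder boundary
   convention, which keeps island edges from diffusing into CpG-poor
   flanks) and satisfies every bound over its full extent, then recurse on
   the flanking remainders so a candidate broken by an interior dip can
   still yield its qualifying parts.  Candidates with no qualifying
   sub-span of the minimum length are dropped.

Ties between equally long sub-spans are broken by G+C count, then CpG
count, then centrality within the candidate — all mirror-invariant — so
output is deterministic and strand-symmetric.

Statistics use effective (non-N) length, so assembly gaps neither create
nor destroy islands.  The observed/expected ratio is defined as 0 when a
region contains no C or no G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from cpgprom.core import CpgPromError, GenomicInterval, SequenceRecord


class UndefinedStatsError(CpgPromError):
    """Window statistics are undefined (all-N sequence)."""


@dataclass(frozen=True)
class IslandCriteria:
    """Bounds and search parameters for island detection.

    ``length_strict`` / ``obs_exp_strict`` select a strict ``>`` bound for
    the minimum length and obs/exp ratio (the G+C bound is always ``>=``).
    """

    min_length: int
    min_gc: float
    min_obs_exp: float
    window: int = 200
    step: int = 1
    merge_gap: int = 100
    length_strict: bool = False
    obs_exp_strict: bool = False
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window > self.min_length:
            raise ValueError("window must not exceed min_length")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (0.0 <= self.min_gc <= 1.0):
            raise ValueError("min_gc must be a fraction in [0, 1]")
        if self.min_obs_exp < 0:
            raise ValueError("min_obs_exp must be >= 0")

    def length_ok(self, length: int) -> bool:
        return length > self.min_length if self.length_strict else length >= self.min_length

    def stats_ok(self, stats: "WindowStats") -> bool:
        if stats.gc_percent < 100.0 * self.min_gc:
            return False
        if self.obs_exp_strict:
            return stats.obs_exp > self.min_obs_exp
        return stats.obs_exp >= self.min_obs_exp


@dataclass(frozen=True)
class WindowStats:
    """Composition statistics of a sequence window."""

    gc_percent: float
    obs_exp: float
    n_c: int
    n_g: int
    n_cpg: int
    effective_length: int


@dataclass(frozen=True)
class CpGIsland:
    """A called island with its defining statistics."""

    interval: GenomicInterval
    length: int
    gc_percent: float
    obs_exp: float


def stringent_criteria() -> IslandCriteria:
    """Alu-excluding preset: length > 500 nt, G+C >= 55%, obs/exp CpG > 0.65."""
    return IslandCriteria(
        min_length=500,
        min_gc=0.55,
        min_obs_exp=0.65,
        length_strict=True,
        obs_exp_strict=True,
    )


def relaxed_criteria() -> IslandCriteria:
    """Broad validation preset: length >= 200 nt, G+C >= 50%, obs/exp >= 0.60.

    The obs/exp floor follows the classical island definition; it is a
    plain field of :class:`IslandCriteria` and freely configurable.
    """
    return IslandCriteria(min_length=200, min_gc=0.50, min_obs_exp=0.60)


def window_stats(seq: str) -> WindowStats:
    """Composition statistics of a sequence.

    gc_percent = 100 (n_C + n_G) / L_eff and
    obs/exp = n_CpG * L_eff / (n_C * n_G), with L_eff the non-N length and
    CpG counted as dinucleotide occurrences of "CG".  obs/exp is 0 when
    either C or G is absent.  All-N input raises
    :class:`UndefinedStatsError`.
    """
    if not seq:
        raise ValueError("window_stats requires a non-empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_n = seq.count("N")
    n_cpg = seq.count("CG")
    eff = len(seq) - n_n
    if eff == 0:
        raise UndefinedStatsError("all-N sequence has undefined statistics")
    gc_percent = 100.0 * (n_c + n_g) / eff
    obs_exp = (n_cpg * eff) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return WindowStats(gc_percent, obs_exp, n_c, n_g, n_cpg, eff)


# -- internal prefix-sum machinery -------------------------------------------


class _SeqSums:
    """O(1) window statistics over one sequence via prefix sums."""

    def __init__(self, seq: str) -> None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")
        is_cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        zero = np.zeros(1, dtype=np.int64)
        self.c = np.concatenate([zero, np.cumsum(is_c, dtype=np.int64)])
        self.g = np.concatenate([zero, np.cumsum(is_g, dtype=np.int64)])
        self.n = np.concatenate([zero, np.cumsum(is_n, dtype=np.int64)])
        # CpG pairs wholly inside [start, end): pair index is its C position.
        self.cpg = np.concatenate([zero, np.cumsum(is_cpg, dtype=np.int64)])
        self.length = len(arr)

    def stats(self, start: int, end: int) -> Optional[WindowStats]:
        """Stats over [start, end); None when the span is all N."""
        n_c = int(self.c[end] - self.c[start])
        n_g = int(self.g[end] - self.g[start])
        n_n = int(self.n[end] - self.n[start])
        n_cpg = int(self.cpg[end - 1] - self.cpg[start]) if end - start > 1 else 0
        eff = (end - start) - n_n
        if eff == 0:
            return None
        gc_percent = 100.0 * (n_c + n_g) / eff
        obs_exp = (n_cpg * eff) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
        return WindowStats(gc_percent, obs_exp, n_c, n_g, n_cpg, eff)


def _qualifying_starts(sums: _SeqSums, criteria: IslandCriteria) -> np.ndarray:
    w = criteria.window
    starts = np.arange(0, sums.length - w + 1, criteria.step)
    if len(starts) == 0:
        return starts
    n_c = sums.c[starts + w] - sums.c[starts]
    n_g = sums.g[starts + w] - sums.g[starts]
    n_n = sums.n[starts + w] - sums.n[starts]
    n_cpg = sums.cpg[starts + w - 1] - sums.cpg[starts]
    eff = w - n_n
    ok = n_n <= criteria.max_n_fraction * w
    ok &= eff > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff > 0, 100.0 * (n_c + n_g) / np.maximum(eff, 1), 0.0)
        denom = n_c * n_g
        obs_exp = np.where(denom > 0, n_cpg * eff / np.maximum(denom, 1), 0.0)
    ok &= gc >= 100.0 * criteria.min_gc
    if criteria.obs_exp_strict:
        ok &= obs_exp > criteria.min_obs_exp
    else:
        ok &= obs_exp >= criteria.min_obs_exp
    return starts[ok]


def _merge_windows(starts: np.ndarray, window: int, merge_gap: int) -> List[list]:
    """Union of windows [s, s+window), merging spans separated by <= merge_gap."""
    spans: List[list] = []
    for s in starts:
        s = int(s)
        if spans and s <= spans[-1][1] + merge_gap:
            spans[-1][1] = max(spans[-1][1], s + window)
        else:
            spans.append([s, s + window])
    return spans


def _cpg_positions(seq: str, start: int, end: int) -> List[int]:
    """C-indices of every CG dinucleotide wholly inside [start, end)."""
    out: List[int] = []
    i = seq.find("CG", start, end)
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1, end)
    return out


def _best_subspan(
    sums: _SeqSums,
    cpgs: List[int],
    cand_start: int,
    cand_end: int,
    criteria: IslandCriteria,
):
    """Longest CpG-bounded sub-span of the candidate passing every bound.

    The tie-break key (length, G+C count, CpG count, centrality) is
    mirror-invariant, keeping the scan strand-symmetric.
    """
    best = None
    best_key = None
    k = len(cpgs)
    for ii in range(k):
        i = cpgs[ii]
        if best_key is not None and cpgs[-1] + 2 - i < best_key[0]:
            break
        for jj in range(k - 1, ii - 1, -1):
            length = cpgs[jj] + 2 - i
            if best_key is not None and length < best_key[0]:
                break
            if not criteria.length_ok(length):
                break
            end = cpgs[jj] + 2
            stats = sums.stats(i, end)
            if stats is None or not criteria.stats_ok(stats):
                continue
            key = (
                length,
                stats.n_c + stats.n_g,
                stats.n_cpg,
                -abs((i - cand_start) - (cand_end - end)),
            )
            if best_key is None or key > best_key:
                best, best_key = (i, end, stats), key
    return best


def _refine(sums: _SeqSums, seq: str, start: int, end: int, criteria: IslandCriteria):
    """Extract all islands from one merged candidate [start, end).

    Greedy: emit the best qualifying sub-span, then recurse on the left and
    right remainders (a long candidate whose middle dips below the bounds
    can legitimately hold more than one island).
    """
    cpgs = _cpg_positions(seq, start, end)
    islands: List[tuple] = []

    def rec(lo: int, hi: int, cand_start: int, cand_end: int) -> None:
        sub = cpgs[lo:hi]
        if not sub or not criteria.length_ok(sub[-1] + 2 - sub[0]):
            return
        found = _best_subspan(sums, sub, cand_start, cand_end, criteria)
        if found is None:
            return
        s, e, _ = found
        islands.append(found)
        left_hi = lo + len([c for c in sub if c + 2 <= s])
        right_lo = hi - len([c for c in sub if c >= e])
        rec(lo, left_hi, cand_start, s)
        rec(right_lo, hi, e, cand_end)

    rec(0, len(cpgs), start, end)
    return sorted(islands)


def scan_islands(
    seq: SequenceRecord,
    criteria: IslandCriteria,
    origin: Optional[GenomicInterval] = None,
) -> List[CpGIsland]:
    """Detect CpG islands in a sequence under the given criteria.

    Returns non-overlapping islands in ascending coordinate order, each
    satisfying every bound of ``criteria`` over its full extent.  When
    ``origin`` is given, island coordinates are reported in that frame
    (``origin.strand == '-'`` means ``seq`` was reverse-complemented out of
    the genome and coordinates are mirrored back).  Sequences shorter than
    the search window yield an empty list.
    """
    s = seq.seq
    if len(s) < criteria.window:
        return []
    sums = _SeqSums(s)
    starts = _qualifying_starts(sums, criteria)
    spans = _merge_windows(starts, criteria.window, criteria.merge_gap)

    refined: List[tuple] = []
    for span in spans:
        refined.extend(_refine(sums, s, span[0], span[1], criteria))

    islands = []
    for start, end, stats in refined:
        if origin is None:
            interval = GenomicInterval(seq.id, start, end)
        elif origin.strand == "-":
            interval = GenomicInterval(
                origin.chrom, origin.end - end, origin.end - start, "-"
            )
        else:
            interval = GenomicInterval(
                origin.chrom, origin.start + start, origin.start + end, origin.strand
            )
        islands.append(
            CpGIsland(
                interval=interval,
                length=end - start,
                gc_percent=stats.gc_percent,
                obs_exp=stats.obs_exp,
            )
        )
    islands.sort(key=lambda i: i.interval.start)
    return islands


def validate_island(island: CpGIsland, seq: SequenceRecord, criteria: IslandCriteria) -> bool:
    """True iff recomputed full-island statistics satisfy every bound.

    ``island.interval`` must be expressed in the coordinate frame of
    ``seq`` (as returned by :func:`scan_islands` without an origin).
    """
    iv = island.interval
    if iv.end > len(seq.seq):
        raise ValueError("island interval extends beyond the sequence")
    if not criteria.length_ok(iv.length()):
        return False
    try:
        stats = window_stats(seq.seq[iv.start : iv.end])
    except UndefinedStatsError:
        return False
    return criteria.stats_ok(stats)
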