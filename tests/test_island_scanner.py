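import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgprom.core import GenomicInterval, SequenceRecord, reverse_complement
from cpgprom.island_scanner import (
    IslandCriteria,
    UndefinedStatsError,
    relaxed_criteria,
    scan_islands,
    stringent_criteria,
    validate_island,
    window_stats,
)
from cpgprom.synthetic_data import BackgroundModel, IslandModel, generate_background, plant_island

from conftest import random_sequence


class TestWindowStats:
    @pytest.mark.parametrize(
        "seq,gc,n_cpg,obs_exp",
        [
            ("CGCGCGCGCG", 100.0, 5, 2.0),  # 5 CG pairs, (5*10)/(5*5)
            ("ATATATATAT", 0.0, 0, 0.0),
            ("ACGT", 50.0, 1, 4.0),  # (1*4)/(1*1)
        ],
    )
    def test_hand_enumerated_examples(self, seq, gc, n_cpg, obs_exp):
        stats = window_stats(seq)
        assert stats.gc_percent == pytest.approx(gc)
        assert stats.n_cpg == n_cpg
        assert stats.obs_exp == pytest.approx(obs_exp)

    def test_all_n_is_undefined(self):
        with pytest.raises(UndefinedStatsError):
            window_stats("NNNN")

    def test_n_excluded_via_effective_length(self):
        # Non-N part is ACGT: same stats as without the Ns.
        with_n = window_stats("ACGTNN")
        assert with_n.effective_length == 4
        assert with_n.gc_percent == pytest.approx(50.0)
        assert with_n.obs_exp == pytest.approx(4.0)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_invariants(self, seq):
        try:
            stats = window_stats(seq)
        except UndefinedStatsError:
            assert set(seq) == {"N"}
            return
        assert 0.0 <= stats.gc_percent <= 100.0
        assert stats.obs_exp >= 0.0
        assert stats.n_cpg <= min(stats.n_c, stats.n_g)
        assert stats.effective_length == len(seq) - seq.count("N")


class TestCriteriaPresets:
    def test_stringent_bounds(self):
        c = stringent_criteria()
        assert (c.min_length, c.min_gc, c.min_obs_exp) == (500, 0.55, 0.65)
        assert c.length_strict and c.obs_exp_strict
        assert (c.window, c.step, c.merge_gap) == (200, 1, 100)

    def test_relaxed_bounds(self):
        c = relaxed_criteria()
        assert (c.min_length, c.min_gc, c.min_obs_exp) == (200, 0.50, 0.60)
        assert not c.length_strict and not c.obs_exp_strict

    def test_exactly_500nt_island_fails_strict_length(self):
        c = stringent_criteria()
        assert not c.length_ok(500)
        assert c.length_ok(501)
        assert relaxed_criteria().length_ok(200)

    def test_window_must_not_exceed_min_length(self):
        with pytest.raises(ValueError):
            IslandCriteria(min_length=100, min_gc=0.5, min_obs_exp=0.6, window=200)


def planted_record(seed, bg_len=10000, position=5000, island=None):
    bg = generate_background(bg_len, BackgroundModel(seed=seed))
    return plant_island(bg, position, island or IslandModel(), seed=seed + 10_000)


class TestScanIslands:
    def test_no_cpg_content_yields_nothing(self):
        rec = SequenceRecord("s", "AT" * 2500)
        assert scan_islands(rec, stringent_criteria()) == []

    def test_sequence_shorter_than_window_is_empty_not_error(self):
        rec = SequenceRecord("s", "CG" * 50)
        assert scan_islands(rec, stringent_criteria()) == []

    def test_sequence_shorter_than_min_length_cannot_qualify(self):
        rec = SequenceRecord("s", "CG" * 200)  # 400 nt of pure CpG
        assert scan_islands(rec, stringent_criteria()) == []

    def test_planted_island_recovered(self):
        rec, truth = planted_record(seed=42)
        islands = scan_islands(rec, stringent_criteria())
        assert len(islands) == 1
        assert islands[0].interval.jaccard(truth) >= 0.8

    def test_origin_frame_plus(self):
        rec, truth = planted_record(seed=43)
        origin = GenomicInterval("chr9", 100000, 100000 + len(rec.seq))
        (island,) = scan_islands(rec, stringent_criteria(), origin=origin)
        local = scan_islands(rec, stringent_criteria())[0]
        assert island.interval.start == 100000 + local.interval.start
        assert island.interval.chrom == "chr9"

    def test_origin_frame_minus_mirrors_coordinates(self):
        rec, truth = planted_record(seed=44)
        L = len(rec.seq)
        origin = GenomicInterval("chr9", 100000, 100000 + L, "-")
        (island,) = scan_islands(rec, stringent_criteria(), origin=origin)
        local = scan_islands(rec, stringent_criteria())[0]
        assert island.interval.start == origin.end - local.interval.end
        assert island.interval.end == origin.end - local.interval.start

    def test_nearby_planted_islands_merge(self):
        bg = generate_background(10000, BackgroundModel(seed=7))
        small = IslandModel(length=600)
        rec, t1 = plant_island(bg, 4000, small, seed=1)
        rec, t2 = plant_island(rec, 4650, small, seed=2)  # 50 nt gap <= merge_gap
        islands = scan_islands(rec, stringent_criteria())
        assert len(islands) == 1
        assert islands[0].interval.start < t1.end <= t2.start < islands[0].interval.end

    def test_assembly_gap_does_not_fabricate_islands(self):
        # An N-rich stretch inside CpG-rich sequence: windows over the gap
        # are disqualified, the flanks still qualify.
        rec, truth = planted_record(seed=45)
        gapped = rec.seq[:4000] + "N" * 2000 + rec.seq[6000:]
        islands = scan_islands(SequenceRecord("s", gapped), stringent_criteria())
        for isl in islands:
            frag = gapped[isl.interval.start : isl.interval.end]
            assert frag.count("N") <= 0.5 * len(frag)


class TestValidateIsland:
    def test_scan_output_revalidates(self):
        rec, _ = planted_record(seed=46)
        crit = stringent_criteria()
        for isl in scan_islands(rec, crit):
            assert validate_island(isl, rec, crit)

    def test_too_short_island_fails(self):
        from cpgprom.island_scanner import CpGIsland

        rec = SequenceRecord("s", "CG" * 500)
        island = CpGIsland(GenomicInterval("s", 0, 300), 300, 100.0, 2.0)
        assert not validate_island(island, rec, stringent_criteria())

    def test_obs_exp_at_strict_bound_fails(self):
        crit = stringent_criteria()
        assert not crit.stats_ok(
            dataclasses.replace(window_stats("CG" * 300), obs_exp=0.64)
        )
        assert not crit.stats_ok(
            dataclasses.replace(window_stats("CG" * 300), obs_exp=0.65)
        )


def coverage(islands):
    return sum(i.length for i in islands)


class TestScannerProperties:
    SEEDS = range(40)

    def _mixed_records(self, n, length=1200):
        rng = np.random.default_rng(777)
        for _ in range(n):
            gc = float(rng.uniform(0.35, 0.75))
            yield SequenceRecord("r", random_sequence(rng, length, gc))

    def test_soundness_on_random_sequences(self):
        """Every emitted island re-validates under both presets."""
        crits = [stringent_criteria(), relaxed_criteria()]
        for rec in self._mixed_records(150):
            for crit in crits:
                for isl in scan_islands(rec, crit):
                    assert validate_island(isl, rec, crit)

    @pytest.mark.parametrize(
        "field,looser,tighter",
        [
            ("min_gc", 0.50, 0.60),
            ("min_obs_exp", 0.60, 0.75),
            ("min_length", 200, 400),
        ],
    )
    def test_tightening_a_bound_never_increases_coverage(self, field, looser, tighter):
        base = relaxed_criteria()
        loose = dataclasses.replace(base, **{field: looser})
        tight = dataclasses.replace(base, **{field: tighter})
        for rec in self._mixed_records(60, length=1500):
            assert coverage(scan_islands(rec, tight)) <= coverage(
                scan_islands(rec, loose)
            )

    def test_every_stringent_island_overlaps_a_relaxed_island(self):
        for rec in self._mixed_records(60, length=2000):
            relaxed = scan_islands(rec, relaxed_criteria())
            for isl in scan_islands(rec, stringent_criteria()):
                assert any(isl.interval.overlaps(r.interval) for r in relaxed)

    def test_strand_invariance(self):
        """Island intervals mirror exactly on the reverse complement."""
        for seed in range(20):
            rec, _ = planted_record(seed=seed, bg_len=6000, position=2500)
            L = len(rec.seq)
            rc = SequenceRecord("s", reverse_complement(rec.seq))
            fwd = scan_islands(rec, stringent_criteria())
            rev = scan_islands(rc, stringent_criteria())
            mirrored = sorted(
                (L - i.interval.end, L - i.interval.start) for i in rev
            )
            assert mirrored == [(i.interval.start, i.interval.end) for i in fwd]


# -- brute-force oracle -------------------------------------------------------


def oracle_islands(seq: str, criteria: IslandCriteria):
    """Independent re-derivation of the scan by exhaustive enumeration.

    Qualifying windows are found by recounting every start position with
    plain string operations; runs of qualifying windows are unioned
    (merge_gap 0); within each union, every CpG-bounded sub-span is
    enumerated outright, the best (longest, ties by G+C count, CpG count,
    centrality) is emitted, and the flanking remainders are re-searched.
    """
    w = criteria.window
    spans = []
    for s in range(0, len(seq) - w + 1):
        win = seq[s : s + w]
        if win.count("N") > criteria.max_n_fraction * w:
            continue
        stats = window_stats(win)
        if criteria.stats_ok(stats):
            if spans and s <= spans[-1][1]:
                spans[-1][1] = s + w
            else:
                spans.append([s, s + w])

    def emit(start, end):
        candidates = []
        for i in range(start, end - 1):
            if seq[i : i + 2] != "CG":
                continue
            for j in range(i, end - 1):
                if seq[j : j + 2] != "CG":
                    continue
                if not criteria.length_ok(j + 2 - i):
                    continue
                stats = window_stats(seq[i : j + 2])
                if criteria.stats_ok(stats):
                    key = (
                        j + 2 - i,
                        stats.n_c + stats.n_g,
                        stats.n_cpg,
                        -abs((i - start) - (end - (j + 2))),
                    )
                    candidates.append((key, i, j + 2))
        if not candidates:
            return []
        _, i, e = max(candidates)
        return emit(start, i) + [(i, e)] + emit(e, end)

    out = []
    for start, end in spans:
        out.extend(emit(start, end))
    return sorted(out)


class TestBruteForceOracle:
    def test_scan_matches_exhaustive_enumeration(self):
        """With window = min_length and merge_gap 0, islands equal the refined
        maximal runs of qualifying windows found by brute force."""
        criteria = IslandCriteria(
            min_length=200, min_gc=0.5, min_obs_exp=0.6, window=200, merge_gap=0
        )
        rng = np.random.default_rng(31)
        n_with_islands = 0
        for _ in range(40):
            gc = float(rng.uniform(0.40, 0.70))
            seq = random_sequence(rng, 2000, gc)
            expected = oracle_islands(seq, criteria)
            got = [
                (i.interval.start, i.interval.end)
                for i in scan_islands(SequenceRecord("s", seq), criteria)
            ]
            assert got == expected
            n_with_islands += bool(expected)
        assert n_with_islands >= 5  # the comparison must exercise real islands
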