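"""Synthetic genomes with CpG-depleted background and planted CpG islands.

Sequence is drawn from a first-order Markov chain because CpG depletion is
inherently a dinucleotide property: the bulk vertebrate genome runs at
roughly 41% G+C with an observed/expected CpG ratio of 0.2-0.3, while
islands sit at 55-65% G+C with obs/exp above 0.65.  The transition matrix
is calibrated by fixed-point iteration so that the chain's *stationary*
G+C content and long-run obs/exp hit the requested targets (naive scaling
of P(G|C) alone shifts the stationary composition by a few percent).

Island boundaries are hard transitions — no gradient — so truth intervals
are unambiguous for Jaccard scoring.  All randomness flows from explicit
seed parameters; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from cpgprom.core import GeneModel, GenomicInterval, SequenceRecord
from cpgprom.genome_io import write_fasta, write_gene_table

_BASES = "ACGT"
_A, _C, _G, _T = range(4)


@dataclass(frozen=True)
class BackgroundModel:
    """Bulk-genome composition target (defaults: 41% G+C, obs/exp 0.25)."""

    gc_content: float = 0.41
    cpg_obs_exp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0.0 <= self.cpg_obs_exp <= 1.0):
            raise ValueError("background cpg_obs_exp must be in [0, 1]")


@dataclass(frozen=True)
class IslandModel:
    """Planted-island composition (defaults satisfy the stringent criteria)."""

    length: int = 800
    gc_content: float = 0.65
    cpg_obs_exp: float = 0.85

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("island length must be >= 0")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.cpg_obs_exp < 0:
            raise ValueError("cpg_obs_exp must be >= 0")


@dataclass
class SyntheticTruth:
    """A generated genome, its gene annotation and planted-island truth."""

    genome: dict
    genes: List[GeneModel]
    truth_islands: List[Tuple[str, GenomicInterval]] = field(default_factory=list)

    @property
    def planted_gene_ids(self) -> set:
        return {gene_id for gene_id, _ in self.truth_islands}


def build_transition_matrix(gc: float, cpg_obs_exp: float) -> np.ndarray:
    """First-order A/C/G/T transition matrix hitting the given targets.

    Rows A, G and T draw the next base from a common frequency vector;
    row C carries the CpG depletion/enrichment: P(G|C) is set so that the
    long-run obs/exp CpG ratio equals ``cpg_obs_exp``, with the displaced
    mass redistributed proportionally over A, C and T.  A fixed-point loop
    adjusts the base-frequency vector until the stationary G+C content
    matches ``gc`` to high precision.  Raises for infeasible combinations
    (redistribution would force a negative probability).
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    if cpg_obs_exp < 0:
        raise ValueError("cpg_obs_exp must be >= 0")

    def assemble(freqs: np.ndarray, p_g_given_c: float) -> np.ndarray:
        if p_g_given_c > 1.0 or p_g_given_c < 0.0:
            raise ValueError(
                f"infeasible targets gc={gc}, cpg_obs_exp={cpg_obs_exp}: "
                f"P(G|C)={p_g_given_c:.4f} out of [0, 1]"
            )
        P = np.tile(freqs, (4, 1))
        non_g = 1.0 - freqs[_G]
        if non_g <= 0:
            raise ValueError("degenerate base frequencies (all G)")
        scale = (1.0 - p_g_given_c) / non_g
        row_c = freqs * scale
        row_c[_G] = p_g_given_c
        P[_C] = row_c
        return P

    freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_gc = cpg_obs_exp * freqs[_G]
    P = assemble(freqs, p_gc)
    for _ in range(200):
        pi = stationary_distribution(P)
        # retarget: obs/exp realized = P(G|C) / pi_G
        p_gc = cpg_obs_exp * pi[_G]
        err_gc = gc - (pi[_C] + pi[_G])
        freqs = freqs + np.array([-err_gc / 2, err_gc / 2, err_gc / 2, -err_gc / 2])
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise ValueError(f"infeasible targets gc={gc}, cpg_obs_exp={cpg_obs_exp}")
        P_new = assemble(freqs, p_gc)
        if np.max(np.abs(P_new - P)) < 1e-12:
            P = P_new
            break
        P = P_new
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary row vector of a 4-state transition matrix."""
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_obs_exp(P: np.ndarray) -> float:
    """Analytic long-run obs/exp CpG ratio of the chain."""
    pi = stationary_distribution(P)
    return float(P[_C, _G] / pi[_G]) if pi[_G] > 0 else 0.0


def _sample_chain(P: np.ndarray, length: int, rng: np.random.Generator) -> str:
    pi = stationary_distribution(P)
    cum = np.cumsum(P, axis=1)
    thresholds = [(float(c[0]), float(c[1]), float(c[2])) for c in cum]
    u = rng.random(length).tolist()
    state = int(rng.choice(4, p=pi))
    out = []
    append = out.append
    for x in u:
        t0, t1, t2 = thresholds[state]
        if x < t0:
            state = 0
        elif x < t1:
            state = 1
        elif x < t2:
            state = 2
        else:
            state = 3
        append(state)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return lut[np.array(out, dtype=np.intp)].tobytes().decode("ascii")


def generate_background(length: int, model: BackgroundModel) -> SequenceRecord:
    """A reproducible background realization of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    P = build_transition_matrix(model.gc_content, model.cpg_obs_exp)
    rng = np.random.default_rng(model.seed)
    return SequenceRecord(id=f"synthetic_bg_{model.seed}", seq=_sample_chain(P, length, rng))


def plant_island(
    seq: SequenceRecord,
    position: int,
    model: IslandModel,
    seed: int,
) -> Tuple[SequenceRecord, GenomicInterval]:
    """Replace seq[position : position+length] with an island realization."""
    if model.length == 0:
        raise ValueError("degenerate island of length 0")
    if position < 0 or position + model.length > len(seq.seq):
        raise IndexError(
            f"island [{position}, {position + model.length}) out of bounds "
            f"for sequence of length {len(seq.seq)}"
        )
    P = build_transition_matrix(model.gc_content, model.cpg_obs_exp)
    rng = np.random.default_rng(seed)
    island_seq = _sample_chain(P, model.length, rng)
    new_seq = seq.seq[:position] + island_seq + seq.seq[position + model.length :]
    truth = GenomicInterval(seq.id, position, position + model.length)
    return SequenceRecord(id=seq.id, seq=new_seq), truth


def generate_gene_set(
    n_genes: int,
    p_island: float,
    seed: int,
    *,
    layout: Tuple[int, int] = (0, 10000),
    spacing: int = 25000,
    background: Optional[BackgroundModel] = None,
    island: Optional[IslandModel] = None,
    min_distance: int = 850,
    max_distance: int = 1800,
    out_prefix: Optional[str] = None,
) -> SyntheticTruth:
    """Simulate a chromosome of ``n_genes`` TSSs with planted proximal islands.

    Genes alternate strand along a single chromosome at ``spacing`` nt
    intervals (spacing must exceed twice the far offset so upstream windows
    never collide).  Exactly ``round(n_genes * p_island)`` genes — chosen
    by a seeded permutation, so the count is deterministic — receive one
    island whose 5' boundary lies ``min_distance``..``max_distance`` nt
    upstream of the TSS, inside the proximal zone with margin for boundary
    diffusion of the scanner.  With ``out_prefix``, FASTA / gene-table TSV
    / truth BED files are written.
    """
    if not (0.0 <= p_island <= 1.0):
        raise ValueError("p_island must be in [0, 1]")
    near, far = layout
    if not (0 <= near < far):
        raise ValueError("layout offsets must satisfy 0 <= near < far")
    if spacing <= 2 * far:
        raise ValueError(
            f"spacing {spacing} collides with upstream windows of width {far}"
        )
    background = background or BackgroundModel()
    island = island or IslandModel()
    if island.length + 50 > max_distance:
        raise ValueError("island does not fit between min/max planting distance")

    rng = np.random.default_rng(seed)
    chrom = "chrSim"
    length = (n_genes + 1) * spacing
    P_bg = build_transition_matrix(background.gc_content, background.cpg_obs_exp)
    seq = _sample_chain(P_bg, length, rng)

    genes: List[GeneModel] = []
    for i in range(n_genes):
        genes.append(
            GeneModel(
                gene_id=f"SYN{i + 1:03d}",
                refseq=f"NM_{900000 + i}",
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                tss=(i + 1) * spacing,
            )
        )

    n_planted = int(round(n_genes * p_island))
    planted_idx = sorted(rng.permutation(n_genes)[:n_planted].tolist())

    record = SequenceRecord(id=chrom, seq=seq)
    truth: List[Tuple[str, GenomicInterval]] = []
    P_isl = build_transition_matrix(island.gc_content, island.cpg_obs_exp)
    seq_list = list(record.seq)
    for i in planted_idx:
        gene = genes[i]
        d5 = int(rng.integers(min_distance, max_distance + 1))
        if gene.strand == "+":
            start = gene.tss - d5
        else:
            start = gene.tss + d5 - island.length + 1
        isl_seq = _sample_chain(P_isl, island.length, rng)
        seq_list[start : start + island.length] = isl_seq
        truth.append((gene.gene_id, GenomicInterval(chrom, start, start + island.length)))
    record = SequenceRecord(id=chrom, seq="".join(seq_list))

    result = SyntheticTruth(genome={chrom: record}, genes=genes, truth_islands=truth)
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(result.genome, f"{prefix}.fasta")
        write_gene_table(result.genes, f"{prefix}.genes.tsv")
        with open(f"{prefix}.truth.bed", "w") as fh:
            for gene_id, iv in result.truth_islands:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene_id}\t0\t+\n")
    return result
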