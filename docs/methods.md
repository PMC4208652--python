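# Methods

## Coordinates and region extraction

All internal coordinates are 0-based half-open; the gene-table TSV and the
curated fixture use the 1-based inclusive convention of their sources and
are converted at the parse boundary.  Upstream windows are defined in gene
orientation as offsets [near, far) from the TSS, exclude the TSS base
itself, and are clipped at contig boundaries with the realized interval
returned.  Minus-strand windows are reverse-complemented so the scanner
always reads 5'→3' toward the TSS; because CG is its own reverse
complement, island statistics — and hence island calls — are
strand-invariant, so orientation matters only for coordinate bookkeeping.

## Island detection

Window statistics over a region of effective (non-N) length L:
gc = (n_C + n_G)/L and obs/exp = n_CpG · L/(n_C · n_G), with obs/exp
defined as 0 when C or G is absent (a disqualifying value, never a
division error).  Windows with more than 10% N are disqualified outright,
so assembly gaps can neither create nor destroy islands.

The search is a deterministic reconstruction of the classical
window-based island finders (the original web tools publish their
criteria but not a reference implementation):

1. slide a 200-nt window by 1 nt and collect windows passing all bounds;
2. merge qualifying windows separated by ≤ 100 nt (`merge_gap`) into
   candidates;
3. per candidate, emit the longest sub-span that starts and ends with a
   CG dinucleotide and satisfies every bound over its full extent, then
   recurse on the flanking remainders; candidates with no qualifying
   sub-span of the minimum length are dropped.

Step 3 deserves a note.  A first implementation trimmed candidates one
base at a time from their ends until the whole region passed, which is
how the procedure is usually paraphrased.  That local rule has two
defects: the result depends on the extent of the initial candidate, so
*tightening* a threshold could occasionally *grow* the reported island
(violating the monotonicity this package guarantees and tests), and
called boundaries diffused ~80 nt into CpG-poor flanks, degrading
planted-island recovery.  The maximal-qualifying-sub-span rule fixes
both: any sub-span available to a tighter criteria set is also available
to a looser one, and CpG-aligned ends (a convention of the classical
tools) pin boundaries to the last informative dinucleotide.  Ties between
equally long sub-spans break by G+C count, then CpG count, then
centrality within the candidate — all mirror-invariant, so output is
deterministic and exactly strand-symmetric.

Preset bounds: stringent = length > 500 nt, G+C ≥ 55%, obs/exp > 0.65
(strict bounds where the defining source states strict inequalities; the
length/GC thresholds are deliberately high to exclude GC-rich Alu
repeats without repeat masking).  Relaxed = length ≥ 200 nt, G+C ≥ 50%,
obs/exp ≥ 0.60; the relaxed obs/exp floor is not stated by the validation
source, so the classical island-definition value 0.60 is adopted and left
configurable.  Window 200 / step 1 / merge gap 100 follow the classical
search parameters; they are validated by the recovery benchmarks rather
than by byte-identity with any retired web service.

## Gene joining and zones

Distance to the TSS is measured from the TSS to the island boundary lying
farther upstream in gene orientation (the 5' boundary), floored at 0 for
islands entirely downstream.  Zones bin the distance with closed far
edges: proximal ≤ 2000 < mid ≤ 4000 < distal ≤ 10000.  By default an
island physically overlapping the TSS is classified proximal regardless
of its upstream-boundary distance (`overlap_promotes=True`): an island
covering the TSS is promoter-associated whatever its upstream extent.
The curated-table census (below) instead bins purely by printed distance,
because that is the counting convention its published aggregates follow.
A gene's zone is that of its best (most proximal) island; island
multiplicity is reported but does not change gene counts, and the four
gene classes always partition the gene set.

## Exact statistics

Both tests use the "small-p" two-tailed definition (sum of outcomes no
more probable than the observed one): Fisher's exact test for 2×2 tables
with explicit control counts, and the exact binomial test against a fixed
baseline fraction for literature baselines whose control denominators are
not published.  The implementations delegate to scipy
(`fisher_exact`, `binomtest`, which implement exactly this definition);
the test suite verifies them against full hypergeometric/binomial
enumeration — every 2×2 table with total ≤ 30 agrees to better than 1e-9
relative.  Odds ratios are the unconditional cross-product a·d/(b·c),
with ∞/0 allowed at zero cells.

## The curated gene table

The packaged fixture transcribes the published 87-gene height-associated
census: per gene the RefSeq accession, chromosome, printed TSS, citation
flags across the four source cohorts, housekeeping flags, and
methylation-annotation flags; per island the printed %G+C, obs/exp,
length, 5'/3' coordinates, upstream distance, TSS-overlap (‡) and
far-window (*) flags.  Printed distances and flags are authoritative;
several coordinate cells are typographically corrupt (wrong magnitude or
transposed digits) and are flagged by `validate_fixture`, never silently
corrected.  The source mixes inclusive and exclusive length conventions,
so coordinate/length consistency is accepted within ±1.

Two curation facts worth knowing:

- The published window tallies (72 proximal, 3 more within 2–4 kb, 4 more
  within 4–10 kb, 8 without islands) are pure distance bins.  Two islands
  carry the TSS-overlap flag while their upstream boundary lies beyond
  2 kb (HMGA1 at 2394 nt, TBX2 at 4458 nt); promoting them to proximal
  would give 74/87, not the published 72.  The fixture census therefore
  counts by distance only, while the live pipeline keeps overlap
  promotion as its default.
- A naive recount of the citation flags gives 22 genes found by more than
  one study, versus the printed 23 (26.4%); both numbers are reported and
  equality is not asserted.

The aggregate hypermethylation-module count (42 of 87 genes, vs 1.5% of
control genes) is stored as a documented constant because the per-gene
list lives in unavailable supplementary material.  For the same reason
the published control-set p-values (8.02e−17, 1.10e−11) cannot be
recomputed: their control denominators are unprinted.  The package
exposes the Fisher route for users who have control counts and the
binomial-vs-baseline route otherwise, and the observed 72/87 against the
45% non-housekeeping baseline is itself significant at p ≈ 7.8e−13.

## Synthetic data

The generator emulates the two compositional regimes the analysis
assumes: bulk genome background at 41% G+C with obs/exp CpG 0.25 (the
genome-wide CpG depletion produced by deamination of methylated
cytosines), and islands at 65% G+C with obs/exp 0.85 over 800 nt —
comfortably inside the stringent bounds, as promoter islands typically
are.  Sequence is drawn from a first-order Markov chain because CpG
depletion is a dinucleotide property that independent draws cannot
represent.  Naively scaling P(G|C) by the target obs/exp perturbs the
stationary composition (≈2.5 G+C percentage points at the background
parameters), so the builder runs a fixed-point calibration of the
base-frequency vector and P(G|C) until the stationary G+C and the
analytic long-run obs/exp (= P(G|C)/π_G) match the targets; empirical
100-kb realizations land within ±2 G+C points and ±0.05 obs/exp.

Island boundaries are hard transitions — no gradient — so truth intervals
are unambiguous for Jaccard scoring.  `generate_gene_set` places TSSs
every 25 kb along one chromosome, alternating strands; a seeded
permutation selects exactly round(n·p_island) genes to receive one
proximal island whose 5' boundary is drawn uniformly 850–1800 nt upstream
— inside the proximal zone with margin, so recovered islands classify as
planted even after boundary diffusion of the scanner.  All randomness
flows from explicit seeds; fixed seeds give byte-identical FASTA/TSV/BED
outputs.

What the simulations do *not* model: repeat content (Alu), isochore
structure, gradients at island edges, multiple islands per promoter, and
methylation states.  Passing recovery benchmarks therefore demonstrate
the scanner's correctness under the stated compositional model, not
performance on real assemblies.

## Benchmarks and problem sizes

The acceptance checks run: the curated-table aggregates (exact); Fisher
vs enumeration over all 2×2 tables with total ≤ 30; scanner soundness,
bound-monotonicity and preset nesting over 1,000 random mixed-GC 1.2-kb
sequences; planted-island recovery over 100 replicates of 10-kb
backgrounds (threshold: ≥95% of islands at Jaccard ≥ 0.8; measured
≈98–100%) with 50 pure-background 100-kb replicates required island-free;
and 20 end-to-end seeds of the 87-gene simulation requiring the reported
proximal count to match the 72 planted genes within 5%.  The
`scripts/acceptance.py` runner uses 50 recovery and 20 background
replicates plus one end-to-end seed, sizes chosen to keep a full rerun
within a couple of minutes on one CPU while leaving the binomial
confidence of the rate estimates informative.

## Known limitations

- The scanner reconstruction is validated behaviorally, not
  byte-for-byte, against the retired web tools; merge/window parameters
  are the classical defaults.
- Whether genes printed without islands were searched beyond −10 kb is
  unstated in the source; the fixture treats them as island-free within
  the surveyed window.
- One TSS per gene: transcript-isoform-specific TSS choice is out of
  scope, as is enhancer modeling beyond 10 kb, liftover between genome
  builds, and methylation-state calling.
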