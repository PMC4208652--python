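# cpgprom

Promoter CpG-island analysis for gene sets: sliding-window island
detection, strand-aware promoter extraction, distance-to-TSS
classification, and exact enrichment statistics — with a curated
87-gene height-associated fixture and a synthetic-genome simulator so the
whole pipeline is testable without any genome download.

## The scientific problem

Genes regulated by DNA methylation almost always carry one or more CpG
islands, most often in their promoter.  Whether a gene set is a plausible
target of methylation-based regulation can therefore be screened
computationally: detect CpG islands upstream of each transcription start
site (TSS), classify them by distance, and ask whether the island
frequency exceeds genome-wide baselines.  This package implements that
screen as a reusable library and CLI, and ships the curated table of the
87 genes most strongly associated with adult human height across four
GWAS cohorts, whose promoter-island census motivated the pipeline.

## The method

For a window or region of effective (non-N) length *L* with base counts
*n*<sub>C</sub>, *n*<sub>G</sub> and *n*<sub>CpG</sub> occurrences of the
dinucleotide CG:

- **G+C content** = (*n*<sub>C</sub> + *n*<sub>G</sub>) / *L*
- **obs/exp CpG** = *n*<sub>CpG</sub> · *L* / (*n*<sub>C</sub> · *n*<sub>G</sub>)

A 200-nt window slides by 1 nt; qualifying windows are merged when
separated by ≤ 100 nt; each merged candidate is refined to its longest
CpG-bounded sub-span satisfying every bound over its full extent
(recursing on the flanks).  Two presets are built in:

| preset    | length   | G+C    | obs/exp | purpose                        |
|-----------|----------|--------|---------|--------------------------------|
| stringent | > 500 nt | ≥ 55%  | > 0.65  | excludes GC-rich Alu repeats   |
| relaxed   | ≥ 200 nt | ≥ 50%  | ≥ 0.60  | broad validation / concordance |

Islands join to genes through the distance from the TSS to the island's
upstream (5') boundary, binned into zones: proximal (≤ 2 kb, or physically
overlapping the TSS), mid (2–4 kb) and distal (4–10 kb).  Enrichment
against a literature baseline fraction *p*₀ uses the exact two-tailed
binomial test; two-sample comparisons with explicit control counts use
Fisher's exact test (both with the conventional "small-p" two-tailed
definition).

## Worked example

Plant one 800-nt island (G+C 0.65, obs/exp 0.85) in 10 kb of CpG-depleted
background (G+C 0.41, obs/exp 0.25) and recover it:

```python
from cpgprom.synthetic_data import (
    BackgroundModel, IslandModel, generate_background, plant_island)
from cpgprom.island_scanner import scan_islands, stringent_criteria

bg = generate_background(10_000, BackgroundModel(seed=7))
rec, truth = plant_island(bg, 5_000, IslandModel(), seed=8)
for isl in scan_islands(rec, stringent_criteria()):
    print(isl.interval.start, isl.interval.end, isl.length,
          round(isl.gc_percent, 1), round(isl.obs_exp, 3),
          round(isl.interval.jaccard(truth), 3))
```

prints

```
5002 5822 820 67.6 0.885 0.971
```

one island of 820 nt at 67.6% G+C and obs/exp 0.885, overlapping the
planted truth interval [5000, 5800) with Jaccard 0.971.

The packaged gene table reproduces the published census from the command
line:

```sh
cpgprom fixture-report
```

reports, among other aggregates, `"proximal_genes": 72` of
`"n_genes": 87` (`"proximal_percent": 82.8`) with a proximal island,
`"distal_window_percent": 90.8` within 10 kb, the 3 / 4 additional genes
in the 2–4 kb and 4–10 kb windows, `"cho_replicated_genes": 15`, and
`"methylation_dynamics_percent": 94.3`.

A full synthetic run:

```sh
cpgprom simulate --n-genes 87 --p-island 0.83 --seed 1 --out-prefix sim/sim
cpgprom classify --fasta sim/sim.fasta --gene-table sim/sim.genes.tsv \
    --out-prefix sim/run --baseline genome=0.45
```

writes `sim/run.islands.bed`, `sim/run.genes.tsv` and
`sim/run.aggregate.json`, whose reported proximal-gene count equals the 72
planted islands.

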