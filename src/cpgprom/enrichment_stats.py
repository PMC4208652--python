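"""Exact statistics for island-frequency comparisons.

Both tests use the conventional "small-p" two-tailed definition: the
p-value sums the probabilities of all outcomes no more probable than the
one observed — the hypergeometric tail sum for Fisher's exact test on a
2x2 table, the binomial tail sum for a proportion against a fixed
baseline.  The binomial path exists because literature baselines are often
published as fractions without control denominators, which rules out a
two-sample table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats as sps

from cpgprom.promoter_analysis import GeneIslandSummary


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows gene sets, columns island present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    p_two_tailed: float
    odds_ratio: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_two_tailed}")


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> TestResult:
    """Two-tailed Fisher exact test; odds ratio is (a*d)/(b*c), inf/0 at zero cells."""
    _, p = sps.fisher_exact([[table.a, table.b], [table.c, table.d]])
    bc = table.b * table.c
    ad = table.a * table.d
    odds = math.inf if bc == 0 and ad > 0 else (ad / bc if bc else math.nan)
    return TestResult(p_two_tailed=min(float(p), 1.0), odds_ratio=odds, method="fisher")


def binomial_exact_vs_baseline(k: int, n: int, p0: float) -> TestResult:
    """Exact two-tailed binomial test of k/n successes against baseline p0."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"baseline fraction out of [0, 1]: {p0}")
    p = float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    expected_odds = p0 / (1 - p0) if p0 < 1 else math.inf
    if k == n:
        observed_odds = math.inf
    else:
        observed_odds = (k / n) / (1 - k / n)
    if expected_odds in (0.0, math.inf):
        odds = math.nan if observed_odds == expected_odds else observed_odds
    else:
        odds = observed_odds / expected_odds
    return TestResult(p_two_tailed=min(p, 1.0), odds_ratio=odds, method="binomial")


def enrichment_report(
    summary: GeneIslandSummary,
    baselines: Sequence[Tuple[str, float]],
    tables: Optional[Iterable[Tuple[str, ContingencyTable2x2]]] = None,
) -> pd.DataFrame:
    """One row per baseline (binomial vs observed proximal fraction) plus any
    user-supplied 2x2 comparisons (Fisher)."""
    n = summary.n_genes
    k = summary.n_genes_proximal
    rows = []
    for label, p0 in baselines:
        if not (0.0 <= p0 <= 1.0):
            raise ValueError(f"baseline {label!r} out of [0, 1]: {p0}")
        res = binomial_exact_vs_baseline(k, n, p0)
        rows.append(
            {
                "comparison": label,
                "method": res.method,
                "observed_k": k,
                "observed_n": n,
                "observed_fraction": round(k / n, 4) if n else float("nan"),
                "baseline_fraction": p0,
                "odds_ratio": res.odds_ratio,
                "p_two_tailed": res.p_two_tailed,
            }
        )
    for label, table in tables or ():
        res = fisher_exact_two_tailed(table)
        rows.append(
            {
                "comparison": label,
                "method": res.method,
                "observed_k": table.a,
                "observed_n": table.a + table.b,
                "observed_fraction": round(table.a / (table.a + table.b), 4)
                if table.a + table.b
                else float("nan"),
                "baseline_fraction": round(table.c / (table.c + table.d), 4)
                if table.c + table.d
                else float("nan"),
                "odds_ratio": res.odds_ratio,
                "p_two_tailed": res.p_two_tailed,
            }
        )
    columns = [
        "comparison",
        "method",
        "observed_k",
        "observed_n",
        "observed_fraction",
        "baseline_fraction",
        "odds_ratio",
        "p_two_tailed",
    ]
    return pd.DataFrame(rows, columns=columns)
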