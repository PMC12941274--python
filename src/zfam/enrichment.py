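"""Hypergeometric over/under-representation tests with Benjamini-Hochberg
correction and the signed +/- lg(P) reporting convention.

Shared by the duplication analysis (tandem duplicates in a family vs the
genome) and GO-style set enrichment of differentially expressed genes.
Tail probabilities come from scipy's hypergeometric distribution (exact,
log-binomial based); the step-up BH procedure is implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ContingencyCounts:
    """Population of N with K successes; sample of n with k successes."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.K <= self.N
            and 0 <= self.n <= self.N
            and 0 <= self.k <= min(self.n, self.K)
        )
        if not ok:
            raise ValueError(
                f"invalid contingency counts N={self.N} K={self.K} n={self.n} k={self.k}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    counts: ContingencyCounts
    p_value: float
    q_value: float
    fold_enrichment: float
    direction: str  # 'enriched' or 'depleted'

    @property
    def signed_log10(self) -> float:
        sign = 1.0 if self.direction == "enriched" else -1.0
        return sign * -math.log10(self.p_value)


def hypergeom_upper(counts: ContingencyCounts) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))


def hypergeom_lower(counts: ContingencyCounts) -> float:
    """P(X <= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.cdf(counts.k, counts.N, counts.K, counts.n))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min_{j >= i} (m * p(j) / j) over ascending p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fold_enrichment(counts: ContingencyCounts) -> float:
    """(k/n) / (K/N); infinity when K = 0 and k > 0, NaN when k = K = 0."""
    if counts.K == 0:
        return math.inf if counts.k > 0 else math.nan
    return (counts.k / counts.n) / (counts.K / counts.N)


def directional_test(counts: ContingencyCounts) -> tuple[str, float]:
    """One-sided test in the observed direction.

    'enriched' (upper tail) iff fold enrichment > 1; otherwise 'depleted'
    (lower tail) — a fold of exactly 1 is tested as depleted.
    """
    fe = fold_enrichment(counts)
    if fe > 1:
        return "enriched", hypergeom_upper(counts)
    return "depleted", hypergeom_lower(counts)


def signed_score(direction: str, p_value: float) -> float:
    """+/- lg(P): -log10(p) signed + for enrichment, - for depletion."""
    sign = 1.0 if direction == "enriched" else -1.0
    return sign * -math.log10(p_value)


def test_term(term_id: str, counts: ContingencyCounts) -> tuple[str, float, float]:
    direction, p = directional_test(counts)
    return direction, p, fold_enrichment(counts)


def enrich_sets(
    study_set: set[str],
    population_annotations: dict[str, set[str]],
    q_max: float = 0.05,
    fe_min: float = 2.0,
    include_zero_study_terms: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Term enrichment of a study set against an annotated population.

    One directional hypergeometric test per term (by default only terms
    with at least one study-set gene, to avoid inflating the BH family),
    BH correction across all tested terms, and the reported subset passing
    q < q_max and fold enrichment > fe_min.

    Returns (filtered_table, full_table).
    """
    if not study_set:
        raise ValueError("empty study set")
    population = set(population_annotations)
    missing = study_set - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)[:5]}")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in population_annotations.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(population), len(study_set)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & study_set)
        if k == 0 and not include_zero_study_terms:
            continue
        counts = ContingencyCounts(N=N, K=len(genes), n=n, k=k)
        direction, p, fe = test_term(term, counts)
        rows.append(
            {
                "term_id": term, "k": k, "n": n, "K": counts.K, "N": N,
                "fold_enrichment": fe, "direction": direction, "p_value": p,
            }
        )
    if not rows:
        raise ValueError("no terms to test")
    full = pd.DataFrame(rows)
    full["q_value"] = bh_adjust(full["p_value"].to_numpy())
    full["signed_lgP"] = [
        signed_score(d, p) for d, p in zip(full["direction"], full["p_value"])
    ]
    full = full.sort_values(["q_value", "term_id"], kind="stable").reset_index(drop=True)
    filtered = full[(full["q_value"] < q_max) & (full["fold_enrichment"] > fe_min)]
    return filtered.reset_index(drop=True), full
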