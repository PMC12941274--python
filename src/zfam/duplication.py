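"""Duplicate-gene classification from an all-vs-all protein hit table.

Re-implements the rank-distance classifier used for gene-family
duplication studies: after filtering self-hits and weak hits, each gene is
assigned the highest-priority class its homology neighbourhood supports —
tandem (a homolog at adjacent gene rank on the same chromosome), proximal
(rank distance 2..proximal_max_rank), dispersed (any other homolog), or
singleton.  Whole-genome/segmental duplicates are not distinguished
(collinearity detection is out of scope), so priority is
tandem > proximal > dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneModel, HitRecord

CLASSES = ("singleton", "dispersed", "proximal", "tandem")


@dataclass(frozen=True)
class GeneRankIndex:
    """Gene order: per chromosome, genes sorted by start coordinate and
    assigned consecutive integer ranks 0..n-1."""

    chrom_of: dict[str, str]
    rank_of: dict[str, int]

    @classmethod
    def from_genes(cls, genes: list[GeneModel]) -> "GeneRankIndex":
        chrom_of: dict[str, str] = {}
        rank_of: dict[str, int] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda g: (g.start, g.gene_id))
            for rank, g in enumerate(lst):
                chrom_of[g.gene_id] = chrom
                rank_of[g.gene_id] = rank
        return cls(chrom_of=chrom_of, rank_of=rank_of)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rank_of


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    duplication_class: str
    witness: str | None  # a homolog justifying the class; None for singletons


def classify_duplicates(
    hits: list[HitRecord],
    gene_index: GeneRankIndex,
    e_max: float = 1e-5,
    proximal_max_rank: int = 10,
) -> list[DuplicationCall]:
    """Classify every indexed gene from the homology graph.

    Hits are kept when e_value < e_max; self-hits are dropped; the graph
    is undirected, so classification is invariant to query/subject swaps
    and to hit-row order.
    """
    neighbours: dict[str, set[str]] = {g: set() for g in gene_index.rank_of}
    for h in hits:
        if h.is_self_hit or h.e_value >= e_max:
            continue
        for gid in (h.query_id, h.subject_id):
            if gid not in gene_index:
                raise ValueError(f"hit-table gene {gid!r} absent from the gene index")
        neighbours[h.query_id].add(h.subject_id)
        neighbours[h.subject_id].add(h.query_id)

    calls = []
    for gene_id in sorted(gene_index.rank_of):
        chrom = gene_index.chrom_of[gene_id]
        rank = gene_index.rank_of[gene_id]
        best_class, witness = "singleton", None
        for other in sorted(neighbours[gene_id]):
            if gene_index.chrom_of[other] == chrom:
                dist = abs(gene_index.rank_of[other] - rank)
                if dist == 1:
                    cls = "tandem"
                elif 2 <= dist <= proximal_max_rank:
                    cls = "proximal"
                else:
                    cls = "dispersed"
            else:
                cls = "dispersed"
            if CLASSES.index(cls) > CLASSES.index(best_class):
                best_class, witness = cls, other
        calls.append(DuplicationCall(gene_id, best_class, witness))
    return calls


def duplication_summary(
    calls: list[DuplicationCall], subset: set[str] | None = None
) -> pd.DataFrame:
    """Per-class counts and fractions for a gene subset (default: all)."""
    if subset is not None:
        calls = [c for c in calls if c.gene_id in subset]
    if not calls:
        raise ValueError("empty gene subset in duplication summary")
    counts = {cls: 0 for cls in CLASSES}
    for c in calls:
        counts[c.duplication_class] += 1
    total = len(calls)
    df = pd.DataFrame(
        {
            "duplication_class": list(CLASSES),
            "count": [counts[c] for c in CLASSES],
            "fraction": [counts[c] / total for c in CLASSES],
        }
    )
    return df


def calls_table(calls: list[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "duplication_class": [c.duplication_class for c in calls],
            "witness": [c.witness or "." for c in calls],
        }
    )
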