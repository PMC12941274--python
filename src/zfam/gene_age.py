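"""Phylostratigraphic gene-age assignment.

A gene's age is the oldest taxonomic stratum containing a species with a
detectable homolog, where "detectable" means reciprocal alignment hits
with both E-values strictly below 1e-5.  The default ladder carries the
four grades used for tardigrade genomes: Cellular organisms > Eukaryota >
Metazoa > Tardigrada-specific.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

DEFAULT_LADDER_STRATA = (
    "Cellular organisms",
    "Eukaryota",
    "Metazoa",
    "Tardigrada-specific",
)


@dataclass(frozen=True)
class LineageLadder:
    """Ordered strata, oldest first, plus the youngest stratum shared
    between each panel species and the focal species."""

    strata: tuple[str, ...]
    species_stratum: dict[str, str]

    def __post_init__(self) -> None:
        bad = sorted(set(self.species_stratum.values()) - set(self.strata))
        if bad:
            raise ValueError(f"species mapped to strata not on the ladder: {bad}")

    def index(self, stratum: str) -> int:
        return self.strata.index(stratum)

    @property
    def youngest(self) -> str:
        return self.strata[-1]


@dataclass(frozen=True)
class ReciprocalEvidence:
    gene_id: str
    species_id: str
    e_forward: float
    e_reverse: float

    def __post_init__(self) -> None:
        if self.e_forward < 0 or self.e_reverse < 0:
            raise ValueError("E-values must be >= 0")


def call_homolog(evidence: ReciprocalEvidence, e_max: float = 1e-5) -> bool:
    """Homolog iff BOTH reciprocal E-values are strictly below e_max."""
    return evidence.e_forward < e_max and evidence.e_reverse < e_max


def assign_stratum(
    gene_id: str,
    evidence: list[ReciprocalEvidence],
    ladder: LineageLadder,
    e_max: float = 1e-5,
) -> str:
    """Oldest stratum containing a called homolog; the youngest stratum
    when no homolog is found outside the focal lineage."""
    best: int | None = None
    for ev in evidence:
        if ev.gene_id != gene_id:
            continue
        if ev.species_id not in ladder.species_stratum:
            raise ValueError(f"species {ev.species_id!r} absent from the ladder")
        if not call_homolog(ev, e_max):
            continue
        idx = ladder.index(ladder.species_stratum[ev.species_id])
        if best is None or idx < best:
            best = idx
    return ladder.strata[best] if best is not None else ladder.youngest


def assign_all(
    gene_ids: list[str],
    evidence: list[ReciprocalEvidence],
    ladder: LineageLadder,
    e_max: float = 1e-5,
) -> dict[str, str]:
    by_gene: dict[str, list[ReciprocalEvidence]] = {g: [] for g in gene_ids}
    for ev in evidence:
        if ev.gene_id in by_gene:
            by_gene[ev.gene_id].append(ev)
    return {
        g: assign_stratum(g, by_gene[g], ladder, e_max) for g in gene_ids
    }


def age_distribution(assignments: dict[str, str], ladder: LineageLadder) -> dict[str, int]:
    """Gene counts per stratum, in ladder order (zeros included)."""
    if not assignments:
        raise ValueError("no gene-age assignments to summarise")
    counts = Counter(assignments.values())
    unknown = sorted(set(counts) - set(ladder.strata))
    if unknown:
        raise ValueError(f"assignments carry strata not on the ladder: {unknown}")
    return {s: counts.get(s, 0) for s in ladder.strata}
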