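"""Gene-family membership logic.

Candidates are the union of evidence channels — a BLASTp search against
curated family sequences and three profile-HMM searches (seed model, full
model, database model), each with its own E-value threshold — then
validated by requiring the family domain to be confirmed by at least one
of four domain databases, minus an explicit exclusion list.  Upstream
searches are external; their hit tables are consumed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: channel -> default E-value threshold; a candidate passes its channel
#: when e_value <= threshold
DEFAULT_THRESHOLDS: dict[str, float] = {
    "blastp": 1e-5,
    "hmm_seed": 1e-2,
    "hmm_full": 1e-5,
    "hmm_pfam": 1e-2,
}

VALIDATION_SOURCES = ("CDD", "SMART", "Pfam", "InterPro")


@dataclass(frozen=True)
class CandidateEvidence:
    protein_id: str
    channel: str
    e_value: float

    def __post_init__(self) -> None:
        if self.channel not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown evidence channel {self.channel!r}")
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class ValidationRecord:
    protein_id: str
    source: str
    has_c4_domain: bool

    def __post_init__(self) -> None:
        if self.source not in VALIDATION_SOURCES:
            raise ValueError(f"unknown validation source {self.source!r}")


def select_longest_isoform(
    proteins: dict[str, list[tuple[str, int]]]
) -> dict[str, str]:
    """Representative protein per gene: longest wins, ties broken by
    lexicographically smallest protein id."""
    out = {}
    for gene, isoforms in proteins.items():
        if not isoforms:
            raise ValueError(f"gene {gene} has no protein isoforms")
        out[gene] = min(isoforms, key=lambda pl: (-pl[1], pl[0]))[0]
    return out


def merge_candidates(
    evidence: list[CandidateEvidence],
    thresholds: dict[str, float] | None = None,
) -> dict[str, set[str]]:
    """Union of proteins passing their channel's threshold (e <= t).

    Returns protein_id -> set of supporting channels; redundancy across
    channels collapses to one entry per protein.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown channels in thresholds: {sorted(unknown)}")
        if any(t <= 0 for t in thresholds.values()):
            raise ValueError("thresholds must be positive")
        thr.update(thresholds)
    out: dict[str, set[str]] = {}
    for ev in evidence:
        if ev.e_value <= thr[ev.channel]:
            out.setdefault(ev.protein_id, set()).add(ev.channel)
    return out


def validate_family(
    candidates: dict[str, set[str]],
    validation: list[ValidationRecord],
    exclusions: set[str] | None = None,
) -> pd.DataFrame:
    """Final family table: candidates confirmed by >= 1 validation source
    and not on the exclusion list, with full provenance.

    Columns: protein_id, channels, validated_by, status
    (kept / no_domain / manual).
    """
    exclusions = exclusions or set()
    seen: set[tuple[str, str]] = set()
    confirmed: dict[str, set[str]] = {}
    for rec in validation:
        key = (rec.protein_id, rec.source)
        if key in seen:
            raise ValueError(f"duplicate validation row for {key}")
        seen.add(key)
        if rec.has_c4_domain:
            confirmed.setdefault(rec.protein_id, set()).add(rec.source)
    rows = []
    for pid in sorted(candidates):
        sources = confirmed.get(pid, set())
        if pid in exclusions:
            status = "manual"
        elif not sources:
            status = "no_domain"
        else:
            status = "kept"
        rows.append(
            {
                "protein_id": pid,
                "channels": ",".join(sorted(candidates[pid])),
                "validated_by": ",".join(sorted(sources)) or ".",
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "channels", "validated_by", "status"])


def family_members(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["status"] == "kept", "protein_id"])
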