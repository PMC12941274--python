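"""Domain-distribution census across a focal species set versus a
reference panel.

For each domain accession, m is the fraction of distinct focal-set
proteins carrying the domain among all focal proteins carrying at least
one annotated domain ("domain proteins"); M is the analogous fraction over
the reference panel; p = m/M compares relative abundance.  Exclusivity
calls flag domains confined to a single superkingdom within the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SUPERKINGDOMS = ("Archaea", "Bacteria", "Eukaryota")


@dataclass(frozen=True)
class DomainCensusRow:
    domain_accession: str
    n_focal_proteins: int
    total_focal_domain_proteins: int
    m: float
    n_ref_proteins: int
    total_ref_domain_proteins: int
    M: float
    p: float | None  # None when M == 0 (undefined, not infinity)


def _validate_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"protein_id", "species_id", "domain_accession", "e_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if (df["e_value"] < 0).any():
        raise ValueError(f"{name} table contains negative e-values")
    return df


def filter_annotations(df: pd.DataFrame, e_max: float = 1e-2) -> pd.DataFrame:
    """Apply the domain-annotation E-value cutoff (keep e <= e_max) and
    deduplicate repeated (protein, domain) hits."""
    kept = df[df["e_value"] <= e_max]
    return kept.drop_duplicates(subset=["protein_id", "domain_accession"])


def compute_census(
    focal_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    domain_filter: set[str] | None = None,
    e_max: float = 1e-2,
    count_instances: bool = False,
) -> list[DomainCensusRow]:
    """Compute m, M and p = m/M per domain.

    Counting unit is the distinct protein carrying the domain (the
    denominator being proteins with any annotated domain); pass
    ``count_instances=True`` for the raw-instance reading of the
    numerator.
    """
    focal = filter_annotations(_validate_table(focal_table, "focal"), e_max)
    ref = filter_annotations(_validate_table(reference_table, "reference"), e_max)
    if focal.empty:
        raise ValueError("focal table empty after E-value filtering")
    if ref.empty:
        raise ValueError("reference table empty after E-value filtering")

    def numerators(df: pd.DataFrame, raw: pd.DataFrame) -> dict[str, int]:
        if count_instances:
            sub = raw[raw["e_value"] <= e_max]
            return sub.groupby("domain_accession").size().to_dict()
        return df.groupby("domain_accession")["protein_id"].nunique().to_dict()

    focal_n = numerators(focal, focal_table)
    ref_n = numerators(ref, reference_table)
    total_focal = focal["protein_id"].nunique()
    total_ref = ref["protein_id"].nunique()

    domains = set(focal_n) | set(ref_n)
    if domain_filter is not None:
        domains &= set(domain_filter)
    rows = []
    for d in domains:
        nf = focal_n.get(d, 0)
        nr = ref_n.get(d, 0)
        m = nf / total_focal
        M = nr / total_ref
        p = (m / M) if M > 0 else None
        rows.append(
            DomainCensusRow(
                domain_accession=d,
                n_focal_proteins=nf,
                total_focal_domain_proteins=total_focal,
                m=m,
                n_ref_proteins=nr,
                total_ref_domain_proteins=total_ref,
                M=M,
                p=p,
            )
        )
    rows.sort(key=lambda r: (-r.n_focal_proteins, r.domain_accession))
    return rows


def find_exclusive_domains(
    reference_table: pd.DataFrame,
    grouping: dict[str, str],
    e_max: float = 1e-2,
) -> dict[str, str]:
    """Domains present in exactly one superkingdom within the panel.

    Returns domain_accession -> superkingdom.  A domain is exclusive to K
    iff at least one panel protein in K carries it and none outside K
    does.  Every panel species must be mapped to a superkingdom.
    """
    ref = filter_annotations(_validate_table(reference_table, "reference"), e_max)
    unmapped = sorted(set(ref["species_id"]) - set(grouping))
    if unmapped:
        raise ValueError(f"species without superkingdom mapping: {unmapped}")
    bad = sorted(set(grouping.values()) - set(SUPERKINGDOMS))
    if bad:
        raise ValueError(f"unknown superkingdoms in grouping: {bad}")
    ref = ref.assign(superkingdom=ref["species_id"].map(grouping))
    out = {}
    for domain, sub in ref.groupby("domain_accession"):
        kingdoms = set(sub["superkingdom"])
        if len(kingdoms) == 1:
            out[str(domain)] = next(iter(kingdoms))
    return out


def census_table(rows: list[DomainCensusRow], exclusivity: dict[str, str] | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain_accession": [r.domain_accession for r in rows],
            "n_focal": [r.n_focal_proteins for r in rows],
            "m": [r.m for r in rows],
            "n_reference": [r.n_ref_proteins for r in rows],
            "M": [r.M for r in rows],
            "p": [r.p if r.p is not None else float("nan") for r in rows],
            "p_defined": [r.p is not None for r in rows],
            "exclusive_to": [
                (exclusivity or {}).get(r.domain_accession, ".") for r in rows
            ],
        }
    )
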