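"""Physicochemical characterization of family proteins.

Molecular weight (average residue masses), the Kyte-Doolittle GRAVY score
with the hydrophilic/hydrophobic binary, and the Guruprasad instability
index with the conventional stable/unstable threshold of 40.  Mass,
hydropathy and dipeptide-weight tables come from Biopython's ProtParam
data (the same tables the ExPASy web calculator uses); the instability
formula is evaluated here so that the weight table is injectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import ProtParamData
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._codon import translate_cds

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
WATER_MASS = 18.0153
INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    cds_length: int | None
    protein_length: int
    molecular_weight: float
    gravy: float
    hydropathy_class: str  # hydrophilic iff gravy < 0
    instability_index: float
    stability_class: str  # unstable iff index > 40


def _check_sequence(sequence: str, min_length: int = 1) -> str:
    seq = sequence.upper()
    if len(seq) < min_length:
        raise ValueError(f"sequence shorter than {min_length} residues")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Da: residue masses plus one water."""
    seq = _check_sequence(sequence)
    return float(ProteinAnalysis(seq).molecular_weight())


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    seq = _check_sequence(sequence)
    return float(ProteinAnalysis(seq).gravy())


def hydropathy_class(gravy_value: float) -> str:
    """Strictly negative GRAVY is hydrophilic; zero falls on the
    hydrophobic side of the binary."""
    return "hydrophilic" if gravy_value < 0 else "hydrophobic"


def instability_index(sequence: str, weights: dict | None = None) -> float:
    """(10/L) * sum of the L-1 ordered-dipeptide instability weights.

    ``weights`` is a nested residue->residue->value table; the default is
    the published DIWV table.  The table is asymmetric, so the value is
    order-sensitive.
    """
    seq = _check_sequence(sequence, min_length=2)
    table = weights if weights is not None else ProtParamData.DIWV
    total = sum(table[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def stability_class(index: float) -> str:
    return "unstable" if index > INSTABILITY_THRESHOLD else "stable"


def characterize(
    protein_id: str, sequence: str, cds: str | None = None
) -> ProteinProperties:
    """All properties of one protein; if its CDS is supplied, the
    CDS/protein length consistency (3L or 3L+3 with terminal stop) is
    verified and the CDS length recorded."""
    seq = _check_sequence(sequence, min_length=2)
    cds_length = None
    if cds is not None:
        if translate_cds(cds) != seq:
            raise ValueError(f"{protein_id}: CDS does not translate to the protein")
        cds_length = len(cds)
    g = gravy(seq)
    ii = instability_index(seq)
    return ProteinProperties(
        protein_id=protein_id,
        cds_length=cds_length,
        protein_length=len(seq),
        molecular_weight=molecular_weight(seq),
        gravy=g,
        hydropathy_class=hydropathy_class(g),
        instability_index=ii,
        stability_class=stability_class(ii),
    )


def properties_table(props: list[ProteinProperties]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in props],
            "cds_length": [p.cds_length for p in props],
            "protein_length": [p.protein_length for p in props],
            "molecular_weight": [p.molecular_weight for p in props],
            "gravy": [p.gravy for p in props],
            "hydropathy_class": [p.hydropathy_class for p in props],
            "instability_index": [p.instability_index for p in props],
            "stability_class": [p.stability_class for p in props],
        }
    )
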