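"""Shared nucleotide / codon helpers.

The standard genetic code is taken from Biopython's codon table so that
every module (simulation, Ka/Ks counting, back-translation) agrees on a
single source of truth.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard code

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
BASES = "ACGT"

#: codon -> one-letter amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; terminal stop tolerated.

    Raises ValueError on length not divisible by 3, internal stops, or
    codons containing non-ACGT letters.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    aas = []
    n = len(cds) // 3
    for i in range(n):
        codon = cds[3 * i : 3 * i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"unrecognised codon {codon!r} at codon index {i}")
        if aa == "*":
            if i != n - 1:
                raise ValueError(f"internal stop codon {codon} at codon index {i}")
            break
        aas.append(aa)
    return "".join(aas)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
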