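"""Promoter extraction and cis-element scanning.

The workflow mirrors the standard JASPAR-based promoter analysis: take the
2000 bp immediately upstream of a gene's annotated start codon (strand
aware), collapse each position frequency matrix to an IUPAC degenerate
consensus, compile the consensus to a character-class regular expression,
and count non-overlapping occurrences in each promoter.

Counting policy: non-overlapping, left-to-right, on the extracted strand
only — the behaviour of ``gregexpr``-style scanning.  Overlapping counting
and both-strand scanning are available as keyword switches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._codon import revcomp
from .io_formats import AnnotatedGenome, GeneModel, PFMRecord

IUPAC_TO_CLASS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

#: IUPAC code -> the base set it denotes
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(cls.strip("[]")) for code, cls in IUPAC_TO_CLASS.items()
}

_BASES_TO_IUPAC = {bases: code for code, bases in IUPAC_TO_BASES.items()}


@dataclass(frozen=True)
class PromoterSequence:
    """An extracted upstream window.

    ``interval`` is the source span on the plus strand of ``chrom``,
    1-based inclusive; for minus-strand genes ``sequence`` is the reverse
    complement of that span.  ``truncated`` marks windows clipped at a
    chromosome boundary.
    """

    gene_id: str
    sequence: str
    truncated: bool
    chrom: str
    interval: tuple[int, int]
    strand: str


@dataclass(frozen=True)
class MotifPattern:
    motif_id: str
    iupac: str
    regex: re.Pattern

    @property
    def length(self) -> int:
        return len(self.iupac)


def extract_upstream(
    gene: GeneModel, genome: AnnotatedGenome | dict[str, str], window: int = 2000
) -> PromoterSequence:
    """Extract up to ``window`` bp upstream of the gene's start codon.

    The anchor is the strand-aware first CDS base of the longest-CDS
    transcript.  A gene whose start codon sits at the chromosome edge
    yields a shorter (possibly empty) promoter flagged ``truncated``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seqs = genome.sequences if isinstance(genome, AnnotatedGenome) else genome
    chrom_seq = seqs[gene.chrom]
    anchor = gene.start_codon_position()
    if gene.strand == "+":
        lo = max(0, anchor - window)
        hi = anchor
        seq = chrom_seq[lo:hi]
    else:
        lo = anchor + 1
        hi = min(len(chrom_seq), anchor + 1 + window)
        seq = revcomp(chrom_seq[lo:hi])
    return PromoterSequence(
        gene_id=gene.gene_id,
        sequence=seq,
        truncated=len(seq) < window,
        chrom=gene.chrom,
        interval=(lo + 1, hi),
        strand=gene.strand,
    )


def pfm_to_degenerate_consensus(pfm: PFMRecord) -> str:
    """Collapse a PFM column-by-column to an IUPAC degenerate consensus.

    Cavener-style rule per column (counts sorted descending c1..c4,
    total T): the single top base if c1 > T/2 and c1 > 2*c2; else the
    two-base code if c1 + c2 > (3/4)*T; else the three-base code if the
    least base is absent; else N.  Ties are broken in A,C,G,T order.
    """
    out = []
    for col in range(pfm.length):
        counts = pfm.counts[:, col]
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"motif {pfm.motif_id}: all-zero column {col}")
        order = sorted(range(4), key=lambda i: (-counts[i], i))
        c = counts[order]
        bases = ["ACGT"[i] for i in order]
        if c[0] > total / 2 and c[0] > 2 * c[1]:
            out.append(bases[0])
        elif c[0] + c[1] > 0.75 * total:
            out.append(_BASES_TO_IUPAC[frozenset(bases[:2])])
        elif c[3] == 0:
            out.append(_BASES_TO_IUPAC[frozenset(bases[:3])])
        else:
            out.append("N")
    return "".join(out)


def iupac_to_pattern(iupac: str, motif_id: str | None = None) -> MotifPattern:
    """Compile an IUPAC degenerate string to a validated regex pattern.

    Every code maps to its character class (R -> [AG], ..., N -> [ACGT]);
    an ``N`` in the scanned sequence therefore never matches any pattern
    position.
    """
    if not iupac:
        raise ValueError("empty IUPAC string")
    parts = []
    for pos, ch in enumerate(iupac.upper()):
        cls = IUPAC_TO_CLASS.get(ch)
        if cls is None:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {pos}")
        parts.append(cls)
    regex = re.compile("".join(parts))
    return MotifPattern(motif_id=motif_id or iupac, iupac=iupac.upper(), regex=regex)


def count_occurrences(
    promoter: PromoterSequence | str, pattern: MotifPattern, overlapping: bool = False
) -> int:
    """Count pattern matches in a promoter.

    Default is non-overlapping left-to-right greedy counting;
    ``overlapping=True`` counts every start position that matches.
    """
    seq = promoter if isinstance(promoter, str) else promoter.sequence
    seq = seq.upper()
    if not overlapping:
        return sum(1 for _ in pattern.regex.finditer(seq))
    count = 0
    pos = 0
    while True:
        m = pattern.regex.search(seq, pos)
        if m is None:
            return count
        count += 1
        pos = m.start() + 1


def scan_all(
    promoters: list[PromoterSequence],
    patterns: list[MotifPattern],
    overlapping: bool = False,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Count every pattern in every promoter.

    Returns a genes x motifs integer DataFrame plus a boolean column
    ``any_element`` marking genes carrying at least one element of any
    type.  ``both_strands=True`` adds reverse-complement-strand matches.
    """
    data = {}
    for pat in patterns:
        col = []
        for prom in promoters:
            n = count_occurrences(prom, pat, overlapping=overlapping)
            if both_strands:
                rc = revcomp(prom.sequence)
                n += count_occurrences(rc, pat, overlapping=overlapping)
            col.append(n)
        data[pat.motif_id] = col
    mat = pd.DataFrame(data, index=[p.gene_id for p in promoters], dtype=int)
    mat.index.name = "gene_id"
    mat["any_element"] = mat.sum(axis=1) > 0 if patterns else False
    return mat


def read_jaspar_patterns(path: str) -> list[MotifPattern]:
    """JASPAR file -> degenerate consensi -> compiled scan patterns."""
    from .io_formats import read_jaspar

    return [
        iupac_to_pattern(pfm_to_degenerate_consensus(pfm), motif_id=pfm.motif_name)
        for pfm in read_jaspar(path)
    ]


def load_packaged_elements() -> list[MotifPattern]:
    """The packaged set of 20 nematode stress-response cis-elements
    (JASPAR CORE degenerate consensi), as compiled patterns."""
    with resources.files("zfam.data").joinpath("nematode_elements.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [iupac_to_pattern(row.iupac, motif_id=row.element) for row in df.itertuples()]
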