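"""Readers and writers for the standard formats the pipeline touches.

Coordinate contract
-------------------
External files (GFF3, result tables) are 1-based inclusive, as the formats
prescribe.  Everything held in memory is 0-based half-open.  The conversion
happens here and only here, so there is a single place to audit off-by-one
errors: ``start_1based = start0 + 1``, ``end_1based = end0``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from ._codon import revcomp

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

__all__ = [
    "GeneModel",
    "Transcript",
    "HitRecord",
    "PFMRecord",
    "AnnotatedGenome",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_jaspar",
    "read_hit_table",
    "write_hit_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    protein_id: str
    #: CDS segments, 0-based half-open, ascending genomic order
    cds: tuple[tuple[int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: coordinates plus its transcripts.

    ``start``/``end`` are 0-based half-open on ``chrom``; ``strand`` is
    exactly '+' or '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}..{self.end}")
        for tr in self.transcripts:
            for s, e in tr.cds:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS segment [{s},{e}) outside gene span"
                    )

    def longest_transcript(self) -> Transcript:
        """The representative isoform: longest CDS, ties by smallest id."""
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return min(self.transcripts, key=lambda t: (-t.cds_length, t.transcript_id))

    def start_codon_position(self) -> int:
        """0-based genomic position of the first base of the start codon
        of the longest-CDS transcript (strand-aware)."""
        tr = self.longest_transcript()
        if not tr.cds:
            raise ValueError(f"gene {self.gene_id}: transcript {tr.transcript_id} has no CDS")
        if self.strand == "+":
            return min(s for s, _ in tr.cds)
        return max(e for _, e in tr.cds) - 1

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS of the longest transcript, in reading orientation."""
        tr = self.longest_transcript()
        parts = [chrom_seq[s:e] for s, e in sorted(tr.cds)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular alignment file (extra columns ignored)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.query_id}/{self.subject_id}")

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.subject_id


@dataclass(frozen=True)
class PFMRecord:
    """A position frequency matrix: 4 x L counts over A,C,G,T."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # shape (4, L), row order A,C,G,T

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative count")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: column with no positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene models — the substrate of every
    genomic stage (promoter extraction, duplication ranks, CDS export)."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.sequences}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: frozenset[str] | None = None) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map.

    Record ids are the first whitespace-delimited token.  Duplicate ids and
    empty files are errors.  ``alphabet`` optionally restricts the residue
    set (pass :data:`NUCLEOTIDE_ALPHABET` for genome files).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: letters outside allowed alphabet: {sorted(bad)}"
                )
        out[rec.id] = seq
    if not out:
        raise ValueError(f"empty FASTA file: {path}")
    return out


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file into GeneModels.

    Coordinates are converted from the file's 1-based inclusive convention
    to internal 0-based half-open.  Referential integrity (every mRNA's
    Parent is a gene, every CDS's Parent an mRNA) is enforced.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    gene_ids = {f.id for f in db.features_of_type("gene")}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        for p in parents:
            if p not in gene_ids:
                raise ValueError(f"mRNA {mrna.id} has Parent {p!r} which is not a gene")
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id}: unknown strand {feat.strand!r}")
        transcripts = []
        for mrna in db.children(feat, featuretype="mRNA"):
            segs = []
            protein_id = mrna.attributes.get("protein_id", [mrna.id + ".p"])[0]
            for cds in db.children(mrna, featuretype="CDS"):
                s0, e0 = cds.start - 1, cds.end  # 1-based incl -> 0-based half-open
                if s0 < feat.start - 1 or e0 > feat.end:
                    raise ValueError(
                        f"CDS of {mrna.id} at {cds.start}..{cds.end} outside gene "
                        f"{feat.id} span {feat.start}..{feat.end}"
                    )
                segs.append((s0, e0))
            transcripts.append(
                Transcript(mrna.id, protein_id, tuple(sorted(segs)))
            )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                transcripts=tuple(transcripts),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels back to GFF3 (1-based inclusive), round-trip safe."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tzfam\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tr in g.transcripts:
                fh.write(
                    f"{g.chrom}\tzfam\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={tr.transcript_id};Parent={g.gene_id};protein_id={tr.protein_id}\n"
                )
                for s, e in tr.cds:
                    fh.write(
                        f"{g.chrom}\tzfam\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={tr.transcript_id}.cds;Parent={tr.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# JASPAR
# ---------------------------------------------------------------------------

def read_jaspar(path: str | os.PathLike) -> list[PFMRecord]:
    """Read JASPAR-format position frequency matrices.

    Uses Biopython's JASPAR parser; the resulting matrices are validated
    (4 complete rows, equal lengths, non-negative counts, every column with
    at least one positive count).
    """
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # malformed rows, missing bases, bad numbers
        raise ValueError(f"cannot parse JASPAR file {path}: {exc}") from exc
    records = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        records.append(
            PFMRecord(
                motif_id=m.matrix_id or m.name,
                motif_name=m.name or m.matrix_id,
                counts=counts,
            )
        )
    if not records:
        raise ValueError(f"no motifs found in {path}")
    return records


# ---------------------------------------------------------------------------
# 12-column tabular alignment (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


def read_hit_table(path: str | os.PathLike) -> list[HitRecord]:
    """Read a 12-column tabular alignment file; extra columns are ignored."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 tab-separated columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = _HIT_COLUMNS
    records = []
    for row in df.itertuples(index=False):
        try:
            e_value = float(row.e_value)
            pct = float(row.percent_identity)
            alen = int(row.alignment_length)
            bits = float(row.bit_score)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric field in row {tuple(row)}") from exc
        records.append(HitRecord(row.query_id, row.subject_id, pct, alen, e_value, bits))
    return records


def write_hit_table(hits: list[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            alen = h.alignment_length
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t{alen}"
                f"\t0\t0\t1\t{alen}\t1\t{alen}\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )
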