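"""Synthetic genomes with a known truth ledger.

Everything downstream of external tools (genomes, annotations, hit
tables, promoters with planted motifs, codon pairs diverged at a
controlled dN/dS, reciprocal homolog evidence, differential-expression
tables) can be generated here with full determinism, so every analysis
stage is testable without downloads.  The ledger records exactly what was
planted; every entry is verifiable from the emitted files alone.

Randomness: one ``numpy`` Generator stream per operation, derived from
the master seed by a stable integer label, so adding a stage never
perturbs the draws of an earlier one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from ._codon import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, revcomp
from .io_formats import (
    AnnotatedGenome,
    GeneModel,
    HitRecord,
    Transcript,
    write_fasta,
    write_gff3,
    write_hit_table,
)
from .promoter_cis import IUPAC_TO_BASES, extract_upstream

# stable RNG stream labels (see module docstring)
_STREAM_GENOME = 11
_STREAM_FAMILY = 23
_STREAM_MOTIF = 37
_STREAM_CODON = 41
_STREAM_HOMOLOG = 53
_STREAM_DE = 67
_STREAM_EVIDENCE = 79


def _rng(seed: int, label: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), label, extra])


# ---------------------------------------------------------------------------
# truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Serialized record of everything the generator planted."""

    seed: int
    planted_families: dict[str, list[str]] = field(default_factory=dict)
    planted_duplication: dict[str, str] = field(default_factory=dict)
    #: gene_id -> motif_id -> verified planted count
    planted_motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_omega: dict[str, float] = field(default_factory=dict)
    planted_strata: dict[str, str] = field(default_factory=dict)
    planted_de: dict[str, str] = field(default_factory=dict)

    def validate(self, genome: AnnotatedGenome | None = None) -> None:
        for counts in self.planted_motif_counts.values():
            if any(c < 0 for c in counts.values()):
                raise ValueError("negative planted motif count")
        if any(w <= 0 for w in self.planted_omega.values()):
            raise ValueError("planted omega must be > 0")
        if genome is not None:
            known = {g.gene_id for g in genome.genes}
            for fam, members in self.planted_families.items():
                missing = set(members) - known
                if missing:
                    raise ValueError(
                        f"family {fam}: planted genes missing from genome: {sorted(missing)}"
                    )

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "TruthLedger":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    n_chrom: int = 3
    genes_per_chrom: int = 40
    gene_len_bp: int = 300
    intergenic_bp: int = 2200
    gc_fraction: float = 0.42

    def __post_init__(self) -> None:
        for name in ("n_chrom", "genes_per_chrom", "gene_len_bp", "intergenic_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one internal, stop)")
    internal = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(internal) + str(stop)


def _single_exon_gene(
    gene_id: str, chrom: str, start: int, cds: str, strand: str
) -> GeneModel:
    end = start + len(cds)
    tr = Transcript(f"{gene_id}.t1", f"{gene_id}.p1", ((start, end),))
    return GeneModel(gene_id, chrom, start, end, strand, (tr,))


def simulate_genome(
    config: GenomeConfig | dict | None = None, seed: int = 0
) -> tuple[AnnotatedGenome, TruthLedger]:
    """Multi-chromosome genome of non-overlapping, strand-alternating
    single-exon genes separated by iid intergenic background.

    Every CDS begins with ATG, ends with a stop, has no internal stop and
    a length divisible by 3.  Deterministic given (config, seed).
    """
    if config is None:
        config = GenomeConfig()
    elif isinstance(config, dict):
        config = GenomeConfig(**config)
    rng = _rng(seed, _STREAM_GENOME)
    n_codons = max(3, config.gene_len_bp // 3)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        parts = [_background(rng, config.intergenic_bp, config.gc_fraction)]
        pos = config.intergenic_bp
        for gi in range(config.genes_per_chrom):
            gene_id = f"{chrom}_g{gi + 1:03d}"
            strand = "+" if gi % 2 == 0 else "-"
            cds = _random_cds(rng, n_codons)
            body = cds if strand == "+" else revcomp(cds)
            genes.append(_single_exon_gene(gene_id, chrom, pos, cds=body, strand=strand))
            parts.append(body)
            pos += len(body)
            spacer = _background(rng, config.intergenic_bp, config.gc_fraction)
            parts.append(spacer)
            pos += len(spacer)
        sequences[chrom] = "".join(parts)
    genome = AnnotatedGenome(sequences=sequences, genes=genes)
    ledger = TruthLedger(seed=seed)
    ledger.validate(genome)
    return genome, ledger


# ---------------------------------------------------------------------------
# family planting
# ---------------------------------------------------------------------------

def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Per-site substitution at ``rate``; the start codon, the stop codon
    and any codon that a mutation would turn into a stop are left as-is."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    out = [codons[0]]
    for codon in codons[1:-1]:
        new = list(codon)
        for j in range(3):
            if rng.random() < rate:
                new[j] = rng.choice([b for b in BASES if b != new[j]])
        cand = "".join(new)
        out.append(codon if cand in STOP_CODONS else cand)
    out.append(codons[-1])
    return "".join(out)


def _insert_gene_after(
    genome: AnnotatedGenome,
    chrom: str,
    after_rank: int,
    gene_id: str,
    cds: str,
    strand: str,
    spacer: str,
) -> AnnotatedGenome:
    """Splice (spacer + gene body) into the chromosome right after the
    gene at ``after_rank``, shifting everything downstream."""
    by_chrom = genome.genes_by_chrom()
    anchor = by_chrom[chrom][after_rank]
    breakpoint = anchor.end
    body = cds if strand == "+" else revcomp(cds)
    segment = spacer + body
    new_start = breakpoint + len(spacer)
    seq = genome.sequences[chrom]
    new_seq = seq[:breakpoint] + segment + seq[breakpoint:]
    shift = len(segment)
    new_genes: list[GeneModel] = []
    for g in genome.genes:
        if g.chrom == chrom and g.start >= breakpoint:
            moved = [
                Transcript(t.transcript_id, t.protein_id,
                           tuple((s + shift, e + shift) for s, e in t.cds))
                for t in g.transcripts
            ]
            new_genes.append(
                replace(g, start=g.start + shift, end=g.end + shift,
                        transcripts=tuple(moved))
            )
        else:
            new_genes.append(g)
    new_genes.append(_single_exon_gene(gene_id, chrom, new_start, body, strand))
    sequences = dict(genome.sequences)
    sequences[chrom] = new_seq
    return AnnotatedGenome(sequences=sequences, genes=new_genes)


def expected_duplication_classes(
    genome: AnnotatedGenome, families: dict[str, list[str]]
) -> dict[str, str]:
    """Ground-truth duplication classes derived directly from the planted
    geometry (no homology graph): for each family member, the smallest
    gene-rank distance to another member on the same chromosome decides
    tandem (1) / proximal (2..10) / dispersed (other member anywhere
    else); genes outside every family are singletons."""
    rank = {}
    for chrom, lst in genome.genes_by_chrom().items():
        for r, g in enumerate(lst):
            rank[g.gene_id] = (chrom, r)
    classes = {g.gene_id: "singleton" for g in genome.genes}
    for members in families.values():
        for gid in members:
            chrom, r = rank[gid]
            dists = [
                abs(rank[o][1] - r)
                for o in members
                if o != gid and rank[o][0] == chrom
            ]
            if dists and min(dists) == 1:
                classes[gid] = "tandem"
            elif dists and min(dists) <= 10:
                classes[gid] = "proximal"
            elif len(members) > 1:
                classes[gid] = "dispersed"
        # lone 'members' lists of size 1 stay singleton
    return classes


def plant_family(
    genome: AnnotatedGenome,
    ledger: TruthLedger,
    family_id: str,
    layout: list[str],
    founder_gene_id: str | None = None,
    mutation_rate: float = 0.0,
    intergenic_bp: int = 2200,
    gc_fraction: float = 0.42,
    seed: int = 0,
) -> tuple[AnnotatedGenome, list[HitRecord], TruthLedger]:
    """Plant a gene family: a founder plus one copy per layout entry.

    Layout entries: ``tandem`` (adjacent gene rank, same chromosome),
    ``proximal`` (rank distance 2..10 from the most recently planted
    same-chromosome member), ``dispersed`` (a chromosome carrying no other
    member of this family).  Copies are point-mutated at ``mutation_rate``
    per site.  The returned hit table connects exactly the family members
    (both directions, e=1e-30) plus their self-hits.

    Duplication ground truth for the whole genome is refreshed from the
    final geometry after planting (see :func:`expected_duplication_classes`).
    """
    if not 0 <= mutation_rate < 0.2:
        raise ValueError("mutation_rate must lie in [0, 0.2)")
    bad = set(layout) - {"tandem", "proximal", "dispersed"}
    if bad:
        raise ValueError(f"unknown layout entries: {sorted(bad)}")
    rng = _rng(ledger.seed, _STREAM_FAMILY, seed)
    by_chrom = genome.genes_by_chrom()
    if founder_gene_id is None:
        # founder on the chromosome with the most genes, away from edges
        chrom = max(by_chrom, key=lambda c: len(by_chrom[c]))
        founder_gene_id = by_chrom[chrom][len(by_chrom[chrom]) // 2].gene_id
    founder = genome.gene(founder_gene_id)
    founder_cds = founder.cds_sequence(genome.sequences[founder.chrom])
    members = [founder_gene_id]
    for i, kind in enumerate(layout):
        copy_id = f"{family_id}_c{i + 1}"
        cds = _mutate_cds(rng, founder_cds, mutation_rate)
        spacer = _background(rng, intergenic_bp, gc_fraction)
        by_chrom = genome.genes_by_chrom()
        member_chroms = {genome.gene(m).chrom for m in members}
        if kind == "tandem":
            anchor = members[-1] if genome.gene(members[-1]).chrom == founder.chrom else founder_gene_id
            chrom = genome.gene(anchor).chrom
            after = _rank_of(by_chrom, chrom, anchor)
            strand = genome.gene(anchor).strand
        elif kind == "proximal":
            same = [m for m in members if genome.gene(m).chrom == founder.chrom]
            chrom = founder.chrom
            last = same[-1]
            base_rank = _rank_of(by_chrom, chrom, last)
            n_on_chrom = len(by_chrom[chrom])
            max_gap = min(10, n_on_chrom - 1 - base_rank)
            if max_gap < 2:
                raise ValueError(
                    f"no room for a proximal copy after {last} on {chrom}"
                )
            gap = int(rng.integers(2, max_gap + 1))
            after = base_rank + gap - 1
            strand = "+" if rng.random() < 0.5 else "-"
        else:  # dispersed
            free = sorted(set(by_chrom) - member_chroms)
            if not free:
                raise ValueError(
                    "dispersed copy needs a chromosome without family members"
                )
            chrom = free[int(rng.integers(0, len(free)))]
            after = int(rng.integers(0, len(by_chrom[chrom])))
            strand = "+" if rng.random() < 0.5 else "-"
        genome = _insert_gene_after(
            genome, chrom, after, copy_id, cds, strand, spacer
        )
        members.append(copy_id)

    hits: list[HitRecord] = []
    for m in members:
        hits.append(HitRecord(m, m, 100.0, len(founder_cds) // 3, 0.0, 500.0))
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            for q, s in ((a, b), (b, a)):
                hits.append(
                    HitRecord(q, s, 98.0, len(founder_cds) // 3, 1e-30, 400.0)
                )
    ledger.planted_families[family_id] = members
    ledger.planted_duplication = expected_duplication_classes(
        genome, ledger.planted_families
    )
    ledger.validate(genome)
    return genome, hits, ledger


def _rank_of(by_chrom: dict[str, list[GeneModel]], chrom: str, gene_id: str) -> int:
    for r, g in enumerate(by_chrom[chrom]):
        if g.gene_id == gene_id:
            return r
    raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# promoter motif planting
# ---------------------------------------------------------------------------

def naive_motif_count(sequence: str, iupac: str) -> int:
    """Brute-force sliding-window, non-overlapping greedy count of an
    IUPAC word.  Independent of the regex scanner — used to verify what
    was actually planted, and as an oracle in tests."""
    sets = [IUPAC_TO_BASES[c] for c in iupac.upper()]
    L = len(sets)
    seq = sequence.upper()
    i = count = 0
    while i + L <= len(seq):
        if all(seq[i + j] in sets[j] for j in range(L)):
            count += 1
            i += L
        else:
            i += 1
    return count


def _realize_iupac(rng: np.random.Generator, iupac: str) -> str:
    return "".join(
        str(rng.choice(sorted(IUPAC_TO_BASES[c]))) for c in iupac.upper()
    )


def _upstream_span(
    gene: GeneModel, chrom_len: int, window: int
) -> tuple[int, int]:
    """Absolute plus-strand interval [lo, hi) the extracted promoter of
    ``gene`` reads from."""
    anchor = gene.start_codon_position()
    if gene.strand == "+":
        return max(0, anchor - window), anchor
    return anchor + 1, min(chrom_len, anchor + 1 + window)


def plant_promoter_motifs(
    genome: AnnotatedGenome,
    ledger: TruthLedger,
    motif_instances: dict[tuple[str, str], int],
    window: int = 2000,
    max_attempts: int = 20,
    seed: int = 0,
) -> tuple[AnnotatedGenome, TruthLedger]:
    """Write concrete realizations of IUPAC words into upstream windows.

    ``motif_instances`` maps (gene_id, iupac_string) -> requested count.
    Words are placed non-overlapping inside each gene's upstream window
    (which must lie in intergenic sequence; neighbouring windows may share
    intergenic ground, so placements are tracked genome-wide and never
    collide).  After every word is written, each promoter is re-counted
    with the brute-force scanner; if a spurious background match desyncs
    any count the whole placement is redrawn, and the ledger records the
    verified count — for textually coupled motifs (one word containing
    another) the verified count is the truth even when it differs from
    the request.
    """
    per_gene: dict[str, dict[str, int]] = {}
    for (gene_id, iupac), count in motif_instances.items():
        if count < 0:
            raise ValueError("negative requested count")
        per_gene.setdefault(gene_id, {})[iupac.upper()] = count

    # precompute windows and fail fast on impossible requests
    spans: dict[str, tuple[int, int]] = {}
    for gene_id, wants in sorted(per_gene.items()):
        gene = genome.gene(gene_id)
        lo, hi = _upstream_span(gene, len(genome.sequences[gene.chrom]), window)
        for other in genome.genes:
            if other.gene_id != gene_id and other.chrom == gene.chrom:
                if other.start < hi and other.end > lo:
                    raise ValueError(
                        f"upstream window of {gene_id} overlaps gene {other.gene_id}"
                    )
        total_len = sum(len(iu) * c for iu, c in wants.items())
        if total_len > hi - lo:
            raise ValueError(
                f"{gene_id}: requested motifs ({total_len} bp) exceed the "
                f"available upstream window ({hi - lo} bp)"
            )
        spans[gene_id] = (lo, hi)

    rng = _rng(ledger.seed, _STREAM_MOTIF, seed)
    sequences = dict(genome.sequences)
    claimed: dict[str, list[tuple[int, int]]] = {}

    # plant the requested words at globally non-colliding positions
    for gene_id, wants in sorted(per_gene.items()):
        gene = genome.gene(gene_id)
        lo, hi = spans[gene_id]
        taken = claimed.setdefault(gene.chrom, [])
        buf = list(sequences[gene.chrom])
        for iupac, count in sorted(wants.items()):
            for _ in range(count):
                word = _realize_iupac(rng, iupac)
                abs_interval = _claim_offset(rng, len(word), lo, hi, taken)
                if abs_interval is None:
                    raise ValueError(
                        f"{gene_id}: could not place motifs without overlap"
                    )
                a, b = abs_interval
                buf[a:b] = word if gene.strand == "+" else revcomp(word)
        sequences[gene.chrom] = "".join(buf)

    # scrub spurious background matches until every count verifies:
    # mutate one base inside each excess match, never touching a planted
    # word, and re-verify (a scrub can create a new match elsewhere, hence
    # the loop)
    verified: dict[str, dict[str, int]] = {}
    for _ in range(max_attempts):
        probe = AnnotatedGenome(sequences=sequences, genes=genome.genes)
        clean = True
        for gene_id, wants in sorted(per_gene.items()):
            gene = genome.gene(gene_id)
            lo, hi = spans[gene_id]
            prom = extract_upstream(probe.gene(gene_id), probe, window=window)
            verified[gene_id] = {}
            buf = None
            for iupac, want in sorted(wants.items()):
                got = naive_motif_count(prom.sequence, iupac)
                verified[gene_id][iupac] = got
                if got <= want:
                    continue
                taken = claimed.setdefault(gene.chrom, [])
                for off in _match_offsets(prom.sequence, iupac):
                    span_abs = (
                        (lo + off, lo + off + len(iupac))
                        if gene.strand == "+"
                        else (hi - off - len(iupac), hi - off)
                    )
                    free = [
                        p for p in range(*span_abs)
                        if all(p < s or p >= e for s, e in taken)
                    ]
                    if not free:
                        continue  # textually coupled with a planted word
                    if buf is None:
                        buf = list(sequences[gene.chrom])
                    p = free[int(rng.integers(0, len(free)))]
                    buf[p] = str(rng.choice([b for b in BASES if b != buf[p]]))
                    clean = False
            if buf is not None:
                sequences[gene.chrom] = "".join(buf)
        if clean:
            break  # verified, or only unresolvable coupled excesses remain
    # final re-verification on the exact emitted sequences
    probe = AnnotatedGenome(sequences=sequences, genes=genome.genes)
    for gene_id, wants in sorted(per_gene.items()):
        prom = extract_upstream(probe.gene(gene_id), probe, window=window)
        verified[gene_id] = {
            iupac: naive_motif_count(prom.sequence, iupac) for iupac in wants
        }
    for gene_id, counts in verified.items():
        ledger.planted_motif_counts.setdefault(gene_id, {}).update(
            {iu: int(c) for iu, c in counts.items()}
        )
    out = AnnotatedGenome(sequences=sequences, genes=genome.genes)
    ledger.validate(out)
    return out, ledger


def _match_offsets(sequence: str, iupac: str) -> list[int]:
    """Start offsets of non-overlapping greedy matches (oracle semantics)."""
    sets = [IUPAC_TO_BASES[c] for c in iupac.upper()]
    L = len(sets)
    seq = sequence.upper()
    i = 0
    out = []
    while i + L <= len(seq):
        if all(seq[i + j] in sets[j] for j in range(L)):
            out.append(i)
            i += L
        else:
            i += 1
    return out


def _claim_offset(
    rng: np.random.Generator,
    length: int,
    lo: int,
    hi: int,
    taken: list[tuple[int, int]],
    tries: int = 200,
) -> tuple[int, int] | None:
    """A random absolute interval of ``length`` inside [lo, hi) that does
    not intersect any already-claimed interval; claims it on success."""
    if hi - lo < length:
        return None
    for _ in range(tries):
        a = lo + int(rng.integers(0, hi - lo - length + 1))
        b = a + length
        if all(b <= s or a >= e for s, e in taken):
            taken.append((a, b))
            return a, b
    return None


# ---------------------------------------------------------------------------
# codon-pair divergence at controlled omega
# ---------------------------------------------------------------------------

def simulate_codon_pair(
    n_codons: int, n_events: int, omega: float, seed: int = 0
) -> tuple[str, str, dict]:
    """A stop-free codon sequence and a derived copy separated by
    ``n_events`` accepted single-base substitutions.

    Proposal: uniform position, uniform alternative base.  A proposal
    creating a stop codon is always rejected and redrawn.  Acceptance
    emulates selection at strength ``omega``: for omega <= 1 synonymous
    proposals are always accepted and nonsynonymous ones with probability
    omega; for omega > 1 the roles invert (synonymous accepted with
    probability 1/omega).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    rng = _rng(seed, _STREAM_CODON)
    codons = [str(c) for c in rng.choice(SENSE_CODONS, size=n_codons)]
    seq_a = "".join(codons)
    current = list(codons)
    accepted = 0
    n_syn = n_nonsyn = 0
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_nonsyn = min(1.0, omega)
    while accepted < n_events:
        site = int(rng.integers(0, 3 * n_codons))
        ci, within = divmod(site, 3)
        codon = current[ci]
        base = str(rng.choice([b for b in BASES if b != codon[within]]))
        mutant = codon[:within] + base + codon[within + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() >= p_accept:
            continue
        current[ci] = mutant
        accepted += 1
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    truth = {
        "omega": omega,
        "n_events": n_events,
        "n_synonymous_events": n_syn,
        "n_nonsynonymous_events": n_nonsyn,
    }
    return seq_a, "".join(current), truth


# ---------------------------------------------------------------------------
# homolog evidence for phylostratigraphy
# ---------------------------------------------------------------------------

def simulate_homolog_evidence(
    gene_ids: list[str],
    ladder,
    planted_strata: dict[str, str],
    seed: int = 0,
) -> list:
    """Reciprocal-hit evidence consistent with planted gene ages.

    For each gene, panel species whose stratum is at or younger than the
    planted stratum receive both E-values < 1e-5; species in older strata
    get at least one direction >= 1e-5.
    """
    from .gene_age import ReciprocalEvidence

    rng = _rng(seed, _STREAM_HOMOLOG)
    per_stratum: dict[str, list[str]] = {s: [] for s in ladder.strata}
    for sp, st in ladder.species_stratum.items():
        per_stratum[st].append(sp)
    missing = [s for s, sps in per_stratum.items() if not sps]
    if missing:
        raise ValueError(f"ladder strata without panel species: {missing}")
    rows = []
    for gene in gene_ids:
        stratum = planted_strata[gene]
        cut = ladder.index(stratum)
        for sp in sorted(ladder.species_stratum):
            sp_idx = ladder.index(ladder.species_stratum[sp])
            if sp_idx >= cut:
                e_fwd = 10.0 ** -rng.uniform(6.0, 30.0)
                e_rev = 10.0 ** -rng.uniform(6.0, 30.0)
            else:
                e_fwd = 10.0 ** -rng.uniform(6.0, 30.0)
                e_rev = 10.0 ** -rng.uniform(-1.0, 4.5)  # fails the reciprocal rule
            rows.append(ReciprocalEvidence(gene, sp, e_fwd, e_rev))
    return rows


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

def simulate_de_table(
    gene_ids: list[str],
    ledger: TruthLedger,
    frac_signif: float = 0.3,
    lfc_magnitude: float = 2.0,
    frac_up: float = 0.5,
    condition: str = "radiation",
    seed: int = 0,
):
    """Per-gene log2 fold changes and p-values with a planted significant
    set: planted genes strictly pass |FC| > lfc_magnitude and p < 0.05,
    the rest strictly fail at least one criterion."""
    import pandas as pd

    if not 0 <= frac_signif <= 1:
        raise ValueError("frac_signif must lie in [0, 1]")
    if lfc_magnitude < 1:
        raise ValueError("lfc_magnitude must be >= 1")
    rng = _rng(ledger.seed, _STREAM_DE, seed)
    n = len(gene_ids)
    n_sig = int(round(frac_signif * n))
    sig_idx = set(rng.choice(n, size=n_sig, replace=False).tolist())
    thr = np.log2(lfc_magnitude)
    rows = []
    for i, gene in enumerate(gene_ids):
        if i in sig_idx:
            up = rng.random() < frac_up
            lfc = thr + rng.uniform(0.2, 2.5)
            lfc = lfc if up else -lfc
            p = 10.0 ** -rng.uniform(2.0, 6.0)
            status = "up" if up else "down"
        else:
            if rng.random() < 0.5:
                lfc = rng.uniform(-0.8, 0.8) * thr
                p = 10.0 ** -rng.uniform(0.0, 4.0)
            else:
                lfc = rng.uniform(-3.0, 3.0)
                p = rng.uniform(0.06, 0.95)
            status = "ns"
        rows.append({"gene_id": gene, "condition": condition,
                     "log2fc": float(lfc), "p_value": float(p)})
        ledger.planted_de[gene] = status
    return pd.DataFrame(rows), ledger


# ---------------------------------------------------------------------------
# family-identification evidence
# ---------------------------------------------------------------------------

def simulate_family_evidence(
    member_proteins: list[str],
    other_proteins: list[str],
    seed: int = 0,
):
    """Candidate evidence and validation rows under which the membership
    logic attains perfect recall and precision: every member passes at
    least one channel and validates in at least one source; every
    non-member either fails every threshold or lacks the domain."""
    from .family_identification import (
        DEFAULT_THRESHOLDS,
        CandidateEvidence,
        ValidationRecord,
    )

    rng = _rng(seed, _STREAM_EVIDENCE)
    channels = sorted(DEFAULT_THRESHOLDS)
    sources = ("CDD", "SMART", "Pfam", "InterPro")
    evidence, validation = [], []
    for pid in member_proteins:
        k = int(rng.integers(1, len(channels) + 1))
        for ch in rng.choice(channels, size=k, replace=False):
            ch = str(ch)
            evidence.append(
                CandidateEvidence(pid, ch, DEFAULT_THRESHOLDS[ch] * 10.0 ** -rng.uniform(1, 10))
            )
        n_src = int(rng.integers(1, 5))
        for src in rng.choice(sources, size=n_src, replace=False):
            validation.append(ValidationRecord(pid, str(src), True))
    for pid in other_proteins:
        if rng.random() < 0.5:
            ch = str(rng.choice(channels))
            evidence.append(
                CandidateEvidence(pid, ch, DEFAULT_THRESHOLDS[ch] * 10.0 ** rng.uniform(1, 6))
            )
        else:
            ch = str(rng.choice(channels))
            evidence.append(
                CandidateEvidence(pid, ch, DEFAULT_THRESHOLDS[ch] * 10.0 ** -rng.uniform(1, 6))
            )
            validation.append(ValidationRecord(pid, "CDD", False))
    return evidence, validation


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit(
    genome: AnnotatedGenome,
    ledger: TruthLedger,
    outdir: str | os.PathLike,
    hits: list[HitRecord] | None = None,
) -> dict[str, str]:
    """Write genome FASTA, GFF3, optional hit table and the ledger."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "ledger": os.path.join(outdir, "truth_ledger.json"),
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gff3(genome.genes, paths["gff3"])
    ledger.write(paths["ledger"])
    if hits is not None:
        paths["hits"] = os.path.join(outdir, "self_hits.tsv")
        write_hit_table(hits, paths["hits"])
    return paths
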