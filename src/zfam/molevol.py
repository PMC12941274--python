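"""Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

The approximate counting method: each codon position contributes a
fractional synonymous site; differences between a codon pair are averaged
over all substitution orderings; the per-site proportions are corrected
for multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p),
and omega = dN/dS.

Stop-codon convention (default): single-base changes that create a stop
codon are excluded from both numerator and denominator of the site
fractions, and substitution orderings that pass through a stop are
excluded from pathway averaging (if every ordering passes through a stop,
all are kept as a fallback).  ``stops_as_nonsynonymous=True`` switches to
the original formulation in which changes to stop codons count as
nonsynonymous and no pathway is excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._codon import BASES, CODON_TO_AA, is_stop, translate_cds

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """A pairwise codon alignment; columns are (codon_a, codon_b) triplets,
    either an A/C/G/T codon or the gap codon '---'."""

    pair_id: str
    columns: tuple[tuple[str, str], ...]

    def used_columns(self) -> list[tuple[str, str]]:
        """Columns retained for counting: ungapped, unambiguous and
        stop-free in both sequences (complete deletion)."""
        used = []
        for a, b in self.columns:
            if GAP_CODON in (a, b):
                continue
            if set(a + b) - set(BASES):
                continue
            if is_stop(a) or is_stop(b):
                continue
            used.append((a, b))
        return used

    @property
    def L_used(self) -> int:
        return len(self.used_columns())


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None  # None when the JC correction is undefined (p >= 3/4)
    dN: float | None
    omega: float | None  # None when dS is 0 or undefined
    se_dN: float | None = None
    se_dS: float | None = None
    n_boot: int = 0


def backtranslate(
    pair_id: str,
    peptide_a: str,
    peptide_b: str,
    cds_a: str,
    cds_b: str,
) -> CodonAlignment:
    """Thread CDS codons onto an aligned peptide pair.

    Each aligned residue is replaced by its source codon; residue gaps
    become codon gaps.  The ungapped peptide must translate exactly from
    its CDS (terminal stop tolerated).
    """
    cols_a = _peptide_to_codons(peptide_a, cds_a, "a")
    cols_b = _peptide_to_codons(peptide_b, cds_b, "b")
    if len(cols_a) != len(cols_b):
        raise ValueError(
            f"{pair_id}: aligned peptides have unequal lengths "
            f"({len(cols_a)} vs {len(cols_b)})"
        )
    return CodonAlignment(pair_id=pair_id, columns=tuple(zip(cols_a, cols_b)))


def _peptide_to_codons(peptide: str, cds: str, label: str) -> list[str]:
    cds = cds.upper()
    residues = peptide.upper().replace("-", "")
    n_codons = len(cds) // 3
    if len(cds) % 3 != 0 or n_codons not in (len(residues), len(residues) + 1):
        raise ValueError(
            f"sequence {label}: CDS length {len(cds)} does not match "
            f"{len(residues)} aligned residues (+/- terminal stop)"
        )
    translated = translate_cds(cds)
    for i, (want, got) in enumerate(zip(residues, translated)):
        if want != got:
            raise ValueError(
                f"sequence {label}: peptide/CDS translation mismatch at residue "
                f"{i + 1}: peptide {want}, CDS encodes {got}"
            )
    out = []
    k = 0
    for ch in peptide.upper():
        if ch == "-":
            out.append(GAP_CODON)
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return out


# ---------------------------------------------------------------------------
# site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def count_sites(codon: str, stops_as_nonsynonymous: bool = False) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one codon.

    At each of the three positions the synonymous fraction is the number
    of single-base changes preserving the amino acid divided by the number
    of changes considered at that position (stop-creating changes excluded
    under the default convention, counted as nonsynonymous under the
    original one); s is the sum of fractions and n = 3 - s.
    """
    codon = codon.upper()
    if set(codon) - set(BASES) or len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r} (ambiguity codes must be dropped)")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                if stops_as_nonsynonymous:
                    considered += 1
                continue
            considered += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if considered:
            s += syn / considered
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(
    codon_a: str, codon_b: str, stops_as_nonsynonymous: bool = False
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    For codons differing at d positions, each of the d! substitution
    orderings is walked one base at a time and its steps classified; the
    counts are averaged over admissible orderings.  Orderings passing
    through a stop codon are excluded (unless all do, or under
    ``stops_as_nonsynonymous``).  Always sd + nd = d.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if set(c) - set(BASES) or len(c) != 3:
            raise ValueError(f"invalid codon {c!r}")
        if is_stop(c):
            raise ValueError(f"stop codon {c} in difference counting")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    admissible: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        current = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                through_stop = True
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        fallback.append((sd, nd))
        if stops_as_nonsynonymous or not through_stop:
            admissible.append((sd, nd))
    paths = admissible or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(
    aln: CodonAlignment, stops_as_nonsynonymous: bool = False
) -> KaKsResult:
    """Compute S, N, Sd, Nd, pS, pN, dS, dN and omega for one codon pair."""
    used = aln.used_columns()
    if not used:
        raise ValueError(f"{aln.pair_id}: no usable codon columns")
    s_a = n_a = s_b = n_b = 0.0
    Sd = Nd = 0.0
    for ca, cb in used:
        sa, na = count_sites(ca, stops_as_nonsynonymous)
        sb, nb = count_sites(cb, stops_as_nonsynonymous)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        sd, nd = count_differences(ca, cb, stops_as_nonsynonymous)
        Sd += sd
        Nd += nd
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return KaKsResult(
        pair_id=aln.pair_id, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega,
    )


def bootstrap_kaks(
    aln: CodonAlignment,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    stops_as_nonsynonymous: bool = False,
) -> tuple[float, float, int]:
    """Codon-bootstrap standard errors of dN and dS.

    Columns are resampled with replacement ``reps`` times; the SE is the
    standard deviation of the replicate distances.  Replicates with an
    undefined distance are dropped (their number is reflected in the
    returned count of retained replicates).

    Returns (se_dN, se_dS, n_retained).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    used = aln.used_columns()
    if len(used) < 2:
        raise ValueError("need at least 2 usable codon columns to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # per-column contributions, so replicates are O(L) sums not O(L) recounts
    contrib = []
    for ca, cb in used:
        sa, na = count_sites(ca, stops_as_nonsynonymous)
        sb, nb = count_sites(cb, stops_as_nonsynonymous)
        sd, nd = count_differences(ca, cb, stops_as_nonsynonymous)
        contrib.append(((sa + sb) / 2.0, (na + nb) / 2.0, sd, nd))
    arr = np.asarray(contrib)  # (L, 4): S_i, N_i, Sd_i, Nd_i
    L = arr.shape[0]
    idx = rng.integers(0, L, size=(reps, L))
    sums = arr[idx].sum(axis=1)  # (reps, 4)
    dNs, dSs = [], []
    for S, N, Sd, Nd in sums:
        pS = Sd / S if S > 0 else 0.0
        pN = Nd / N if N > 0 else 0.0
        dS = jukes_cantor(pS)
        dN = jukes_cantor(pN)
        if dS is None or dN is None:
            continue
        dSs.append(dS)
        dNs.append(dN)
    if not dNs:
        raise ValueError("all bootstrap replicates had undefined distances")
    ddof = 1 if len(dNs) > 1 else 0
    return (
        float(np.std(dNs, ddof=ddof)),
        float(np.std(dSs, ddof=ddof)),
        len(dNs),
    )


def kaks_with_bootstrap(
    aln: CodonAlignment,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    stops_as_nonsynonymous: bool = False,
) -> KaKsResult:
    base = nei_gojobori(aln, stops_as_nonsynonymous)
    se_dN, se_dS, kept = bootstrap_kaks(aln, reps, seed, stops_as_nonsynonymous)
    return KaKsResult(
        **{**base.__dict__, "se_dN": se_dN, "se_dS": se_dS, "n_boot": kept}
    )


def batch_kaks(
    pairs: list[CodonAlignment],
    labels: dict[str, str] | None = None,
    reps: int = 0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Ka/Ks for a list of codon alignments plus an omega-fraction summary.

    ``labels`` optionally maps pair_id -> {orthologous, paralogous}; the
    summary attribute ``.attrs['summary']`` reports, per label, the number
    of pairs and the fractions with omega > 1 and < 1 among pairs where
    omega is defined.
    """
    import pandas as pd

    if not pairs:
        raise ValueError("empty pair list")
    rng = np.random.default_rng(seed)
    rows = []
    for aln in pairs:
        if reps > 0:
            res = kaks_with_bootstrap(aln, reps=reps, seed=rng)
        else:
            res = nei_gojobori(aln)
        rows.append(
            {
                "pair_id": res.pair_id,
                "label": (labels or {}).get(res.pair_id, "unlabelled"),
                "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                "pS": res.pS, "pN": res.pN, "dS": res.dS, "dN": res.dN,
                "omega": res.omega, "se_dN": res.se_dN, "se_dS": res.se_dS,
            }
        )
    df = pd.DataFrame(rows)
    summary = {}
    for label, sub in df.groupby("label"):
        defined = sub["omega"].dropna()
        summary[label] = {
            "n_pairs": int(len(sub)),
            "n_defined": int(len(defined)),
            "frac_gt1": float((defined > 1).mean()) if len(defined) else float("nan"),
            "frac_lt1": float((defined < 1).mean()) if len(defined) else float("nan"),
        }
    df.attrs["summary"] = summary
    return df
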