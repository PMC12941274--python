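import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfam._codon import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from zfam.molevol import (
    CodonAlignment,
    backtranslate,
    bootstrap_kaks,
    batch_kaks,
    count_differences,
    count_sites,
    jukes_cantor,
    nei_gojobori,
)


def oracle_count_differences(a, b, stops_as_nonsyn=False):
    """Literal enumeration of all d! substitution orderings."""
    diff = [i for i in range(3) if a[i] != b[i]]
    paths, fallback = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                stop = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if stops_as_nonsyn or not stop:
            paths.append((sd, nd))
    paths = paths or fallback
    if not diff:
        return (0.0, 0.0)
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_count_sites(codon, stops_as_nonsyn=False):
    """Literal enumeration of all 9 single-base changes."""
    s = 0.0
    for pos in range(3):
        syn = considered = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if m in STOP_CODONS and not stops_as_nonsyn:
                continue
            considered += 1
            if CODON_TO_AA[m] == CODON_TO_AA[codon]:
                syn += 1
        if considered:
            s += syn / considered
    return s, 3.0 - s


class TestCountSites:
    def test_phenylalanine_third_position(self):
        s, n = count_sites("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_site(self):
        assert count_sites("ATG")[0] == 0.0

    def test_glycine_fourfold_third_position(self):
        assert count_sites("GGG")[0] >= 1.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            count_sites("ATN")

    @pytest.mark.parametrize("variant", [False, True])
    def test_all_sense_codons_match_enumeration_oracle(self, variant):
        for codon in SENSE_CODONS:
            assert count_sites(codon, variant) == pytest.approx(
                oracle_count_sites(codon, variant)
            )

    def test_site_conservation_s_plus_n_is_three(self):
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            assert s + n == pytest.approx(3.0)


class TestCountDifferences:
    def test_single_nonsynonymous_change(self):
        assert count_differences("TTT", "TTA") == (0.0, 1.0)

    def test_two_path_average(self):
        assert count_differences("TTT", "GTA") == (0.5, 1.5)

    def test_identical_codons(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_symmetry(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("GGG", "TCT")]:
            assert count_differences(a, b) == count_differences(b, a)

    @pytest.mark.parametrize("variant", [False, True])
    def test_all_pairs_match_pathway_enumeration_oracle(self, variant):
        """Exhaustive 61 x 61 check against literal d! path enumeration."""
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                got = count_differences(a, b, variant)
                want = oracle_count_differences(a, b, variant)
                assert got == pytest.approx(want), (a, b)

    def test_sd_plus_nd_equals_number_of_differences(self):
        for a in SENSE_CODONS[::5]:
            for b in SENSE_CODONS[::7]:
                d = sum(x != y for x, y in zip(a, b))
                sd, nd = count_differences(a, b)
                assert sd + nd == pytest.approx(d)


class TestJukesCantor:
    def test_closed_form_at_half(self):
        assert jukes_cantor(0.5) == pytest.approx(0.8239, abs=1e-4)

    def test_small_p_limit(self):
        p = 1e-4
        assert jukes_cantor(p) / p == pytest.approx(1.0, abs=1e-3)

    def test_undefined_beyond_three_quarters(self):
        assert jukes_cantor(0.75) is None and jukes_cantor(0.9) is None

    @given(st.floats(0.001, 0.74))
    def test_distance_inflates_proportion(self, p):
        assert jukes_cantor(p) >= p


def _aln(pair_id, a, b):
    cols = tuple((a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3))
    return CodonAlignment(pair_id, cols)


class TestNeiGojobori:
    def test_identical_sequences(self):
        res = nei_gojobori(_aln("p", "ATGGCT" * 10, "ATGGCT" * 10))
        assert res.dN == 0 and res.dS == 0 and res.omega is None

    def test_single_synonymous_difference(self):
        a = "ATGGCTGCTGCTGCT"
        b = "ATGGCTGCTGCTGCG"  # GCT->GCG is synonymous (Ala)
        res = nei_gojobori(_aln("p", a, b))
        assert res.Sd == 1 and res.Nd == 0 and res.dN == 0 and res.omega == 0

    def test_symmetry_in_sequence_order(self):
        a, b = "ATGGCTAAATTTGGG", "ATGGTTAAGTTCGGA"
        r1, r2 = nei_gojobori(_aln("p", a, b)), nei_gojobori(_aln("p", b, a))
        assert (r1.S, r1.N, r1.Sd, r1.Nd, r1.dS, r1.dN) == (
            r2.S, r2.N, r2.Sd, r2.Nd, r2.dS, r2.dN
        )

    def test_gapped_and_stop_columns_dropped(self):
        cols = (("ATG", "ATG"), ("---", "GCT"), ("TAA", "TAA"), ("GCT", "GCT"))
        aln = CodonAlignment("p", cols)
        assert aln.L_used == 2

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori(CodonAlignment("p", (("---", "ATG"),)))


class TestBacktranslate:
    def test_gap_threading(self):
        aln = backtranslate("p", "M-K", "MLK", "ATGAAA", "ATGCTGAAA")
        assert aln.columns == (("ATG", "ATG"), ("---", "CTG"), ("AAA", "AAA"))

    def test_terminal_stop_tolerated(self):
        aln = backtranslate("p", "MK", "MK", "ATGAAATAA", "ATGAAG")
        assert aln.L_used == 2

    def test_translation_mismatch_detected(self):
        with pytest.raises(ValueError, match="mismatch"):
            backtranslate("p", "MK", "MK", "ATGCCC", "ATGAAA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            backtranslate("p", "MK", "MK", "ATGTAAAAA", "ATGAAA")


class TestBootstrap:
    def test_identical_pair_zero_se(self):
        aln = _aln("p", "ATGGCTAAA" * 20, "ATGGCTAAA" * 20)
        se_dN, se_dS, kept = bootstrap_kaks(aln, reps=100, seed=1)
        assert se_dN == 0 and se_dS == 0 and kept == 100

    def test_same_seed_reproducible(self):
        from zfam.synthetic_data import simulate_codon_pair

        a, b, _ = simulate_codon_pair(200, 60, 0.5, seed=3)
        aln = _aln("p", a, b)
        assert bootstrap_kaks(aln, 300, seed=9) == bootstrap_kaks(aln, 300, seed=9)

    def test_se_shrinks_with_length(self):
        from zfam.synthetic_data import simulate_codon_pair

        ses = []
        for L, ev in [(100, 30), (1600, 480)]:
            a, b, _ = simulate_codon_pair(L, ev, 0.5, seed=5)
            se_dN, se_dS, _ = bootstrap_kaks(_aln("p", a, b), 300, seed=2)
            ses.append(se_dS)
        assert ses[1] < ses[0] / 2  # ~ 1/sqrt(16) = 1/4 expected

    def test_too_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_kaks(_aln("p", "ATG", "ATG"), reps=10, seed=0)


class TestBatch:
    def test_summary_fractions_over_defined_only(self):
        alns = [
            _aln("same", "ATGGCTAAA", "ATGGCTAAA"),  # omega undefined
            _aln("syn", "GCTGCTGCC", "GCCGCTGCT"),  # dN=0 -> omega 0
        ]
        df = batch_kaks(alns)
        summ = df.attrs["summary"]["unlabelled"]
        assert summ["n_pairs"] == 2 and summ["n_defined"] == 1
        assert summ["frac_lt1"] == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            batch_kaks([])


class TestOmegaRecovery:
    def test_purifying_vs_neutral_separation(self):
        """Planted omega=0.2 and omega=1.0 pairs separate cleanly."""
        from zfam.synthetic_data import simulate_codon_pair

        means = {}
        for w in (0.2, 1.0):
            est = []
            for r in range(20):
                a, b, _ = simulate_codon_pair(500, 150, w, seed=100 * r + int(10 * w))
                est.append(nei_gojobori(_aln("p", a, b)).omega)
            means[w] = sum(est) / len(est)
            if w == 0.2:
                assert sum(e < 1 for e in est) >= 18
        assert means[0.2] < 0.5 < means[1.0]
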