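import pytest

from zfam._codon import STOP_CODONS, translate_cds
from zfam import synthetic_data as synth
from zfam.io_formats import read_fasta, read_gff3
from zfam.promoter_cis import extract_upstream

from conftest import naive_scan_count


class TestSimulateGenome:
    def test_deterministic_emission(self, tmp_path):
        for d in ("a", "b"):
            genome, ledger = synth.simulate_genome(
                synth.GenomeConfig(n_chrom=1, genes_per_chrom=5), seed=7
            )
            synth.emit(genome, ledger, tmp_path / d)
        assert (tmp_path / "a/genome.fa").read_bytes() == (tmp_path / "b/genome.fa").read_bytes()
        assert (tmp_path / "a/genes.gff3").read_bytes() == (tmp_path / "b/genes.gff3").read_bytes()

    def test_different_seed_changes_output(self):
        g1, _ = synth.simulate_genome(seed=1)
        g2, _ = synth.simulate_genome(seed=2)
        assert g1.sequences != g2.sequences

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synth.GenomeConfig(genes_per_chrom=0)
        with pytest.raises(ValueError):
            synth.GenomeConfig(gc_fraction=1.5)

    def test_every_cds_translates_without_internal_stops(self):
        genome, _ = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=2, genes_per_chrom=10), seed=3
        )
        for g in genome.genes:
            cds = g.cds_sequence(genome.sequences[g.chrom])
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            assert len(cds) % 3 == 0
            translate_cds(cds)  # raises on internal stop

    def test_genes_nonoverlapping_alternating_strands(self):
        genome, _ = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=8, intergenic_bp=50), seed=5
        )
        genes = genome.genes_by_chrom()["chr1"]
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end >= 50
            assert a.strand != b.strand

    def test_emitted_files_parse_back(self, tmp_path):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=2, genes_per_chrom=4), seed=9
        )
        paths = synth.emit(genome, ledger, tmp_path)
        seqs = read_fasta(paths["fasta"])
        genes = read_gff3(paths["gff3"])
        assert set(seqs) == {"chr1", "chr2"} and len(genes) == 8
        by_id = {g.gene_id: g for g in genes}
        for g in genome.genes:
            r = by_id[g.gene_id]
            assert (r.start, r.end, r.strand) == (g.start, g.end, g.strand)


class TestPlantFamily:
    def test_tandem_copy_gets_adjacent_rank(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=2, genes_per_chrom=10), seed=1
        )
        genome, hits, ledger = synth.plant_family(
            genome, ledger, "f", ["tandem"], founder_gene_id="chr1_g005", seed=0
        )
        ranks = {
            g.gene_id: r
            for r, g in enumerate(genome.genes_by_chrom()["chr1"])
        }
        assert abs(ranks["f_c1"] - ranks["chr1_g005"]) == 1
        assert ledger.planted_duplication["f_c1"] == "tandem"
        assert ledger.planted_duplication["chr1_g005"] == "tandem"

    def test_dispersed_impossible_on_single_chromosome(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=10), seed=1
        )
        with pytest.raises(ValueError, match="chromosome"):
            synth.plant_family(genome, ledger, "f", ["dispersed"], seed=0)

    def test_zero_mutation_rate_keeps_cds_identical(self, small_genome):
        genome, hits, ledger = small_genome
        members = ledger.planted_families["famA"]
        founder = genome.gene(members[0])
        founder_cds = founder.cds_sequence(genome.sequences[founder.chrom])
        for m in members[1:]:
            g = genome.gene(m)
            assert g.cds_sequence(genome.sequences[g.chrom]) == founder_cds

    def test_mutation_rate_bounds(self, small_genome):
        genome, _, ledger = small_genome
        with pytest.raises(ValueError):
            synth.plant_family(genome, ledger, "x", ["tandem"], mutation_rate=0.5)

    def test_hit_table_connects_exactly_the_family(self, small_genome):
        genome, hits, ledger = small_genome
        members = set(ledger.planted_families["famA"])
        non_self = {(h.query_id, h.subject_id) for h in hits if not h.is_self_hit}
        assert all(q in members and s in members for q, s in non_self)
        # both directions present for every unordered pair
        assert all((s, q) in non_self for q, s in non_self)
        selfs = {h.query_id for h in hits if h.is_self_hit}
        assert selfs == members


class TestPlantPromoterMotifs:
    def test_ledger_bookkeeping_and_recovery(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=6), seed=21
        )
        reqs = {
            ("chr1_g002", "GGATTA"): 2,
            ("chr1_g002", "RTAAACA"): 1,
            ("chr1_g003", "GGATTA"): 0,
        }
        genome, ledger = synth.plant_promoter_motifs(genome, ledger, reqs, seed=0)
        assert ledger.planted_motif_counts["chr1_g002"]["GGATTA"] == 2
        assert ledger.planted_motif_counts["chr1_g003"]["GGATTA"] == 0
        for gid, wants in ledger.planted_motif_counts.items():
            prom = extract_upstream(genome.gene(gid), genome)
            for iupac, count in wants.items():
                assert naive_scan_count(prom.sequence, iupac) == count

    def test_degenerate_word_realized_within_code(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=4), seed=22
        )
        genome, ledger = synth.plant_promoter_motifs(
            genome, ledger, {("chr1_g002", "RTAAACA"): 1}, seed=1
        )
        prom = extract_upstream(genome.gene("chr1_g002"), genome)
        assert naive_scan_count(prom.sequence, "RTAAACA") == 1

    def test_minus_strand_gene_promoter_planting(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=4), seed=23
        )
        minus = next(g for g in genome.genes if g.strand == "-")
        genome, ledger = synth.plant_promoter_motifs(
            genome, ledger, {(minus.gene_id, "GGATTA"): 3}, seed=2
        )
        prom = extract_upstream(genome.gene(minus.gene_id), genome)
        assert naive_scan_count(prom.sequence, "GGATTA") == 3

    def test_unplaceable_request_rejected(self):
        genome, ledger = synth.simulate_genome(
            synth.GenomeConfig(n_chrom=1, genes_per_chrom=3, intergenic_bp=30), seed=24
        )
        with pytest.raises(ValueError, match="exceed"):
            synth.plant_promoter_motifs(
                genome, ledger, {("chr1_g002", "GGATTA"): 10}, window=30, seed=0
            )


class TestSimulateCodonPair:
    def test_identity_at_zero_events(self):
        a, b, truth = synth.simulate_codon_pair(50, 0, 0.5, seed=1)
        assert a == b and truth["n_events"] == 0

    def test_determinism(self):
        assert synth.simulate_codon_pair(100, 30, 0.3, seed=9) == \
            synth.simulate_codon_pair(100, 30, 0.3, seed=9)

    def test_tiny_omega_yields_only_synonymous_differences(self):
        from zfam._codon import CODON_TO_AA

        a, b, truth = synth.simulate_codon_pair(200, 50, 1e-9, seed=2)
        assert truth["n_nonsynonymous_events"] == 0
        for i in range(0, len(a), 3):
            assert CODON_TO_AA[a[i : i + 3]] == CODON_TO_AA[b[i : i + 3]]

    def test_no_stops_introduced(self):
        a, b, _ = synth.simulate_codon_pair(300, 200, 2.0, seed=3)
        for seq in (a, b):
            assert not any(
                seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq), 3)
            )

    def test_preconditions(self):
        with pytest.raises(ValueError):
            synth.simulate_codon_pair(0, 5, 1.0, seed=0)
        with pytest.raises(ValueError):
            synth.simulate_codon_pair(10, 5, 0.0, seed=0)


class TestHomologEvidence:
    def _ladder(self):
        from zfam.gene_age import DEFAULT_LADDER_STRATA, LineageLadder

        return LineageLadder(
            DEFAULT_LADDER_STRATA,
            {
                "ecoli": "Cellular organisms",
                "yeast": "Eukaryota",
                "fly": "Metazoa",
                "other_tardigrade": "Tardigrada-specific",
            },
        )

    def test_metazoa_gene_fails_reciprocal_rule_in_bacteria(self):
        from zfam.gene_age import call_homolog

        rows = synth.simulate_homolog_evidence(
            ["g1"], self._ladder(), {"g1": "Metazoa"}, seed=4
        )
        by_sp = {r.species_id: r for r in rows}
        assert not call_homolog(by_sp["ecoli"])
        assert not call_homolog(by_sp["yeast"])
        assert call_homolog(by_sp["fly"]) and call_homolog(by_sp["other_tardigrade"])

    def test_species_specific_gene_passes_nowhere_older(self):
        from zfam.gene_age import call_homolog

        rows = synth.simulate_homolog_evidence(
            ["g1"], self._ladder(), {"g1": "Tardigrada-specific"}, seed=5
        )
        passing = {r.species_id for r in rows if call_homolog(r)}
        assert passing == {"other_tardigrade"}

    def test_reproducible(self):
        args = (["g1", "g2"], self._ladder(), {"g1": "Eukaryota", "g2": "Metazoa"})
        a = synth.simulate_homolog_evidence(*args, seed=6)
        b = synth.simulate_homolog_evidence(*args, seed=6)
        assert a == b


class TestDeTable:
    def test_zero_fraction_means_no_gene_passes(self):
        from zfam.integration import filter_de

        _, ledger = synth.simulate_genome(seed=1)
        genes = [f"g{i}" for i in range(40)]
        table, ledger = synth.simulate_de_table(genes, ledger, frac_signif=0.0, seed=1)
        assert filter_de(table) == []

    def test_planted_direction_and_exact_recovery(self):
        from zfam.integration import filter_de

        _, ledger = synth.simulate_genome(seed=2)
        genes = [f"g{i}" for i in range(60)]
        table, ledger = synth.simulate_de_table(genes, ledger, frac_signif=0.4, seed=2)
        records = filter_de(table)
        got = {r.gene_id: r.direction for r in records}
        planted = {g: s for g, s in ledger.planted_de.items() if s != "ns"}
        assert got == planted
        assert all(
            r.log2fc < 0 for r in records if ledger.planted_de[r.gene_id] == "down"
        )


class TestLedgerSerialization:
    def test_roundtrip(self, tmp_path, small_genome):
        _, _, ledger = small_genome
        p = tmp_path / "ledger.json"
        ledger.write(p)
        back = synth.TruthLedger.read(p)
        assert back.planted_families == ledger.planted_families
        assert back.planted_duplication == ledger.planted_duplication
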