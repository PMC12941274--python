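import json
import hashlib
import os

import pandas as pd
import pytest

from zfam.integration import (
    DERecord,
    chromosome_table,
    filter_de,
    group_de_summary,
    read_config,
    reconcile_localisation,
    run_pipeline,
    upregulated_cis_check,
)


def _de(gene, lfc, p):
    return pd.DataFrame(
        [{"gene_id": gene, "condition": "radiation", "log2fc": lfc, "p_value": p}]
    )


class TestFilterDe:
    def test_clear_upregulation_passes(self):
        (rec,) = filter_de(_de("g1", 2.0, 0.001))
        assert rec.direction == "up"

    def test_fold_change_boundary_strict(self):
        assert filter_de(_de("g1", 1.0, 0.001)) == []  # |FC| = 2 exactly fails
        assert filter_de(_de("g1", 0.9, 0.001)) == []

    def test_p_boundary_strict(self):
        assert filter_de(_de("g1", 2.0, 0.05)) == []

    def test_downregulation_direction(self):
        (rec,) = filter_de(_de("g1", -1.5, 0.01))
        assert rec.direction == "down"


class TestGroupSummary:
    def _records(self):
        return [
            DERecord("a", "c", -2.0, 0.001),
            DERecord("b", "c", -1.5, 0.01),
            DERecord("c", "c", 2.0, 0.01),
            DERecord("d", "c", 3.0, 0.01),
        ]

    def test_monotone_down_group(self):
        groups = {"a": "G5", "b": "G5", "c": "G1", "d": "G1"}
        df = group_de_summary(self._records(), groups).set_index("group")
        assert bool(df.loc["G5", "monotone"]) and df.loc["G5", "direction"] == "down"

    def test_mixed_group_flagged_false(self):
        groups = {"a": "G1", "c": "G1"}
        df = group_de_summary(self._records(), groups).set_index("group")
        assert not df.loc["G1", "monotone"] and df.loc["G1", "direction"] == "mixed"

    def test_group_without_significant_members_is_na(self):
        groups = {"zzz": "G9"}
        df = group_de_summary([], groups).set_index("group")
        assert df.loc["G9", "direction"] == "NA"


class TestUpregulatedCis:
    def _matrix(self):
        m = pd.DataFrame(
            {"GGATTA": [2, 0], "RTAAACA": [0, 0]}, index=["up1", "up2"]
        )
        m["any_element"] = m.sum(axis=1) > 0
        return m

    def test_fraction_computed(self):
        recs = [DERecord("up1", "c", 2.0, 0.01), DERecord("up2", "c", 2.0, 0.01)]
        assert upregulated_cis_check(recs, self._matrix()) == 0.5

    def test_no_upregulated_genes_rejected(self):
        recs = [DERecord("up1", "c", -2.0, 0.01)]
        with pytest.raises(ValueError):
            upregulated_cis_check(recs, self._matrix())

    def test_column_order_irrelevant(self):
        recs = [DERecord("up1", "c", 2.0, 0.01)]
        m = self._matrix()
        assert upregulated_cis_check(recs, m) == upregulated_cis_check(
            recs, m[m.columns[::-1]]
        )


class TestLocalisation:
    def test_primary_wins_with_conflict_flag(self):
        call = reconcile_localisation("p1", "nucleus", "mitochondrial transfer peptide")
        assert call.final == "nucleus" and call.conflict

    def test_agreement_no_conflict(self):
        call = reconcile_localisation("p1", "nucleus", "nucleus")
        assert call.final == "nucleus" and not call.conflict

    def test_missing_primary_rejected(self):
        with pytest.raises(ValueError):
            reconcile_localisation("p1", None, "nucleus")


class TestChromosomeTable:
    def test_sorted_within_chromosome_and_classes_joined(self, small_genome):
        from zfam.duplication import GeneRankIndex, classify_duplicates

        genome, hits, ledger = small_genome
        fam = set(ledger.planted_families["famA"])
        calls = classify_duplicates(hits, GeneRankIndex.from_genes(genome.genes))
        tab = chromosome_table(fam, genome.genes, calls)
        assert set(tab["gene_id"]) == fam
        for _, sub in tab.groupby("chrom"):
            assert list(sub["start"]) == sorted(sub["start"])
        call_of = {c.gene_id: c.duplication_class for c in calls}
        for row in tab.itertuples(index=False):
            assert row.duplication_class == call_of[row.gene_id]


class TestConfig:
    def test_flat_key_value_parsing(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("# comment\nn_chrom = 2\ngc_fraction = 0.5\nfamily_layout = tandem\n")
        cfg = read_config(p)
        assert cfg["n_chrom"] == 2 and cfg["gc_fraction"] == 0.5
        assert cfg["family_layout"] == "tandem"

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("warp_speed = 9\n")
        with pytest.raises(ValueError, match="warp_speed"):
            read_config(p)


SMALL_CFG = {
    "n_chrom": 3,
    "genes_per_chrom": 18,
    "n_families": 2,
    "kaks_n_codons": 150,
    "kaks_n_events": 45,
    "kaks_pairs_per_omega": 3,
    "bootstrap_reps": 50,
}


class TestPipeline:
    def _hashes(self, d):
        return {
            f: hashlib.sha256((d / f).read_bytes()).hexdigest()
            for f in sorted(os.listdir(d))
        }

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        s1 = run_pipeline(tmp_path / "r1", seed=3, config=SMALL_CFG)
        s2 = run_pipeline(tmp_path / "r2", seed=3, config=SMALL_CFG)
        assert self._hashes(tmp_path / "r1") == self._hashes(tmp_path / "r2")
        assert s1["duplication_counts"] == s2["duplication_counts"]

    def test_report_contains_every_stage_table(self, tmp_path):
        run_pipeline(tmp_path / "r", seed=4, config=SMALL_CFG)
        files = set(os.listdir(tmp_path / "r"))
        for expect in (
            "genome.fa", "genes.gff3", "truth_ledger.json", "self_hits.tsv",
            "duplication_calls.tsv", "tandem_enrichment.tsv", "element_counts.tsv",
            "kaks.tsv", "gene_ages.tsv", "protein_properties.tsv", "groups.tsv",
            "de_table.tsv", "group_de_summary.tsv", "chromosome_table.tsv",
            "manifest.jsonl",
        ):
            assert expect in files

    def test_ledger_closure_on_default_run(self, tmp_path):
        """Every integration summary matches the truth ledger."""
        from zfam.synthetic_data import TruthLedger

        run_pipeline(tmp_path / "r", seed=5, config=SMALL_CFG)
        out = tmp_path / "r"
        ledger = TruthLedger.read(out / "truth_ledger.json")
        # duplication classes
        dup = pd.read_csv(out / "duplication_calls.tsv", sep="\t")
        got = dict(zip(dup["gene_id"], dup["duplication_class"]))
        assert got == ledger.planted_duplication
        # motif counts
        mat = pd.read_csv(out / "element_counts.tsv", sep="\t", index_col=0)
        iupac_of = {"ceh-36": "GGATTA", "fkh-2": "RTAAACA",
                    "lin-14": "GAACRC", "hsf-1": "TTCYAGAA"}
        for gene, wants in ledger.planted_motif_counts.items():
            for col, iupac in iupac_of.items():
                if iupac in wants:
                    assert mat.loc[gene, col] == wants[iupac]
        # DE truth
        de = pd.read_csv(out / "de_table.tsv", sep="\t")
        recs = {r.gene_id: r.direction for r in filter_de(de)}
        planted = {g: s for g, s in ledger.planted_de.items() if s != "ns"}
        assert recs == planted
        # strata
        ages = pd.read_csv(out / "gene_ages.tsv", sep="\t")
        got_ages = dict(zip(ages["gene_id"], ages["stratum"]))
        assert got_ages == ledger.planted_strata
        # planted omega ordering visible in estimates
        kaks = pd.read_csv(out / "kaks.tsv", sep="\t")
        kaks["planted"] = kaks["pair_id"].map(ledger.planted_omega)
        mean_low = kaks.loc[kaks["planted"] == 0.2, "omega"].mean()
        mean_high = kaks.loc[kaks["planted"] == 1.0, "omega"].mean()
        assert mean_low < mean_high
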