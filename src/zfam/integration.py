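"""Cross-stage joins and the end-to-end synthetic pipeline driver.

Differential-expression filtering uses the symmetric linear-scale rule
|fold change| > 2 (i.e. |log2FC| > 1) with p < 0.05, both strict.
Subcellular-localisation calls from a primary predictor always win; the
auxiliary predictor only flags conflicts.  The pipeline driver wires the
synthetic generator through every analysis stage and writes one table per
stage plus a manifest of input hashes, so reruns can be diffed
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    condition: str
    log2fc: float
    p_value: float

    @property
    def significant(self) -> bool:
        return abs(self.log2fc) > 1.0 and self.p_value < 0.05

    @property
    def direction(self) -> str:
        if not self.significant:
            return "ns"
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class LocalisationCall:
    protein_id: str
    primary_call: str
    auxiliary_call: str | None
    final: str
    conflict: bool


def filter_de(
    table: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.05
) -> list[DERecord]:
    """Significant DE records: |fold change| > fc_min and p < p_max,
    both strict; direction is the sign of log2FC."""
    thr = math.log2(fc_min)
    out = []
    for row in table.itertuples(index=False):
        if abs(row.log2fc) > thr and row.p_value < p_max:
            out.append(
                DERecord(row.gene_id, getattr(row, "condition", ""), row.log2fc, row.p_value)
            )
    return out


def group_de_summary(
    de_records: list[DERecord], group_of: dict[str, str]
) -> pd.DataFrame:
    """Per-group counts of up/down significant genes and a monotone flag:
    true iff every significant member of the group shares one direction
    (NA for groups with no significant member)."""
    groups = sorted(set(group_of.values()))
    rows = []
    for group in groups:
        members = [r for r in de_records if group_of.get(r.gene_id) == group]
        n_up = sum(1 for r in members if r.direction == "up")
        n_down = sum(1 for r in members if r.direction == "down")
        if n_up + n_down == 0:
            monotone, direction = pd.NA, "NA"
        elif n_up == 0 or n_down == 0:
            monotone, direction = True, ("up" if n_up else "down")
        else:
            monotone, direction = False, "mixed"
        rows.append(
            {"group": group, "n_up": n_up, "n_down": n_down,
             "monotone": monotone, "direction": direction}
        )
    return pd.DataFrame(rows)


def upregulated_cis_check(
    de_records: list[DERecord], element_matrix: pd.DataFrame
) -> float:
    """Fraction of significantly upregulated genes whose promoter carries
    at least one cis element of any type."""
    up = [r.gene_id for r in de_records if r.direction == "up"]
    if not up:
        raise ValueError("no upregulated genes to check")
    motif_cols = [c for c in element_matrix.columns if c != "any_element"]
    with_element = 0
    for gene in up:
        if gene in element_matrix.index and element_matrix.loc[gene, motif_cols].sum() > 0:
            with_element += 1
    return with_element / len(up)


def reconcile_localisation(
    protein_id: str, primary_call: str | None, auxiliary_call: str | None
) -> LocalisationCall:
    """Final compartment = the primary predictor's call, always; the
    auxiliary predictor can only raise a conflict flag (e.g. a targeting
    peptide contradicting a nuclear call)."""
    if not primary_call:
        raise ValueError(f"{protein_id}: missing primary localisation call")
    conflict = auxiliary_call is not None and auxiliary_call != primary_call
    return LocalisationCall(
        protein_id=protein_id,
        primary_call=primary_call,
        auxiliary_call=auxiliary_call,
        final=primary_call,
        conflict=conflict,
    )


def chromosome_table(
    family_genes: set[str],
    gene_models: list,
    duplication_calls: list,
) -> pd.DataFrame:
    """Per-chromosome ordered listing of family genes with duplication
    class labels (tabular analogue of a chromosome-localisation figure)."""
    call_of = {c.gene_id: c.duplication_class for c in duplication_calls}
    rows = []
    for g in sorted(gene_models, key=lambda g: (g.chrom, g.start, g.gene_id)):
        if g.gene_id not in family_genes:
            continue
        rows.append(
            {
                "chrom": g.chrom,
                "start": g.start + 1,  # report 1-based inclusive
                "end": g.end,
                "strand": g.strand,
                "gene_id": g.gene_id,
                "duplication_class": call_of.get(g.gene_id, "singleton"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "duplication_class"]
    )
    if len(set(df["gene_id"])) != len(df):
        raise ValueError("a family gene appears more than once")
    return df


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG: dict = {
    "n_chrom": 4,
    "genes_per_chrom": 30,
    "gene_len_bp": 300,
    "intergenic_bp": 2200,
    "gc_fraction": 0.42,
    "n_families": 3,
    "family_layout": "tandem,tandem,proximal,dispersed",
    "n_motif_genes": 12,
    "max_motif_count": 3,
    "kaks_n_codons": 300,
    "kaks_n_events": 90,
    "kaks_omegas": "0.2,1.0",
    "kaks_pairs_per_omega": 6,
    "bootstrap_reps": 200,
    "de_frac_signif": 0.35,
    "de_lfc_magnitude": 2.0,
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_config(path: str | os.PathLike) -> dict:
    """Flat ``key = value`` config file; values parsed as int/float when
    possible, otherwise kept as strings."""
    config = dict(DEFAULT_PIPELINE_CONFIG)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in config:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            try:
                parsed: object = int(value)
            except ValueError:
                try:
                    parsed = float(value)
                except ValueError:
                    parsed = value
            config[key] = parsed
    return config


def run_pipeline(outdir: str | os.PathLike, seed: int = 0, config: dict | None = None) -> dict:
    """Simulate a genome with planted structure and run every analysis
    stage over it, writing one tab-separated table per stage, the truth
    ledger, and a JSON-lines manifest with the SHA-256 of every output.

    Returns a summary dict of the headline quantities each stage computed.
    """
    from . import duplication as dup
    from . import enrichment, gene_age, molevol, phylo_groups, protein_props
    from . import promoter_cis, synthetic_data as synth

    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    if config:
        cfg.update(config)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)

    genome_cfg = synth.GenomeConfig(
        n_chrom=int(cfg["n_chrom"]),
        genes_per_chrom=int(cfg["genes_per_chrom"]),
        gene_len_bp=int(cfg["gene_len_bp"]),
        intergenic_bp=int(cfg["intergenic_bp"]),
        gc_fraction=float(cfg["gc_fraction"]),
    )
    genome, ledger = synth.simulate_genome(genome_cfg, seed=seed)
    layout = [s.strip() for s in str(cfg["family_layout"]).split(",") if s.strip()]
    all_hits = []
    by_chrom = genome.genes_by_chrom()
    chroms = sorted(by_chrom)
    for i in range(int(cfg["n_families"])):
        founder_chrom = chroms[i % len(chroms)]
        founder = genome.genes_by_chrom()[founder_chrom][5 + 3 * i].gene_id
        genome, hits, ledger = synth.plant_family(
            genome, ledger, f"fam{i + 1}", layout,
            founder_gene_id=founder,
            intergenic_bp=genome_cfg.intergenic_bp,
            gc_fraction=genome_cfg.gc_fraction,
            seed=i,
        )
        all_hits.extend(hits)

    family_genes = sorted(
        {m for ms in ledger.planted_families.values() for m in ms}
    )

    # plant promoter elements in a deterministic subset of family genes
    patterns = promoter_cis.load_packaged_elements()
    simple = [p for p in patterns if p.iupac in {"GGATTA", "GAACRC", "RTAAACA", "TTCYAGAA"}]
    rng = np.random.default_rng([seed, 5])
    motif_requests: dict[tuple[str, str], int] = {}
    motif_genes = family_genes[: int(cfg["n_motif_genes"])]
    for gene in motif_genes:
        for pat in simple:
            motif_requests[(gene, pat.iupac)] = int(
                rng.integers(0, int(cfg["max_motif_count"]) + 1)
            )
    genome, ledger = synth.plant_promoter_motifs(
        genome, ledger, motif_requests, seed=seed
    )

    paths = synth.emit(genome, ledger, outdir, hits=all_hits)

    # --- duplication classification -------------------------------------
    index = dup.GeneRankIndex.from_genes(genome.genes)
    calls = dup.classify_duplicates(all_hits, index)
    dup_table = dup.calls_table(calls)
    dup_table.to_csv(os.path.join(outdir, "duplication_calls.tsv"), sep="\t", index=False)
    fam_summary = dup.duplication_summary(calls, set(family_genes))

    # --- tandem enrichment (family vs genome) ---------------------------
    tandem_genes = {c.gene_id for c in calls if c.duplication_class == "tandem"}
    counts = enrichment.ContingencyCounts(
        N=len(index.rank_of), K=len(tandem_genes),
        n=len(family_genes), k=len(tandem_genes & set(family_genes)),
    )
    direction, p = enrichment.directional_test(counts)
    q = float(enrichment.bh_adjust([p])[0])
    enrich_row = pd.DataFrame(
        [{
            "test": "tandem_family_vs_genome", "k": counts.k, "n": counts.n,
            "K": counts.K, "N": counts.N,
            "fold_enrichment": enrichment.fold_enrichment(counts),
            "direction": direction, "p_value": p, "q_value": q,
            "signed_lgP": enrichment.signed_score(direction, p),
        }]
    )
    enrich_row.to_csv(os.path.join(outdir, "tandem_enrichment.tsv"), sep="\t", index=False)

    # --- promoter scanning ----------------------------------------------
    proms = [
        promoter_cis.extract_upstream(genome.gene(g), genome) for g in family_genes
    ]
    matrix = promoter_cis.scan_all(proms, simple)
    matrix.to_csv(os.path.join(outdir, "element_counts.tsv"), sep="\t")

    # --- Ka/Ks on simulated codon pairs ----------------------------------
    pair_alns, labels = [], {}
    omegas = [float(x) for x in str(cfg["kaks_omegas"]).split(",")]
    pair_seed = 0
    for omega in omegas:
        for r in range(int(cfg["kaks_pairs_per_omega"])):
            a, b, truth = synth.simulate_codon_pair(
                int(cfg["kaks_n_codons"]), int(cfg["kaks_n_events"]), omega,
                seed=seed * 10000 + pair_seed,
            )
            pid = f"pair_w{omega}_{r}"
            cols = tuple(
                (a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)
            )
            pair_alns.append(molevol.CodonAlignment(pid, cols))
            labels[pid] = "paralogous" if omega < 1 else "orthologous"
            ledger.planted_omega[pid] = omega
            pair_seed += 1
    kaks = molevol.batch_kaks(
        pair_alns, labels, reps=int(cfg["bootstrap_reps"]), seed=seed
    )
    kaks.to_csv(os.path.join(outdir, "kaks.tsv"), sep="\t", index=False)

    # --- gene age ---------------------------------------------------------
    ladder = gene_age.LineageLadder(
        strata=gene_age.DEFAULT_LADDER_STRATA,
        species_stratum={
            "ecoli": "Cellular organisms", "yeast": "Eukaryota",
            "fly": "Metazoa", "other_tardigrade": "Tardigrada-specific",
        },
    )
    strata_cycle = list(gene_age.DEFAULT_LADDER_STRATA)
    planted_strata = {
        g: strata_cycle[i % len(strata_cycle)] for i, g in enumerate(family_genes)
    }
    evidence = synth.simulate_homolog_evidence(family_genes, ladder, planted_strata, seed=seed)
    ledger.planted_strata.update(planted_strata)
    ages = gene_age.assign_all(family_genes, evidence, ladder)
    pd.DataFrame(
        {"gene_id": list(ages), "stratum": list(ages.values())}
    ).to_csv(os.path.join(outdir, "gene_ages.tsv"), sep="\t", index=False)

    # --- protein properties ----------------------------------------------
    props = []
    for g in family_genes:
        gm = genome.gene(g)
        cds = gm.cds_sequence(genome.sequences[gm.chrom])
        from ._codon import translate_cds

        props.append(protein_props.characterize(f"{g}.p1", translate_cds(cds), cds))
    protein_props.properties_table(props).to_csv(
        os.path.join(outdir, "protein_properties.tsv"), sep="\t", index=False
    )

    # --- clade grouping on a synthetic family tree ------------------------
    fams = sorted(ledger.planted_families)
    newick = (
        "("
        + ",".join(
            "(" + ",".join(sorted(ledger.planted_families[f])) + ")" for f in fams
        )
        + ",outgroup);"
    )
    tree = phylo_groups.read_tree(newick, from_string=True)
    rooted = phylo_groups.reroot_at_outgroup(tree, "outgroup")
    anchors = {
        f"Group{i + 1}": set(sorted(ledger.planted_families[f])[:2])
        for i, f in enumerate(fams)
    }
    assignment = phylo_groups.assign_groups(rooted, anchors)
    pd.DataFrame(
        {
            "leaf": list(assignment.leaf_group),
            "group": list(assignment.leaf_group.values()),
        }
    ).sort_values("leaf").to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t", index=False
    )

    # --- differential expression ------------------------------------------
    de_table, ledger = synth.simulate_de_table(
        family_genes, ledger,
        frac_signif=float(cfg["de_frac_signif"]),
        lfc_magnitude=float(cfg["de_lfc_magnitude"]),
        seed=seed,
    )
    de_table.to_csv(os.path.join(outdir, "de_table.tsv"), sep="\t", index=False)
    de_records = filter_de(de_table, fc_min=float(cfg["de_lfc_magnitude"]))
    group_summary = group_de_summary(de_records, assignment.leaf_group)
    group_summary.to_csv(os.path.join(outdir, "group_de_summary.tsv"), sep="\t", index=False)

    chrom_tab = chromosome_table(set(family_genes), genome.genes, calls)
    chrom_tab.to_csv(os.path.join(outdir, "chromosome_table.tsv"), sep="\t", index=False)

    ledger.write(paths["ledger"])  # refresh with strata/omega/DE truth

    # --- manifest ----------------------------------------------------------
    outputs = sorted(
        f for f in os.listdir(outdir)
        if f.endswith((".tsv", ".fa", ".gff3", ".json")) and f != "manifest.jsonl"
    )
    manifest_path = os.path.join(outdir, "manifest.jsonl")
    with open(manifest_path, "w") as fh:
        fh.write(json.dumps({"stage": "config", "seed": seed, **{k: cfg[k] for k in sorted(cfg)}}) + "\n")
        for f in outputs:
            fh.write(
                json.dumps({"stage": "output", "file": f, "sha256": _sha256(os.path.join(outdir, f))})
                + "\n"
            )

    defined = kaks["omega"].dropna()
    return {
        "n_genes": len(genome.genes),
        "n_family_genes": len(family_genes),
        "duplication_counts": dict(
            zip(fam_summary["duplication_class"], fam_summary["count"])
        ),
        "tandem_enrichment_q": q,
        "tandem_enrichment_direction": direction,
        "kaks_frac_lt1": float((defined < 1).mean()),
        "n_de_significant": len(de_records),
        "manifest": manifest_path,
    }
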