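"""Generate a small synthetic genome with one planted gene family.

The generator writes FASTA/GFF3-backed structure with a truth ledger, so
every downstream analysis can be checked against what was planted.
"""

from zfam import synthetic_data as synth

genome, ledger = synth.simulate_genome(
    synth.GenomeConfig(n_chrom=3, genes_per_chrom=20), seed=11
)
genome, hits, ledger = synth.plant_family(
    genome, ledger, "famA", ["tandem", "tandem", "proximal", "dispersed"], seed=1
)

print(f"chromosomes: {len(genome.sequences)}, genes: {len(genome.genes)}")
print(f"family members: {ledger.planted_families['famA']}")
for gid in ledger.planted_families["famA"]:
    print(f"  {gid}: planted duplication class = {ledger.planted_duplication[gid]}")
print(f"hit-table rows emitted (incl. self-hits): {len(hits)}")
# The class labels are the ground truth the duplicate classifier must
# recover exactly when mutation_rate = 0.
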