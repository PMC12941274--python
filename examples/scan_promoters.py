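"""Extract 2000-bp upstream promoters and count stress-response
cis-elements (the packaged 20-element nematode set) by IUPAC-pattern
scanning."""

from zfam import synthetic_data as synth
from zfam.promoter_cis import extract_upstream, load_packaged_elements, scan_all

genome, ledger = synth.simulate_genome(
    synth.GenomeConfig(n_chrom=1, genes_per_chrom=6), seed=21
)
# plant two daf-16-like words and one degenerate fkh-2 word upstream of g002
requests = {
    ("chr1_g002", "GGATTA"): 2,     # ceh-36
    ("chr1_g002", "RTAAACA"): 1,    # fkh-2, R realized as A or G
    ("chr1_g004", "TTCYAGAA"): 3,   # hsf-1
}
genome, ledger = synth.plant_promoter_motifs(genome, ledger, requests, seed=0)

patterns = load_packaged_elements()
promoters = [extract_upstream(g, genome) for g in genome.genes]
matrix = scan_all(promoters, patterns)

cols = ["ceh-36", "fkh-2", "hsf-1", "any_element"]
print(matrix[cols].to_string())
# each cell: non-overlapping occurrences of the element in that gene's
# promoter; any_element flags genes carrying >= 1 element of any type
print("\nledger says:", dict(ledger.planted_motif_counts))
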