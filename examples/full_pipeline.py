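"""Run the whole synthetic pipeline end to end and print the headline
numbers each stage computed.  Rerunning with the same seed reproduces
every output byte for byte (see the manifest of SHA-256 hashes)."""

import json

from zfam.integration import run_pipeline

summary = run_pipeline("scratch/example_run", seed=5)
print(json.dumps(summary, indent=1, default=str))
# n_family_genes: planted family members across all families
# duplication_counts: classifier output over the family subset
# tandem_enrichment_q: BH-corrected hypergeometric tail for tandem excess
# kaks_frac_lt1: fraction of simulated homolog pairs with omega < 1
# n_de_significant: genes passing |FC| > 2 and p < 0.05
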