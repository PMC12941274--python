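# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic-data generator does and does not
emulate, and the numerical edge-case policies.

## Coordinates and formats

All external files follow their formats' conventions (GFF3 and result
tables 1-based inclusive); everything in memory is 0-based half-open.
The conversion happens only in `io_formats`, so off-by-one behaviour is
auditable in one place and write→read round-trips are identity maps.
Nucleotide input is restricted to A/C/G/T/N; other letters are rejected
so that pattern-scanning semantics stay unambiguous. A gene's start
codon is the strand-aware first CDS base of its longest-CDS transcript —
the longest-isoform convention used throughout for representative
proteins (ties break to the lexicographically smallest identifier).

## Promoter extraction and cis-element scanning

The promoter window is the 2000 bp immediately upstream of the start
codon, strand-aware: for a plus-strand gene with ATG at 1-based position
s, the interval [max(1, s−2000), s−1] as-is; for a minus-strand gene the
mirrored downstream interval, reverse-complemented. Windows clipped at a
chromosome boundary are flagged truncated; a gene whose ATG sits at
position 1 yields an empty promoter and zero counts, not an error.

Position frequency matrices collapse to IUPAC degenerate consensi by the
Cavener-style column rule: with counts sorted c1 ≥ c2 ≥ c3 ≥ c4 and
total T, emit the single top base if c1 > T/2 and c1 > 2·c2; else the
two-base code if c1 + c2 > (3/4)·T; else the three-base code if c4 = 0;
else N. Ties break in A,C,G,T order. Consensi compile to character-class
regular expressions (R → [AG], ..., N → [ACGT]); since classes never
contain N, an N in the scanned sequence matches nothing.

Counting is non-overlapping, left-to-right greedy, on the extracted
strand only, case-insensitive — the behaviour of `gregexpr`-style
scanning. Overlapping counting and both-strand scanning exist as keyword
switches because neither policy is universal in the literature; the
defaults are the package's choice and are documented where they matter
(e.g. "ATATA" vs "ATA" counts 1 non-overlapping, 2 overlapping).

## Duplicate-gene classification

Hits with e ≥ 1e-5 and self-hits are discarded; the surviving hits form
an undirected homology graph, so every result is invariant to
query/subject order and row permutation. Genes are ranked 0..n−1 per
chromosome by start coordinate over *all* annotated genes (the
classification context is the whole genome, not the family). A gene is
tandem if some homolog sits at rank distance 1 on the same chromosome;
else proximal at distance 2..10 (the classifier's conventional default
window); else dispersed if any homolog exists anywhere; else singleton.
The whole-genome/segmental class is deliberately omitted — it requires
collinearity-block detection, which is out of scope — so the priority
order is tandem > proximal > dispersed.

## Enrichment statistics

Over/under-representation uses the exact hypergeometric distribution
(scipy's log-binomial implementation; verified against exhaustive subset
enumeration for all populations N ≤ 12). Tests are one-sided in the
observed direction: upper tail when fold enrichment (k/n)/(K/N) exceeds
1, lower tail otherwise; a fold of exactly 1 is tested as depleted (a
documented tie-break). The signed score is ±log10(p), positive for
enrichment. Benjamini–Hochberg q-values follow the step-up formula
q(i) = min_{j≥i}(m·p(j)/j) capped at 1, applied globally across tested
terms; terms with zero study-set genes are skipped by default to avoid
inflating the correction family (switchable). Note the step-up map is
not idempotent as a function — re-adjusting q-values changes them except
at fixed points such as an all-equal vector — but it is a pure,
deterministic function of its input. Set enrichment reports rows passing
q < 0.05 and fold > 2 alongside the unfiltered table.

## Nei–Gojobori Ka/Ks

Site counts: at each codon position the synonymous fraction is
(#single-base changes preserving the amino acid) / (#changes considered
at that position). Under the default convention, changes creating a stop
codon are excluded from both numerator and denominator, and the
position's synonymous and nonsynonymous fractions are complementary, so
S + N = 3·L exactly. The original formulation — stops counted as
nonsynonymous changes — is available as `stops_as_nonsynonymous=True`;
both variants are tested against literal enumeration of all nine
single-base changes per codon.

Differences: codons differing at d ≤ 3 positions are averaged over all
d! substitution orderings, each walked base by base and its steps
classified; orderings passing through a stop codon are excluded unless
every ordering does (then all are kept as fallback). sd + nd = d always.
Verified against literal path enumeration for all 61 × 61 stop-free
codon pairs.

Distances use Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p), undefined (and
flagged, not raised) when p ≥ 3/4; ω = dN/dS is undefined when dS = 0.
Columns with gaps, ambiguity codes or stop codons in either sequence are
dropped pairwise (complete deletion). Codon alignments are built by
back-translating a supplied protein alignment against the source CDS,
with a translation check at every residue. The bootstrap resamples codon
columns with replacement (default 1000 replicates), reports the standard
deviation of replicate distances as the SE, drops replicates with
undefined distances, and is deterministic given a seed.

## Phylostratigraphy

A homolog call requires both reciprocal E-values strictly below 1e-5
("less than", so the boundary value fails). A gene's stratum is the
oldest ladder rung containing at least one species with a called
homolog; genes without any such species fall to the youngest
(lineage-specific) rung. Any-hit evidence per species is used — the
best-hit-only alternative would only matter with conflicting rows for
one species, which the evidence format does not produce. The packaged
default ladder has the four grades used for tardigrade genomes; it is
fully configurable.

## Protein properties

Average (not monoisotopic) residue masses plus one water, matching the
reference web calculator's convention; Kyte–Doolittle GRAVY with the
strict gravy < 0 hydrophilic binary (0 falls on the hydrophobic side);
instability index (10/L)·Σ DIWV over ordered dipeptides with the
conventional unstable > 40 threshold. The DIWV table is injectable,
which keeps the formula testable against a uniform-weight fixture
independent of the published weights.

## Clade grouping

Tree inference is consumed as newick (rooted reading, underscores
preserved). Rooting splits the branch subtending the named outgroup leaf
with a new bifurcating root, preserving all bipartitions. Manual clade
delineation is replaced by a reproducible rule: each named group is the
leaf set of the smallest clade containing all its anchor leaves; anchor
sets must be disjoint and the resulting clades non-overlapping, so the
partition is deterministic and rotation-invariant.

## Integration rules

DE significance is |fold change| > 2 and p < 0.05, both strict, on the
linear scale (|log2FC| > 1); the p-value column defaults to the raw p,
configurable for adjusted values. Group summaries flag a group monotone
when all its significant members share one direction (NA when none are
significant). Localisation reconciliation always takes the primary
predictor's compartment; the auxiliary predictor can only raise a
conflict flag. The pipeline driver logs a JSON-lines manifest with the
SHA-256 of every output so reruns can be diffed exactly.

## Synthetic data and what passing tests show

The generator emulates the *structure* the analyses consume, not the
biology of real genomes: single-exon genes (no introns), iid intergenic
background at a configurable GC fraction (no repeats or higher-order
composition), alternating strands, and homology emitted directly as hit
tables (sequences are nevertheless mutated copies, so a real aligner
could regenerate an equivalent table). Codon-pair divergence uses an
acceptance-rejection scheme — nonsynonymous proposals accepted with
probability min(1, ω), synonymous with min(1, 1/ω), stop-creating
proposals always redrawn — which reproduces the dN/dS signal but not
transition/transversion bias or rate heterogeneity. Consequently,
passing tests demonstrate the correctness of the *computations* (exact
recovery of planted structure, oracle equivalence, determinism), not
robustness to alignment error, annotation noise or compositional
complexity in real data.

Default study conditions: genomes of 3–5 chromosomes with 20–100 genes
each and 2200 bp intergenic spacing (so full 2000 bp promoters fit);
families of ~5 members covering tandem/proximal/dispersed modes; ω
recovery at L = 500 codons, 150 substitution events, 20 replicates per
ω ∈ {0.2, 1.0}; the tandem-enrichment scenario plants 40% tandem genes
in a 20-gene family against ~5% in a ~500-gene genome. These sizes make
the full suite and the acceptance script run in seconds while leaving
the statistical checks overwhelming margins.

Two ledger conventions matter. Duplication ground truth is recomputed
from the final gene geometry after each planting (a later insertion can
change an earlier rank distance); the derivation is geometric — nearest
same-family member distance — and independent of the hit-graph
classifier it validates. Planted motif counts are recorded as verified
by a brute-force sliding-window scanner on the finished promoter:
because several packaged elements are textually coupled (TGACTCA is a
substring of ATGACTCA; elt-2 and elt-3 share one motif; fkh-2's
degenerate word matches inside daf-16's), requested counts are not
always jointly realizable, and spurious background matches are scrubbed
by single-base edits that never touch a planted word. The ledger is
therefore verifiable from the emitted files alone, by an independent
code path from the production regex scanner.

One RNG stream per operation, derived from the master seed by a stable
integer label, keeps every stage's draws independent of whether other
stages run. All operations are deterministic given (config, seed);
the pipeline's byte-identical rerun check rests on that.

## Known limitations

No GTF dialect, no SAM/VCF, no collinearity/WGD detection, no
maximum-likelihood ω, no score-threshold PWM scanning, no motif
discovery, no GO DAG propagation (annotations are consumed as given),
and no secondary-structure prediction. The domain census counts
distinct proteins carrying a domain (matching the "domain proteins"
denominator and keeping m ≤ 1); the raw-instance reading is available
via `count_instances=True` but is not the default.
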