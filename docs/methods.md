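# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nbscensus`, in the spirit of a software methods appendix.

## Architecture coding and the eight NBS types

A gene qualifies as NBS-encoding iff it has at least one NB-ARC domain
hit; genes with only LRR/TIR/CC/RPW8 hits are ignored. The architecture
code is computed relative to a single *reference* NB-ARC — the hit with
the smallest protein start (ties by end). A prefix letter is emitted if
any TIR, CC or RPW8 hit *starts strictly before the reference NB-ARC
start*; when several classes qualify the precedence is **T > R > C**.
TIR is the strongest phylogenetic marker of the family's deep split and
RPW8 the next-most-specific domain, so they outrank the weakly specified
coiled-coil; the choice is logged whenever it is exercised. An `L` suffix
is emitted if any LRR hit starts strictly after the reference NB-ARC
*end* — "after the domain" is read as downstream of its full extent, not
merely of its start. Repeated same-class hits (multiple LRR repeats)
collapse into one letter. The resulting code is one of
{N, CN, RN, TN, NL, CNL, RNL, TNL} and maps identically onto the type
enum; census percentages are half-up rounded to two decimals to match the
conventional table precision.

Coiled-coil calls are taken as given in the domain table: the package
consumes detector output (HMM or COILS-style) and does not re-run or
intersect detectors.

## Cluster detection: the chained 200-kb rule

The rule is defined on *adjacent* gene pairs: per chromosome or scaffold,
with genes sorted by (start, end, id), genes i and i+1 link iff
`end(i+1) − start(i) < 200 000` (strict; a difference of exactly 200 kb
does not link). Maximal chains of linked adjacent pairs with ≥ 2 members
are clusters. Because the rule chains transitively, a cluster's total span
can far exceed 200 kb — the only reading compatible with clusters of tens
of members. Only NBS genes participate; intervening non-NBS genes are
invisible to the rule. Enlarging the window can only add links, so the
number of clustered genes is monotone in the window (property-tested).
Summaries round the clustered-gene percentage and mean members half-up to
one decimal. With zero clusters the mean is reported as 0 with an
explicit "undefined" flag rather than NaN.

## Global alignment and the similarity census

Distances are pairwise quantities, so the package computes them from
pairwise Needleman–Wunsch global alignments rather than a progressive
multiple alignment: the censused statistics (matched length, identity
over matched columns) are unchanged by that substitution while the cost
drops from cubic-ish MSA to independent O(nm) pairs.

The aligner is an affine-gap NW over BLOSUM62 with gap open 10 and
extend 0.5 (classic protein defaults): the first column of a gap run
costs `open`, later columns `extend`, and a gap switching sides re-opens.
Ties in the DP prefer substitution over a gap in the second sequence over
a gap in the first, which makes the traceback deterministic. The unknown
residue X scores 0 against everything and is never counted as identical.
The kernel is a numba-compiled DP with full traceback (~3 ms for a pair
of 600-residue proteins after a one-off JIT compile).

Matched length m counts columns with residues in both rows; distance is
`1 − identical/m` and similarity its complement. The ClustalW-lineage
"genetic distance" is uncorrected identity under default flags, so the
uncorrected distance is the default; a Kimura-corrected variant
(`kimura=True`) is provided but off. Every boundary in the census is
strict, mirroring "more than / greater than / less than": pairs survive
the length filter iff m > 200 aa (the NB-ARC domain is ~300 aa, so
genuine family members comfortably pass), a gene counts at level t iff
its best similarity exceeds t/100, and the low-similarity list collects
genes whose *best* similarity is strictly below the cutoff — including
genes with no surviving record at all. An optional shared-k-mer prefilter
(off by default) can skip hopeless pairs; its output is explicitly a
heuristic subset.

## Synteny chaining

Anchors keep each A-gene's top-5 best-scoring partners (ties at fifth
place all kept), with ranks assigned per chromosome by start-position
order. Anchor scores are the aligner's scores; a configurable score floor
stands in for an external aligner's E-value cutoff, so no BLAST run is
needed. Per chromosome pair, an exact DP finds the maximum-scoring chain
with strictly increasing rank in A, strictly monotone rank in B (both
orientations tried; ascending wins exact ties), adjacent-anchor rank gaps
of at most 25 on both sides, and a penalty of 1 per rank skipped. Blocks
are extracted greedily: the best chain is removed from the pool, kept if
it has ≥ 5 anchors (MCScanX's published defaults: min block 5, max gap
25), discarded otherwise, and the search repeats on the remainder — so no
anchor appears in two blocks. The gene universe for ranks is whatever
gene set the caller supplies (the pipeline supplies the NBS gene sets).

## Distances, neighbor joining and bootstrap

For tree building, p-distances are computed with pairwise deletion
(columns with residues in both rows); complete deletion is available and
removes columns with a gap in *any* row first. The protein Kimura
correction `d = −ln(1 − p − 0.2 p²)` — the conventional reading of a
"Kimura" distance on amino-acid data in the MEGA/ClustalW lineage — is
the default; it diverges as p approaches ~0.854, beyond which the
distance is capped at 10 and flagged, and a raw p-distance mode is
available as the alternative reading.

Neighbor joining is the standard Saitou–Nei scheme: join the pair
minimizing Q, branch lengths from the usual formulas (negative lengths
clamped to zero and logged), final trifurcation solved by the exact
three-point equations. Q-ties break to the lowest (i, j) in current
matrix order, so trees are deterministic for a fixed input; on exactly
additive matrices the generating topology is provably recovered
(tested against random additive trees, and cross-checked against
scikit-bio's independent NJ implementation).

Bootstrap supports resample alignment columns with replacement, rebuild
the tree per replicate, and report for each internal edge of the original
tree the percentage of replicates containing its bipartition (attached as
the internal node label, integer percent). The default is 1000 replicates;
the test suite and acceptance script use 100–200 to stay fast, which only
coarsens the support granularity. Replicate pairs that lose all shared
columns fall back to the saturation cap instead of aborting the
replicate set.

The multiple alignment consumed here can come from any aligner; for
synthetic data the package uses its own reference-star alignment (align
everything to the longest sequence, project gaps into common columns). It
is a deliberate stand-in for a real progressive MSA: adequate for
same-family synthetic proteins whose differences are substitutions, not a
general-purpose aligner.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not real sequences. Every gene is a concatenation of per-class domain
blocks (TIR 150 aa, CC 60, RPW8 140, NB-ARC 280, LRR 70 ×2, with 5-aa
random linkers) drawn from ancestral class motifs fixed by an internal
seed. Species identity = ancestral motifs mutated at `species_divergence`
(default 0.25, giving ~50–56% cross-species identity between independent
diploids); per-gene variation = species motifs mutated at `gene_noise`
(default 0.15, placing same-type paralogs near 70–75% identity). These
two rates bracket the 80% census level the analysis pivots on: orthologs
inherited into a tetraploid at divergence 0.05 sit near 95% identity and
pass, paralog background does not. NB-ARC at 280 aa guarantees same-family
pairs exceed the 200-aa matched-length filter, so the filter is exercised
rather than emptied.

Mutation is substitution-only (uniform over the 19 other residues,
length-preserving), so true domain coordinates remain valid after
mutation and the domain table can carry exact block positions. This is
also the model's main simplification: no indels, no selection, no
nucleotide-level realism — passing tests show the *pipeline arithmetic*
is right under controlled conditions, not that the generator mimics real
cotton proteins.

Placement shares the 200-kb constant with the detector: cluster groups
are laid out with adjacent spacings that always link (inter-gene offsets
≤ ~116 kb against gene lengths of 2–6 kb) and groups are separated by
≥ 250 kb so they never link. Cluster sizes are 1 + geometric(p), with p
per preset (0.45 ≈ mean 3.2 members for the A-genome preset, 0.22 ≈ 5.5
for the D-genome preset). Exon counts are 1 + Poisson(mean − 1) per type.
The presets encode the published diploid census shapes: type proportions
from the 246- and 365-gene complements, cluster fractions 74.0% and
78.6%, and per-type exon means chosen to give overall means near 2.3 and
2.8–2.9.

Allotetraploids: with inheritance bias β, `round(β·(n_A+n_D))` gene
copies descend from parent A and the rest from parent D — sampled without
replacement while possible, with extra copies (duplicates) once a parent
is exhausted. Copies are mutated at the per-subgenome divergence, keep
parent chromosome order on A-/D-prefixed chromosomes (so collinearity
with parents is built in), and extra copies sit adjacent to their source
so they join its cluster. Loss and tandem duplication are applied as
rounded fractions of the copy list. At β = 0.5 with equal parents and no
loss every parent gene is inherited exactly once, so census comparisons
tie; tests probing the unbiased case add 10% loss to break the
degeneracy.

## Numerical and formatting choices

* All genomic coordinates are GFF3-style 1-based inclusive end to end;
  nothing converts internally, eliminating off-by-one risk in the 200-kb
  arithmetic.
* Printed percentages use decimal half-up rounding (`round_half_up`),
  not banker's rounding: two decimals for the type census, one for
  cluster/exon summaries, integer (default) or one decimal for the
  similarity census and synteny proportions.
* Exon counts come from each gene's first-listed mRNA (isoform handling
  is otherwise undefined when a table reports one exon number per gene);
  genes with no exon features fall back to 1 with a warning.
* HMMER domtblout hits use envelope coordinates, HMMER's recommended
  domain extent.
* Multi-NB-ARC genes code against the leftmost NB-ARC, since the coding
  rule is phrased relative to a single domain position.
* Strand is recorded but never used by clustering or synteny.

## Problem sizes

The test suite and the acceptance script run scaled-down problems chosen
as the package's own defaults for a quick desk run: diploids of 20–40
genes on 3–5 chromosomes (246/365 genes for the census round-trip
checks), 100–200 random layouts for oracle equivalence, anchor sets of
≤ 12 for exhaustive chain enumeration, additive matrices of ≤ 12 taxa,
and 100–200 bootstrap replicates. The genome-scale published counts enter
only as *inputs* to the summary arithmetic, which is exact at any scale.

## Known limitations

* The aligner is global-only; no local or semi-global modes.
* The star MSA is not a general aligner (see above).
* Block extraction is greedy per chromosome pair; a discarded short chain
  could in principle shadow an alternative longer chain sharing its
  anchors. The behavior is deterministic and oracle-tested, but it is a
  heuristic, as is MCScanX's own extraction.
* The generator's inheritance model samples genes, not chromosomal
  segments; subgenome-scale rearrangements are out of scope.
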