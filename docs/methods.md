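# Methods

This note documents the models, statistics, and design choices behind
regulonkit, in the order the pipeline runs them, together with the
assumptions a user should know before trusting the output.

## Inputs and conventions

The pipeline consumes a single circular replicon (FASTA; multi-record
files use the first record with a warning — plasmids are out of scope), a
DOOR2-style operon table, and a pre-normalized log-ratio expression matrix
with a paired control/treatment design. Coordinates are 1-based inclusive
on disk (the convention of GenBank and the operon databases) and 0-based
half-open in memory; the conversion is involutive and tested. Ambiguity
codes other than N are rejected because the PWM machinery is defined over
{A,C,G,T}; windows containing N are never counted as motif sites.
Expression values are used as provided — normalization (e.g. LOWESS for
two-color arrays) is the provider's responsibility.

## Differential expression

Each gene is tested with a paired Wilcoxon signed-rank test
(treatment − control per replicate pair). Zero differences are dropped and
tied absolute differences midranked, the standard conventions. For n ≤ 25
informative pairs the exact null distribution of the positive-rank sum W⁺
is obtained by convolving ½(δ₀ + δᵣ) over the observed (doubled, hence
integer) ranks; this conditions on the observed tie pattern and therefore
remains exact under ties, where textbook tables and scipy's exact mode do
not apply. Beyond n = 25 a normal approximation with tie and continuity
correction is used. Two-sided p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).

Significance defaults to raw p < 0.05. With eight pairs the smallest
achievable two-sided p is 2/2⁸ = 0.0078, so Benjamini–Hochberg control is
largely vacuous at this sample size; adjusted values are nevertheless
always reported, and the unpaired rank-sum test is available behind
`paired: false` for designs without a meaningful pairing. Direction is the
sign of the median paired difference; a zero median gives `none`.

## Co-expression modules

Operon profiles are arithmetic means of member-gene profiles (operons with
no expressed gene are dropped and logged). Agglomerative clustering uses
Euclidean distance with complete linkage (the default of the classical R
hierarchical-clustering routine; average and single are configurable), and
the tree is cut at h = cut_fraction × max pairwise distance with
cut_fraction = 0.05. "Max distance" is read literally as the maximum of
the pairwise distance matrix, not the dendrogram root height; under
complete linkage the two differ only in degenerate cases. Clusters larger
than 200 operons are removed (large agglomerates disproportionately
attract false members) and singletons are dropped; both removals are
logged, so the partition accounting (kept + removed + singletons = total)
is checkable. Module ids are assigned by descending size then smallest
member operon id, making the partition invariant to input row order.

Note the structural consequence of the proportional cut: modules are only
recoverable when between-module separation exceeds within-module scatter
by roughly 1/cut_fraction. Real expression data that violates this will
produce few, large, or no modules — that is a property of the cut rule,
not a bug.

## Promoters

The promoter of an operon is the 300 bp (configurable) immediately
upstream of the translation start of its first transcribed gene — leftmost
gene on the + strand, rightmost on −, since operon-level transcription
start sites are generally unavailable. Minus-strand promoters are
reverse-complemented so the returned string always reads 5'→3' into the
start codon. Windows may wrap the origin of the circular chromosome
(implemented by indexing the doubled genome string); on a linear genome an
insufficient upstream region yields a truncated, flagged promoter.
Promoters overlapping upstream coding sequence are deliberately not
trimmed: the extraction rule is a fixed window, and trimming would couple
promoter content to annotation density. Divergent operon pairs may share
(reverse-complemented) upstream DNA; this is allowed and logged.

## Motif discovery

The finder is a deterministic seed–extend–refine search for fixed-width
(w = 12) PWMs in a CEM's promoter set, scored against an order-0
background estimated from the whole genome:

1. **Seeding.** All exact 8-mers (both strands) with count ≥ expectation +
   2·√expectation under the background are candidates; the `seed_cap`
   (default 40) candidates with the smallest Poisson count tails are
   refined. The cap bounds runtime on noisy inputs where thousands of
   words clear the 2σ rule; refining a word with a weak count tail cannot
   produce a motif that survives the significance floor below, so the cap
   loses essentially nothing.
2. **Extension and refinement.** Each seed word is centered in a width-w
   PWM (0.85 on the seed base, background flanks) and refined by
   hard-assignment EM: pick the best window per promoter (both strands,
   zero-or-one occurrence per sequence — regulon membership downstream is
   per-operon binary), re-estimate the PWM from those windows with a
   background-proportional pseudocount of 2, and stop after 20 passes or
   a relative log-likelihood change below 1e-4.
3. **Sites and score.** A promoter contributes a site only if its best
   window's log₂ odds reaches **half the PWM's maximum achievable
   log-odds**. A positive-log-odds criterion is far too permissive: for a
   sharp 12-column PWM a random window exceeds 0 with probability ~10⁻³,
   so every promoter's best-of-~580 windows would qualify. The motif score
   is the summed log₂ odds over sites.
4. **Significance.** The probability q that a random background window
   reaches the site threshold is computed exactly by convolving the
   per-column score distributions on an integer grid (discretization error
   ≤ w/(2·200) score units), giving λ = q × windows scanned and a Poisson
   upper tail on the observed site count. Because the refined PWM was
   trained on the very windows it counts, that tail alone is
   anti-conservative under the null; the reported p is therefore floored
   by the seed word's own exact count tail, which involves no refinement
   and is honestly calibrated. The adjusted p multiplies by the full
   enumerated seed family (4⁸), the size of the search actually performed.
   Motifs with adjusted p < 0.001 are kept (the looser raw-p 0.05 gate is
   available in config), deduplicated at pairwise similarity > 0.95
   (higher score wins), and the top 5 per CEM are pooled.

Null calibration was the binding constraint in this design: on 20 i.i.d.
background promoters the procedure must (and, per the test suite, does)
report no motif at adjusted p < 0.001 in ≥ 95% of replicates, while exact
planted 12-mers reach adjusted p ~ 10⁻²⁰ and IC-1.5-bits/column sampled
sites ~ 10⁻⁴–10⁻¹⁶. Small promoter sets (≲ 10 sequences) cannot clear the
family-wise floor — a deliberate sensitivity/honesty trade-off.

## Motif clustering and regulons

Similarity between two column-stochastic PWMs is the maximum over relative
offsets (overlap ≥ 6 columns) and both orientations of the mean per-column
term 1 − ‖a_c − b_c‖₂/√2: identical PWMs score exactly 1, maximally
different deterministic columns score 0, and reverse-complement pairs are
recognized (an all-A PWM vs an all-T PWM scores 1 in rc orientation).
Clustering processes edges in descending similarity through a union–find
while similarity ≥ T, which is provably the connected components of the
thresholded graph — hence deterministic regardless of tie order. T₁ = 0.8
partitions motifs into highly reliable clusters; T₂ (default 0.6 — a value
the source study leaves unstated, so it is exposed in config and recorded
on every regulon) additionally records relatively-reliable merges with
references to their T₁ children. A regulon is a motif cluster plus the
exact union of its member motifs' site operons (and their genes); ids are
assigned by descending operon count, then smallest motif id.

## Annotation and validation

**TFBS library matching.** For each (query motif, library entry) pair the
similarity above is compared against a null of 1000 column permutations of
the query, p = (1 + #null ≥ observed)/(N + 1), E = p × library size,
gate E < 0.05. Column shuffling preserves the query's composition, so
low-complexity motifs (e.g. poly-A/T) legitimately struggle to reach
significance — matches at the gate boundary should be read accordingly.
The permutation-matrix implementation precomputes the per-column term
matrix once per pair, so the 1000 shuffles cost one gather each.

**TF mapping.** Template TF proteins are scanned against the target
proteome with Smith–Waterman (BLOSUM62, gap open 11 / extend 1) and the
best score converted to an E-value via Karlin–Altschul with the standard
gapped-BLOSUM62 parameters (λ = 0.267, K = 0.041). The default gate is
E < 10⁻⁵ (ortholog scale); literature gene mapping uses the stricter
10⁻¹⁰. A 12-column tabular adapter accepts external alignment output in
place of the built-in scan.

**Verdicts.** A regulon is `computationally_verified` iff it contains at
least one DEG and has a mapped TF; TFBS-matched regulons failing that are
`candidate`; unmatched regulons are `excluded`. The sieve counts
(TFBS-matched → DEG-containing → TF-mapped → verified) are logged and the
chain is asserted monotone. DEG enrichment per regulon is the exact
hypergeometric upper tail P(X ≥ k), with the universe taken as the genes
of the retained CEMs — the population that was actually clustered.

**Set comparison.** Given the computationally verified set C, the
literature-supported set L, the TFBS-matched (significant) set S and the
full regulon set A: the false-positive fraction is |C\L|/|C| and the
insignificant-but-supported fraction is |L ∩ (A\S)|/|A\S|. On the packaged
tables these reproduce 1/5 (the ccpA regulon, #15, is the one verified
regulon without literature support) and 2/37 (regulons #8 and #39).
When a TF name tags several regulons (llrA → #12 and #37, ccpA → #15 and
#47), name resolution prefers the DEG-containing representative, matching
the convention of naming the retained regulon after its TF.

## Packaged annotation tables

Three curated TSVs for the *L. lactis* MG1363 acid-stress study ship as
package data: the 14 TFBS-matched regulons with operon counts, DEG status,
template and mapped TFs; the 36 literature-collected acid-response
templates with their 33 mapped locus tags, nine functional modules (LDH,
GAD, ADI pathway, urea degradation, F0/F1ATPase, acid response, protein
repair and protease, envelope alterations, DNA repair) and regulon
assignments; and a network-curation table carrying the literature-only
elements (H⁺ sensor, the rcfB global-initiator TF, two transmembrane
proteins) as `uncertain` edges. One known inconsistency is preserved
as-is: NHP6A is unmapped ("N/A") in the regulon-TF table yet anchors
regulon #20 in the literature table; the loaders encode both facts and no
resolution is attempted.

## Network assembly

Nodes are every computationally verified or literature-supported regulon,
every functional module with ≥ 1 mapped gene, every mapped gene, plus TF
genes and curated elements; edges are regulon→module `regulates` (with
provenance computational, literature, or both, depending on whether the
module's genes fall inside the regulon's computed gene set),
module→gene `contains`, regulon→TF-gene `maps_to`, and curated
`uncertain` edges. Modules that no regulon reaches (GAD, urea degradation
in the curated tables) remain as orphan nodes. Self-loops are forbidden
and `regulates`/`uncertain` edges must originate from regulator-typed
nodes; JSON export round-trips losslessly, GraphML carries all attributes.

## Synthetic data generator

The generator emulates the *structure* of the study, not its biology: an
i.i.d. genome at GC 0.35; 300 operons (10 planted regulons × 20 members +
100 background) of 1–2 genes, placed with ≥ 400 bp intergenic gaps so the
300 bp promoter windows stay intergenic; per-regulon PWMs built
column-wise from Dirichlet draws sharpened to 1.5 bits/column, with
PWM-sampled sites planted on either strand in 90% of member promoters
(collisions in shared intergenic DNA are re-drawn or skipped so the
ground-truth manifest always matches the emitted genome); and expression
built from a latent profile per (regulon, replicate pair) shared by the
control and treatment sample of that pair, plus gene-level N(0, 0.5²)
noise and a +2.0 log-ratio treatment shift for the 50% of regulons flagged
DE. Background operons get independent latent profiles and so fall out of
clustering as singletons.

The latent-profile amplitude (default 15 log-ratio units) is deliberately
large: the proportional dendrogram cut (h = 5% of the maximum pairwise
distance) demands between-module separation ≈ 20× within-module scatter,
and the generator's job is to realize the regime in which the published
cut rule is meaningful. Consequences for interpretation: passing recovery
tests demonstrates the pipeline's correctness under clean planted
structure — they say nothing about noisy real data where co-expression
modules blur, operon maps err, or motifs are variable-width. Codon
structure, realistic operon length distributions, and array-level
artifacts are explicitly not modeled.

Recovery is scored by matching each planted regulon to the inferred
regulon maximizing operon-set Jaccard (recovered ⇔ J ≥ 0.5), plus a
consensus Hamming distance that minimizes over both orientations and
shifts up to ±2 columns, counting each shifted column as a mismatch.

## Determinism and numerics

A single `rng_seed` governs every stochastic stage (synthetic generation,
shuffle nulls); EM refinement, clustering, and regulon numbering are
deterministic by construction, and a rerun with identical inputs and
config reproduces byte-identical TSV outputs. Ties: similarity ties need
no tie-break (component clustering is order-invariant); motif ranking
breaks ties by adjusted p then score; module and regulon numbering break
ties lexicographically. Exact-test grids: signed-rank ranks are doubled to
integers; PWM score distributions are discretized at 1/200 of a log₂ unit.
Degenerate inputs (all-zero differences, empty DEG sets, empty libraries,
single promoters) return the defined degenerate results or raise typed
errors, all covered by tests.

## Problem sizes used in validation

The validation suite runs planted-recovery at the default scenario (300
operons, 10 regulons), 20 replicates of single-CEM consensus recovery, and
100 replicates of null calibration; the exhaustive statistics checks cover
all hypergeometric configurations with N ≤ 30 and signed-rank enumeration
for n ≤ 10. These sizes were chosen so the full suite and the acceptance
script each complete in about a minute on one CPU while still exercising
every stage at study-like scale.

## Known limitations

- The motif finder is a fixed-width, single-motif-per-promoter model; no
  gapped or variable-width motifs, no phylogenetic footprinting.
- The TFBS-match null penalizes low-complexity motifs; the TF-mapping
  E-value uses ungapped Karlin–Altschul parameters applied to gapped
  scores, the standard pragmatic approximation.
- Operon prediction, expression normalization, and TSS identification are
  consumed, not performed.
- The curated-table analyses reproduce bookkeeping over published
  annotations; they do not re-derive those annotations from raw data.
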