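# Methods

This note records the models, conventions and numerical choices behind
`concord16s`, and what the synthetic validation does and does not show.

## Data model

A *feature table* is a features × samples matrix of non-negative integer
read counts. A *cluster set* bundles one clustering method's table with a
centroid (representative) DNA sequence per feature, a seven-rank
Greengenes-style taxonomy string, and an optional cluster origin
(`reference` / `de_novo` / `unknown`). Taxonomy strings are canonicalized
on input: once a rank is empty, every deeper rank is emptied too (with a
logged warning if labels had to be dropped). This makes the
"informative tag" predicate well defined — a lineage is informative at a
rank iff its label there is non-empty — and makes read-resolution profiles
monotone non-increasing with depth.

Feature tables are plain TSV (features in rows), sequences FASTA (RNA is
normalized to DNA; anything outside ACGT is rejected rather than guessed),
trees Newick. A branch without an explicit length is an error, never a
silent zero. Readers preserve file order; writers are deterministic, so
write–read round trips are exact.

## Filtering

Two filters run in a fixed order, once each:

1. **Sample singletons** (default mode): every cell equal to 1 is zeroed —
   a single read of a feature within a sample is treated as noise in that
   sample — then all-zero features are dropped. A whole-table mode
   (features with exactly one read in total) is available behind a flag.
2. **Tailored abundance filter**: a feature is kept iff
   count/sample_total ≥ θ (default θ = 0.1%) in *at least one* sample,
   with per-sample totals taken from the input table in a single pass.
   Kept features keep all their counts. The comparison is done in exact
   integer arithmetic (`count · den ≥ num · total`), so the boundary case
   (exactly 0.1%) is inclusive and float-free; a zero-total sample simply
   contributes no qualifying ratio.

The filter is applied once because removal lowers the totals: re-running
on its own output with recomputed denominators is not guaranteed to be a
no-op in general (a test verifies it is one on fixtures with wide margins).

Taxonomic collapsing sums features sharing an identical lineage prefix
through the requested rank; lineages truncated at different depths form
distinct keys, so "unassigned at this rank" rows stay separate and total
reads are conserved exactly at every level.

## Sequence comparison

Pairwise comparison is a global end-to-end alignment under unit costs
(match 0, mismatch 1, indel 1), computed with edlib: *changes* is the edit
distance (mismatches plus gap columns) and *identity* is matching columns
over alignment columns of one optimal path. Unit costs were chosen because
the analysis counts "single nucleotide changes including indels and
mismatches" with no gap-open parameter to tune. When several optimal
alignments exist the identity is that of the path edlib reports; the test
suite brackets it between the minimum- and maximum-match optimal
alignments of an independent DP.

The difference profile reports, per centroid, the change count to its
nearest other centroid whose identity is ≥ 75% (a floor roughly at the
divergence of related phyla; more distant pairs are not meaningful
"variants" of each other). The cumulative curve divides by all centroids
in the stratum, so centroids without a qualifying neighbour never enter
any bin.

Greedy clustering (for resilience curves and the 97%-merge emulation)
processes sequences in decreasing read abundance with a lexicographic
tie-break — deterministic and seedless, emulating abundance-sorted
centroid clustering. Each threshold of a resilience sweep is clustered
independently (no nesting across thresholds); pairwise identities are
computed once and reused.

Exact overlap partitions the union of centroid sequences into Venn
compartments by string equality on the given strand (all sets derive from
identically oriented amplicons, so no reverse-complement matching).
Compartment reads sum every member set's reads for the sequence, so
compartment totals add up to the grand total over sets, exactly.

## α diversity

Rarefaction is a multivariate-hypergeometric draw (subsampling without
replacement); every draw sums exactly to the depth, by construction the
smallest sample's total. Estimators per draw: observed features; Shannon
entropy in nats with 0·ln 0 := 0; bias-corrected Chao1
S_obs + F₁(F₁−1)/(2(F₂+1)), which is ≥ S_obs and equals it when
F₁(F₁−1) = 0. Point estimates are means over iterations (default 10,000;
the tests and drivers use 50–1,000 — the means stabilize far below the
default at these problem sizes, and the contracts are iteration-count
invariant).

The group comparison is deliberately nonparametric, since only "sample
medians at α = 0.05" is specified by the design: Wilcoxon–Mann–Whitney for
two-level factors (exact p for groups of ≤ 10, normal approximation with
tie correction otherwise) and Kruskal–Wallis for the four organ×pond
groups. If every sample's point estimate is identical the comparison is
reported as degenerate with p = 1 rather than producing a 0/0 tie
correction.

Seeding: one master seed is expanded with `numpy.random.SeedSequence.spawn`
into one independent stream per sample, so results are bit-reproducible
and independent of evaluation order.

## β diversity

Tables are standardized by *average rarefaction*: the elementwise mean of
n independent rarefied draws (default 100), kept real-valued. Presence for
Jaccard on the averaged table is "> 0".

Distances: Bray–Curtis Σ|x−y|/Σ(x+y); Jaccard 1 − |∩|/|∪| on presence;
UniFrac over the tree sheared to the two samples' observed features —
unweighted = unique branch length / observed branch length, weighted_raw =
Σ_b ℓ_b |p_b(x) − p_b(y)| with p_b the fraction of a sample's reads below
branch b, and weighted_normalized divides by Σ_b ℓ_b (p_b(x)+p_b(y)).
Normalized weighted UniFrac is the default weighted variant (bounded
[0, 1], comparable with the other metrics); the raw form stays available.

PCoA is the classical Gower construction: eigendecompose the
double-centered −½D², coordinates from positive eigenvalues scaled by
√λ. Negative eigenvalues (non-Euclidean input) are counted and their
magnitude reported; no Cailliez/Lingoes correction is applied by default.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within)/(n(n−1)/4) on
average-tied ranks of the off-diagonal distances, so R ∈ [−1, 1] and is
invariant under monotone transforms of the distances. The p-value is
exhaustive whenever the label multiset admits ≤ 20,000 distinct
assignments (then p is the exact tail fraction, identity included);
otherwise B random relabelings give p = (1 + hits)/(1 + B) (default
B = 999). Because permutation p-values are discrete, level-α decisions use
p ≤ α. Pairwise post hoc tests are ANOSIMs on each group pair with
Benjamini–Hochberg adjustment (no correction is canonical here; BH is the
conventional default).

## Synthetic study design

The generator emulates the *structure* of a three-method comparison, not
any particular dataset: its purpose is that every designed distortion is
recoverable exactly by the pipeline.

* **Truth**: 40 taxa in a nested taxonomy (families two-per-order, etc.),
  one V3-length centroid per taxon (137–158 nt, inside the 127–168 nt V3
  envelope) mutated from a common ancestor. Families carry disjoint
  substitution blocks (8 nt) and taxa disjoint private blocks within their
  family (5 nt), so within-family distance (10 nt) is strictly below
  across-family distance (≥ 16 nt) — consistent with the taxonomy — and no
  two taxa fall within a 97% identity radius, so the 97%-merge step finds
  nothing to merge under defaults (the merging machinery is exercised by
  its own tests on closer-spaced truths).
* **Abundances**: lognormal (σ = 1), floored at 0.5% relative abundance.
  The floor encodes a deliberate scope choice: the generator models the
  abundant, real fraction of a community; the artifactual rare tail is
  modelled *only* by the satellites. Consequently every true taxon safely
  clears the 0.1% filter and every satellite falls safely below it —
  recovery is exact by design, not by seed luck.
* **Groups**: 2 organs × 2 ponds × 6 replicates (24 samples), nominal
  20,000 reads/sample with CV ≈ 0.15 depth variation, 10% per-sample taxon
  dropout (patchy occupancy). A disjoint 30% of taxa get a 4× organ
  fold-change and 30% a 3× pond fold-change, applied multiplicatively and
  renormalized.
* **Per-set distortions**: the ASV-like set is the truth, with 20% of taxa
  (1 − shared_fraction) carrying a 1-nt variant centroid (different
  paired-end joining); the 99%-OTU-like set adds 5 satellites per top-10
  abundant taxon, each 1–2 nt from its parent and siphoning ~0.1% of the
  parent's reads; the 97%-OTU-like set truncates genus labels with
  probability 0.3 and species labels 0.45, and would merge any taxa within
  its 97% radius. Satellites inherit their parent's taxonomy, so taxonomic
  collapsing re-absorbs them. Trees are average-linkage dendrograms on
  alignment-identity distances — adequate for exercising the UniFrac
  contracts without claiming phylogenetic inference.

What passing tests on this generator do *not* show: robustness to chimeras,
to contaminant lineages, to compositional biases between sets (all three
sets share one multinomial draw here), or to real phylogenies; and the
degenerate identity of the filtered tables across sets is stronger than
real data, where the sets' read totals differ.

## Problem sizes and determinism

Tests and the acceptance script run the study at its default size
(40 taxa, 24 samples, ~20k reads), with 50–1,000 rarefaction iterations,
100 standardization draws, and 199–999 permutations; null calibrations use
500 (ANOSIM) and 200 (rank test) replicates. All stochastic stages take
explicit seeds; an orchestrated run derives per-stage seeds from the
master seed and two runs with the same config are byte-identical.

## Known limitations

* Identity of an optimal alignment is path-dependent when ties exist;
  only the change count is unique.
* Kruskal–Wallis uses the χ² approximation (no exact small-sample table).
* The differential-taxa screen compares set-wide relative abundances; it
  is a screen, not a compositional test (no variance model).
* BIOM/HDF5, FASTQ and chimera handling are out of scope: the package
  consumes standard text outputs of upstream tools.
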