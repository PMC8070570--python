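# concord16s

Concordance analysis of OTU and ASV feature sets from 16S rRNA amplicon
profiling.

## The problem

Microbiome surveys of the same amplicon pool can be clustered three ways:
operational taxonomic units at 97% or 99% sequence identity (open-reference
OTUs) or denoised amplicon sequence variants (ASVs). Whether results from
the three are comparable — in taxonomy, within-sample (α) diversity and
between-sample (β) diversity — decides whether legacy OTU studies can be
compared with newer ASV studies. This package implements the full
comparison pipeline for such a three-way design (motivated by shrimp
*L. vannamei* hepatopancreas/intestine microbiota sampled from two rearing
ponds, hence the *organ* and *pond* grouping factors):

1. **Filtering** — per-sample singleton removal, then a *tailored abundance
   filter*: a feature is kept only if it reaches ≥ 0.1% of the total reads
   in at least one sample. This is the step that reconciles the sets: OTU
   pipelines produce a long tail of low-frequency "satellite" clusters
   whose centroids differ from an abundant centroid by 1–2 nt, and the
   filter removes that tail while preserving nearly all reads.
2. **Sequence concordance** — exact centroid-sequence overlap between sets
   (Venn compartments, read-weighted), nearest-neighbour nucleotide
   difference profiles (unit-cost global alignment; changes = mismatches +
   indels; neighbour eligibility gated at ≥ 75% identity), expected
   identity (L − c)/L for V3-length amplicons, and greedy-clustering
   *resilience curves*: the fraction of sequences that survive as unique
   centroids as the clustering identity threshold rises.
3. **Taxonomy concordance** — per-rank *informative tag* resolution (a tag
   is informative when its terminal node at that rank is non-empty),
   attribution of missing species labels to LCA truncation vs unlabeled
   references, taxa Venn overlaps per rank, cross-set Spearman ρ of
   informative-taxa relative abundances, and a differential-species screen
   (taxa whose abundance elsewhere is < 33% of the reference set's).
4. **α diversity** — observed features, Shannon entropy (nats,
   H = −Σ pᵢ ln pᵢ) and bias-corrected Chao1
   (S_obs + F₁(F₁−1)/(2(F₂+1))), each averaged over rarefied tables drawn
   at the smallest sample's depth; organ/pond/organ-pond groups compared
   with Wilcoxon–Mann–Whitney / Kruskal–Wallis at α = 0.05.
5. **β diversity** — tables standardized by average rarefaction; Jaccard,
   Bray–Curtis and unweighted/weighted UniFrac distances; PCoA (Gower
   double-centering); ANOSIM, R = (r̄_between − r̄_within)/(n(n−1)/4), with
   permutation p-values (exhaustive enumeration when feasible) and BH-
   adjusted pairwise post hoc tests.

A first-class **synthetic generator** (`concord16s.synth`) renders a
ground-truthed community as three linked cluster sets — shared centroids,
designed satellite clusters below the filter threshold, taxonomy
truncation in the 97% set, organ/pond fold-changes — so the entire
pipeline runs and is validated without any sequencing download.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1   # synthetic study
python analysis/02_filter_features.py           # singleton + abundance filters
python analysis/03_sequence_overlap.py          # Venn, profiles, resilience
python analysis/04_taxonomy_resolution.py       # resolution, rho, differential
python analysis/05_alpha_diversity.py           # rarefied alpha + group tests
python analysis/06_beta_diversity.py            # distances, PCoA, ANOSIM
```

Output of the run above (abridged):

```
01_OTU_97: 40 features, 466,937 reads over 24 samples
02_OTU_99: 90 features, 466,937 reads over 24 samples
03_ASV:    40 features, 466,937 reads over 24 samples

02_OTU_99: 90 -> 40 features; abundance filter lost 0.222% of reads
centroids identical in all three sets: 32 (73.68% of all reads)
02_OTU_99: 40.0% of centroids have a 1-nt neighbour
01_OTU_97: reads informative at family 100.0%, genus 82.3%, species 44.4%
species-level Spearman rho: {'01~02': 0.40, '01~03': 0.40, '02~03': 1.00}
01_OTU_97: significant at 0.05 -> pond/shannon (p=0.0404), organ_pond/shannon (p=0.0305)
03_ASV: Bray-Curtis ANOSIM R organ=0.734 pond=0.221 organ-pond=0.904 (p=0.0010)
```

Reading this: the 99%-OTU-like set carries 50 designed satellite clusters
that the 0.1% filter removes completely (90 → 40 features, only 0.22% of
reads lost), after which the three sets are identical in feature count.
The 32 designed shared centroids are recovered exactly in the three-way
Venn compartment. Genus/species taxonomy truncation designed into the
97%-OTU-like set alone drops its informative-read fractions and its
species-level ρ (0.40 vs 1.00 between the untruncated sets) while
family-level agreement stays perfect. The designed organ and pond
fold-changes are detected by Bray–Curtis ANOSIM, with the organ×pond
grouping separating most strongly — the qualitative pattern such
three-way comparisons are expected to reproduce.

An orchestrated end-to-end run (same stages, one config, deterministic
summary JSON) is available as `concord run --config run.toml`, and
`concord synth` writes fixture bundles from the command line.

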