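"""Ground-truthed synthetic fixtures: one true community rendered as three
linked cluster sets emulating 97% OTU, 99% OTU and ASV outputs.

The generator draws a "true" bacterial community -- full seven-rank
lineages, one V3-length (127-168 nt) centroid sequence per taxon mutated
from a common ancestor so that within-family sequences are more similar
than across families, lognormal base abundances, and designated
organ-/pond-responsive taxa with multiplicative fold-changes -- and renders
it as three cluster sets sharing the same underlying reads:

* the ASV-like set holds the denoised truth (one feature per taxon);
* the 99%-OTU-like set adds low-frequency *satellite* clusters around the
  abundant taxa (1-2 nt sequence errors siphoning a small fraction of the
  parent's reads), emulating identity clustering's oversplit rare tail;
* the 97%-OTU-like set merges taxa within its identity radius (none under
  the default sequence spacing) and truncates a fraction of its genus and
  species labels, emulating the coarser set's lower taxonomic resolution.

Every distortion is parameterized and recorded in the truth object so
recovery tests can check the designed structure exactly. The generator
emulates the *abundant, real* fraction of a community (base abundances are
floored at 0.5%); the artifactual rare tail is modelled exclusively by the
satellites, which are designed to fall below the 0.1% per-sample abundance
filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from . import io as cio
from .seqcompare import identity_matrix
from .types import ClusterSet, FeatureTable, PhyloTree, SampleMetadata, TaxonomyString

log = logging.getLogger("concord16s")

BASES = np.array(list("ACGT"))

ORGANS = ("I", "H")  # intestine, hepatopancreas
PONDS = ("F3", "R2")


@dataclass
class SetDesign:
    """Per-set distortion parameters."""

    satellite_count: int = 0  # satellites per abundant taxon
    satellite_error_nt: int = 2  # max nt changes of a satellite vs its parent
    satellite_read_fraction: float = 0.001  # fraction of parent reads siphoned per satellite
    taxonomy_truncation_prob: dict = field(default_factory=dict)  # rank name -> prob
    merge_identity: float | None = None  # merge features at >= this identity
    variant_centroids: bool = False  # non-shared taxa get 1-nt variant centroids


def default_designs() -> dict[str, SetDesign]:
    """The study conditions: distortions per emulated method."""
    return {
        "01_OTU_97": SetDesign(
            merge_identity=0.97,
            taxonomy_truncation_prob={"genus": 0.3, "species": 0.45},
        ),
        "02_OTU_99": SetDesign(satellite_count=5, satellite_error_nt=2),
        "03_ASV": SetDesign(variant_centroids=True),
    }


def identical_sets_design() -> dict[str, SetDesign]:
    """Degenerate design: no distortions, three identical sets."""
    return {sid: SetDesign() for sid in ("01_OTU_97", "02_OTU_99", "03_ASV")}


@dataclass
class TruthParams:
    n_families: int | None = None  # default ~ n_taxa / 5
    family_divergence_nt: int = 8  # substitutions separating a family from the ancestor
    taxon_divergence_nt: int = 5  # private substitutions per taxon within its family
    lognormal_sigma: float = 1.0
    min_rel_abundance: float = 0.005  # floor: every true taxon is non-rare
    organ_effect_fraction: float = 0.3
    organ_fold_change: float = 4.0
    pond_effect_fraction: float = 0.3
    pond_fold_change: float = 3.0
    dropout_prob: float = 0.1  # per taxon, per sample: patchy occupancy
    shared_fraction: float = 0.8
    n_abundant_taxa: int = 10  # taxa that receive satellites


@dataclass
class SyntheticTruth:
    """Designed ground truth used by the recovery tests."""

    n_taxa: int
    seed: int
    taxa: list[TaxonomyString]
    centroids: list[str]
    base_abundances: np.ndarray
    organ_responsive: np.ndarray  # taxon indices boosted in organ H
    pond_responsive: np.ndarray  # taxon indices boosted in pond R2
    shared_taxa: np.ndarray  # indices whose centroid is identical in all sets
    params: TruthParams
    designs: dict[str, SetDesign]

    def group_weights(self, organ: str, pond: str) -> np.ndarray:
        """Expected relative abundances for one organ x pond condition."""
        w = self.base_abundances.copy()
        if organ == "H":
            w[self.organ_responsive] *= self.params.organ_fold_change
        if pond == "R2":
            w[self.pond_responsive] *= self.params.pond_fold_change
        return w / w.sum()

    def to_json(self) -> str:
        payload = {
            "n_taxa": self.n_taxa,
            "seed": self.seed,
            "taxa": [list(t.ranks) for t in self.taxa],
            "centroids": self.centroids,
            "base_abundances": self.base_abundances.tolist(),
            "organ_responsive": self.organ_responsive.tolist(),
            "pond_responsive": self.pond_responsive.tolist(),
            "shared_taxa": self.shared_taxa.tolist(),
            "params": asdict(self.params),
            "designs": {k: asdict(v) for k, v in self.designs.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute a different base at each given position."""
    chars = np.array(list(seq))
    for p in positions:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


def generate_truth(
    n_taxa: int = 40,
    seed: int = 0,
    params: TruthParams | None = None,
    designs: dict[str, SetDesign] | None = None,
) -> SyntheticTruth:
    """Draw the true community: taxonomy, centroid sequences, abundances, effects.

    Sequences mutate a common V3-like ancestor: each family carries its own
    block of substitutions (disjoint across families), and each taxon adds
    private substitutions disjoint within its family -- so within-family
    distances are strictly smaller than across-family distances, consistent
    with the taxonomy, and no two taxa fall within a 97% identity radius
    under the defaults.
    """
    if n_taxa < 5:
        raise ValueError("n_taxa must be >= 5")
    params = params or TruthParams()
    designs = designs if designs is not None else default_designs()
    if params.organ_effect_fraction + params.pond_effect_fraction > 1:
        raise ValueError("effect fractions overlap: together they must be <= 1")
    rng = np.random.default_rng(seed)

    n_families = params.n_families or max(3, round(n_taxa / 5))
    length = int(rng.integers(137, 159))  # V3-like, inside the 127-168 nt envelope
    fam_block = params.family_divergence_nt
    tax_block = params.taxon_divergence_nt
    max_per_family = int(np.ceil(n_taxa / n_families))
    need = n_families * fam_block + max_per_family * tax_block
    if need > length:
        raise ValueError(
            f"sequence length {length} too short for {n_families} families: need {need} positions"
        )

    ancestor = "".join(rng.choice(BASES, size=length))
    family_of = np.sort(rng.integers(0, n_families, size=n_taxa))
    # guarantee every family non-empty
    family_of[:n_families] = np.arange(n_families)
    family_of = np.sort(family_of)

    family_seqs = []
    for f in range(n_families):
        pos = np.arange(f * fam_block, (f + 1) * fam_block)
        family_seqs.append(_mutate(ancestor, pos, rng))

    taxon_pool_start = n_families * fam_block
    centroids, taxa = [], []
    rank_of_family = _family_lineages(n_families)
    within_rank = {f: 0 for f in range(n_families)}
    for i in range(n_taxa):
        f = int(family_of[i])
        k = within_rank[f]
        within_rank[f] += 1
        pos = np.arange(taxon_pool_start + k * tax_block, taxon_pool_start + (k + 1) * tax_block)
        centroids.append(_mutate(family_seqs[f], pos, rng))
        kingdom, phylum, klass, order, family = rank_of_family[f]
        genus = f"Genus{f + 1:02d}{'ab'[k % 2]}"
        species = f"species{i + 1:03d}"
        taxa.append(TaxonomyString((kingdom, phylum, klass, order, family, genus, species)))
    assert len(set(centroids)) == n_taxa

    raw = rng.lognormal(0.0, params.lognormal_sigma, size=n_taxa)
    p = raw / raw.sum()
    p = np.maximum(p, params.min_rel_abundance)
    p = p / p.sum()

    n_organ = round(params.organ_effect_fraction * n_taxa)
    n_pond = round(params.pond_effect_fraction * n_taxa)
    perm = rng.permutation(n_taxa)
    organ_responsive = np.sort(perm[:n_organ])
    pond_responsive = np.sort(perm[n_organ : n_organ + n_pond])

    n_shared = round(params.shared_fraction * n_taxa)
    shared = np.sort(rng.permutation(n_taxa)[:n_shared])

    return SyntheticTruth(
        n_taxa=n_taxa,
        seed=seed,
        taxa=taxa,
        centroids=centroids,
        base_abundances=p,
        organ_responsive=organ_responsive,
        pond_responsive=pond_responsive,
        shared_taxa=shared,
        params=params,
        designs=designs,
    )


def _family_lineages(n_families: int) -> list[tuple[str, str, str, str, str]]:
    """Nest families under orders/classes/phyla two-by-two."""
    out = []
    for f in range(n_families):
        order = f // 2
        klass = order // 2
        phylum = klass // 2
        out.append(
            (
                "Bacteria",
                f"Phylum{phylum + 1:02d}",
                f"Class{klass + 1:02d}",
                f"Order{order + 1:02d}",
                f"Family{f + 1:02d}",
            )
        )
    return out


@dataclass
class FixtureBundle:
    """Three rendered cluster sets plus metadata, trees and the truth."""

    sets: dict[str, ClusterSet]
    metadata: SampleMetadata
    trees: dict[str, PhyloTree]
    truth: SyntheticTruth

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sid, cset in self.sets.items():
            cio.write_cluster_set(cset, directory / sid)
            cio.write_newick(self.trees[sid], directory / sid / "tree.nwk")
        cio.write_metadata(self.metadata, directory / "metadata.tsv")
        (directory / "truth.json").write_text(self.truth.to_json())


def _make_metadata(n_per_group: int) -> SampleMetadata:
    ids, organ, pond = [], {}, {}
    for o in ORGANS:
        for p in PONDS:
            for r in range(n_per_group):
                sid = f"{o}{p}_{r + 1}"
                ids.append(sid)
                organ[sid] = o
                pond[sid] = p
    return SampleMetadata(ids, organ, pond)


def _variant(seq: str, n_changes: int, taken: set[str], rng: np.random.Generator) -> str:
    """A sequence ``n_changes`` substitutions away, distinct from ``taken``."""
    for _ in range(1000):
        pos = rng.choice(len(seq), size=n_changes, replace=False)
        cand = _mutate(seq, pos, rng)
        if cand not in taken:
            return cand
    raise RuntimeError("could not generate a distinct variant sequence")


def _linkage_tree(feature_ids: list[str], sequences: list[str]) -> PhyloTree:
    """Average-linkage dendrogram on pairwise identity distances."""
    if len(feature_ids) < 2:
        raise ValueError("need at least 2 features for a tree")
    dist = 1.0 - identity_matrix(sequences)
    z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(z, feature_ids)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    tree.length = None
    return PhyloTree(tree)


def render_cluster_sets(
    truth: SyntheticTruth,
    n_samples_per_group: int = 6,
    reads_per_sample: int = 20_000,
    seed: int = 1,
) -> FixtureBundle:
    """Render the truth as three linked cluster sets over shared reads.

    All sets start from the same per-sample multinomial draw of the true
    taxa (the paper's sets derive from the same amplicons); each set then
    applies its designed distortions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    metadata = _make_metadata(n_samples_per_group)
    n_taxa = truth.n_taxa

    base_counts = np.empty((n_taxa, len(metadata.sample_ids)), dtype=np.int64)
    for j, sid in enumerate(metadata.sample_ids):
        w = truth.group_weights(metadata.organ[sid], metadata.pond[sid])
        # patchy occupancy: each taxon independently absent from this sample
        present = rng.random(n_taxa) >= truth.params.dropout_prob
        if not present.any():
            present[:] = True
        w = np.where(present, w, 0.0)
        w = w / w.sum()
        # sequencing depth varies between samples (CV ~ 0.15, floored at half
        # the nominal depth), as in real runs
        depth = max(reads_per_sample // 2, int(rng.normal(reads_per_sample, 0.15 * reads_per_sample)))
        base_counts[:, j] = rng.multinomial(depth, w)

    abundant = np.argsort(truth.base_abundances)[::-1][: truth.params.n_abundant_taxa]
    shared = set(truth.shared_taxa.tolist())
    sets: dict[str, ClusterSet] = {}
    trees: dict[str, PhyloTree] = {}

    for sid, design in truth.designs.items():
        prefix = sid.split("_", 1)[1].replace("_", "")
        fids = [f"{prefix}_{i + 1:04d}" for i in range(n_taxa)]
        counts = base_counts.copy()
        taken = set(truth.centroids)
        centroids = {}
        for i, fid in enumerate(fids):
            if design.variant_centroids and i not in shared:
                seq = _variant(truth.centroids[i], 1, taken, rng)
                taken.add(seq)
            else:
                seq = truth.centroids[i]
            centroids[fid] = seq
        taxonomy = {}
        for i, fid in enumerate(fids):
            t = truth.taxa[i]
            depth = 7
            if rng.random() < design.taxonomy_truncation_prob.get("genus", 0.0):
                depth = 5
            elif rng.random() < design.taxonomy_truncation_prob.get("species", 0.0):
                depth = 6
            taxonomy[fid] = TaxonomyString.canonicalize(list(t.ranks[:depth]))
        origin = {fid: ("reference" if "OTU" in sid else "unknown") for fid in fids}

        # satellites: low-frequency sequence-error clusters around abundant taxa
        sat_rows, sat_ids = [], []
        if design.satellite_count > 0:
            for i in abundant:
                for s in range(design.satellite_count):
                    err = int(rng.integers(1, design.satellite_error_nt + 1))
                    seq = _variant(centroids[fids[i]], err, taken, rng)
                    taken.add(seq)
                    sat_id = f"{prefix}_S{i + 1:04d}_{s + 1}"
                    siphon = rng.binomial(counts[i, :], design.satellite_read_fraction)
                    if siphon.sum() == 0:
                        log.warning(
                            "satellite %s of %s drew no reads at depth %d; dropped",
                            sat_id, sid, reads_per_sample,
                        )
                        continue
                    counts[i, :] -= siphon
                    sat_rows.append(siphon)
                    sat_ids.append(sat_id)
                    centroids[sat_id] = seq
                    taxonomy[sat_id] = truth.taxa[i]
                    origin[sat_id] = "de_novo"
        all_ids = fids + sat_ids
        matrix = np.vstack([counts] + [r[np.newaxis, :] for r in sat_rows]) if sat_rows else counts
        table = FeatureTable(all_ids, list(metadata.sample_ids), matrix)

        cset = ClusterSet(sid, table, centroids, taxonomy=taxonomy, origin=origin)
        if design.merge_identity is not None:
            cset = merge_near_identical(cset, design.merge_identity)
        sets[sid] = cset
        trees[sid] = _linkage_tree(
            list(cset.table.feature_ids), [cset.centroids[f] for f in cset.table.feature_ids]
        )

    return FixtureBundle(sets=sets, metadata=metadata, trees=trees, truth=truth)


def merge_near_identical(cset: ClusterSet, min_identity: float) -> ClusterSet:
    """Greedily merge features whose centroids are within the identity radius.

    Features are processed in decreasing read abundance (ties lexicographic
    by sequence); each joins the first surviving centroid at >= the given
    identity, pooling its counts; the survivor keeps its centroid, taxonomy
    and origin.
    """
    features = list(cset.table.feature_ids)
    seqs = [cset.centroids[f] for f in features]
    reads = cset.feature_reads()
    ident = identity_matrix(seqs)
    order = sorted(range(len(seqs)), key=lambda i: (-reads[features[i]], seqs[i]))
    assigned: dict[int, int] = {}
    survivors: list[int] = []
    for i in order:
        for c in survivors:
            if ident[i, c] >= min_identity:
                assigned[i] = c
                break
        else:
            survivors.append(i)
            assigned[i] = i
    keep = sorted(survivors)
    counts = np.zeros((len(keep), cset.table.n_samples), dtype=np.int64)
    pos = {c: k for k, c in enumerate(keep)}
    for i, c in assigned.items():
        counts[pos[c], :] += cset.table.counts[i, :]
    kept_ids = [features[c] for c in keep]
    return ClusterSet(
        cset.set_id,
        FeatureTable(kept_ids, list(cset.table.sample_ids), counts),
        {features[c]: seqs[c] for c in keep},
        taxonomy={features[c]: cset.taxonomy[features[c]] for c in keep if features[c] in cset.taxonomy},
        origin={features[c]: cset.origin[features[c]] for c in keep},
    )


def generate_bundle(
    n_taxa: int = 40,
    n_samples_per_group: int = 6,
    reads_per_sample: int = 20_000,
    seed: int = 0,
    params: TruthParams | None = None,
    designs: dict[str, SetDesign] | None = None,
) -> FixtureBundle:
    """Truth + rendering under one master seed (derived streams)."""
    ss = np.random.SeedSequence(seed)
    truth_seed, render_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    truth = generate_truth(n_taxa, truth_seed, params=params, designs=designs)
    return render_cluster_sets(truth, n_samples_per_group, reads_per_sample, seed=render_seed)
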