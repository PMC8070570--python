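"""Sequence-level concordance between cluster sets.

Compares the centroid (representative) sequences of 2-3 cluster sets:
exact-match overlap partitions with read weighting, nearest-neighbour
nucleotide-difference profiles, expected-identity arithmetic for V3-length
amplicons, and greedy-clustering resilience sweeps over an identity
threshold grid, optionally stratified by cluster origin (reference vs
de novo).

Pairwise comparison is a global end-to-end alignment under unit costs
(match 0, mismatch 1, indel 1): "changes" is the minimum number of
mismatches plus gap columns, and identity is matching columns over
alignment columns of one optimal alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .types import ClusterSet

log = logging.getLogger("concord16s")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def pairwise_changes(a: str, b: str) -> tuple[int, float]:
    """Unit-cost global alignment: (changes, identity).

    changes = mismatches + inserted/deleted columns (the edit distance);
    identity = matching columns / total alignment columns.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    changes = res["editDistance"]
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return changes, (columns - changes) / columns


def identity_matrix(sequences: list[str]) -> np.ndarray:
    """Symmetric pairwise identity matrix (diagonal 1)."""
    n = len(sequences)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, idv = pairwise_changes(sequences[i], sequences[j])
            ident[i, j] = ident[j, i] = idv
    return ident


def expected_identity(length: int, changes: int) -> float:
    """Identity of a length-``length`` amplicon after ``changes`` accumulated edits."""
    if changes > length:
        raise ValueError(f"changes ({changes}) exceed length ({length})")
    if length <= 0 or changes < 0:
        raise ValueError("length must be positive and changes non-negative")
    return (length - changes) / length


@dataclass
class OverlapPartition:
    """Disjoint, exhaustive compartments of the union of centroid sequences.

    Keys are frozensets of set ids (Venn compartments); reads in a
    compartment sum every member set's reads for its items, so compartment
    reads total the grand read count over all sets.
    """

    set_ids: list[str]
    n_sequences: dict[frozenset, int]
    n_reads: dict[frozenset, int]
    total_sequences: int
    total_reads: int
    items: dict[frozenset, list[str]] = field(default_factory=dict)

    def pct_sequences(self, compartment: frozenset) -> float:
        return 100.0 * self.n_sequences[compartment] / self.total_sequences

    def pct_reads(self, compartment: frozenset) -> float:
        return 100.0 * self.n_reads[compartment] / self.total_reads

    def compartment(self, *set_ids: str) -> frozenset:
        return frozenset(set_ids)


def _reads_by_centroid(cset: ClusterSet) -> dict[str, int]:
    """Reads per distinct centroid sequence (duplicates merged with a warning)."""
    reads: dict[str, int] = {}
    dup = False
    for fid, n in cset.feature_reads().items():
        seq = cset.centroids[fid]
        if seq in reads:
            dup = True
        reads[seq] = reads.get(seq, 0) + n
    if dup:
        log.warning("set %s has duplicate centroid sequences; reads merged", cset.set_id)
    return reads


def exact_overlap(sets: list[ClusterSet], items: str = "sequence") -> OverlapPartition:
    """Venn partition of the sets' centroid sequences, weighted by reads.

    With ``items='sequence'`` membership is exact string equality of
    centroids; with ``items='feature_id'`` it is identity of feature ids
    (used for collapsed-taxon tables, where ids are lineage keys).
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("exact_overlap compares 2 or 3 sets")
    per_set: dict[str, dict[str, int]] = {}
    for cs in sets:
        if items == "sequence":
            per_set[cs.set_id] = _reads_by_centroid(cs)
        elif items == "feature_id":
            per_set[cs.set_id] = cs.feature_reads()
        else:
            raise ValueError(f"unknown items mode {items!r}")
    universe = set().union(*(d.keys() for d in per_set.values()))
    n_sequences: dict[frozenset, int] = {}
    n_reads: dict[frozenset, int] = {}
    members: dict[frozenset, list[str]] = {}
    for item in sorted(universe):
        comp = frozenset(sid for sid, d in per_set.items() if item in d)
        n_sequences[comp] = n_sequences.get(comp, 0) + 1
        n_reads[comp] = n_reads.get(comp, 0) + sum(per_set[sid][item] for sid in comp)
        members.setdefault(comp, []).append(item)
    return OverlapPartition(
        set_ids=[cs.set_id for cs in sets],
        n_sequences=n_sequences,
        n_reads=n_reads,
        total_sequences=len(universe),
        total_reads=sum(sum(d.values()) for d in per_set.values()),
        items=members,
    )


@dataclass
class OriginBreakdown:
    set_id: str
    n_sequences: dict[str, int]
    n_reads: dict[str, int]

    def pct_reads(self, origin: str) -> float:
        total = sum(self.n_reads.values())
        return 100.0 * self.n_reads.get(origin, 0) / total if total else 0.0


def origin_breakdown(cset: ClusterSet) -> OriginBreakdown:
    """Partition a set's sequences and reads by cluster origin."""
    n_seq: dict[str, int] = {}
    n_reads: dict[str, int] = {}
    for fid, reads in cset.feature_reads().items():
        o = cset.origin.get(fid, "unknown")
        n_seq[o] = n_seq.get(o, 0) + 1
        n_reads[o] = n_reads.get(o, 0) + reads
    return OriginBreakdown(cset.set_id, n_seq, n_reads)


@dataclass
class DifferenceProfile:
    """Cumulative nearest-neighbour change-count profile for one stratum."""

    set_id: str
    stratum: str
    n_centroids: int
    nearest_changes: dict[str, int]  # feature -> nearest qualifying neighbour distance
    max_changes: int
    flagged_empty: bool = False

    def cum_fraction(self, n: int) -> float:
        """Fraction of stratum centroids whose nearest neighbour is <= n changes."""
        if self.n_centroids == 0:
            return 0.0
        return sum(1 for d in self.nearest_changes.values() if d <= n) / self.n_centroids

    def curve(self) -> list[tuple[int, float]]:
        return [(n, self.cum_fraction(n)) for n in range(1, self.max_changes + 1)]


def _stratum_features(cset: ClusterSet, stratum: str) -> list[str]:
    if stratum == "all":
        return list(cset.table.feature_ids)
    return [f for f in cset.table.feature_ids if cset.origin.get(f, "unknown") == stratum]


def difference_profile(
    cset: ClusterSet,
    max_changes: int = 20,
    min_identity: float = 0.75,
    stratum: str = "all",
) -> DifferenceProfile:
    """Nearest-neighbour difference counts among a stratum's centroids.

    For each centroid, the change count to its nearest other centroid in the
    stratum whose pairwise identity is >= ``min_identity`` (the eligibility
    gate keeping comparisons within roughly related phyla); centroids with no
    qualifying neighbour never enter any cumulative bin.
    """
    features = _stratum_features(cset, stratum)
    if len(features) < 2:
        log.warning("stratum %r of %s has <2 sequences; empty profile", stratum, cset.set_id)
        return DifferenceProfile(cset.set_id, stratum, len(features), {}, max_changes, flagged_empty=True)
    seqs = [cset.centroids[f] for f in features]
    nearest: dict[str, int] = {}
    for i, fi in enumerate(features):
        best = None
        for j, _ in enumerate(features):
            if i == j:
                continue
            changes, ident = pairwise_changes(seqs[i], seqs[j])
            if ident >= min_identity and (best is None or changes < best):
                best = changes
        if best is not None:
            nearest[fi] = best
    return DifferenceProfile(cset.set_id, stratum, len(features), nearest, max_changes)


@dataclass
class ResilienceCurve:
    """Surviving-centroid fractions of a greedy clustering threshold sweep."""

    set_id: str
    thresholds: list[float]
    remaining_fraction: list[float]
    n_input: int


def greedy_cluster(
    sequences: list[str], abundances: list[int], threshold: float
) -> list[int]:
    """Greedy centroid clustering at one identity threshold.

    Sequences are processed in decreasing abundance (ties broken
    lexicographically by sequence); each joins the first existing centroid
    with identity >= threshold, else founds a new one. Returns the indices
    (into the input list) of the surviving centroids.
    """
    order = sorted(range(len(sequences)), key=lambda i: (-abundances[i], sequences[i]))
    centroids: list[int] = []
    for i in order:
        for c in centroids:
            _, ident = pairwise_changes(sequences[i], sequences[c])
            if ident >= threshold:
                break
        else:
            centroids.append(i)
    return centroids


def resilience_curve(cset: ClusterSet, thresholds: list[float]) -> ResilienceCurve:
    """Fraction of centroids surviving greedy clustering at each threshold.

    Each threshold is clustered independently (no nesting across the sweep).
    Pairwise identities are computed once and reused across thresholds.
    """
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    features = list(cset.table.feature_ids)
    seqs = [cset.centroids[f] for f in features]
    reads = cset.feature_reads()
    abund = [reads[f] for f in features]
    ident = identity_matrix(seqs)
    order = sorted(range(len(seqs)), key=lambda i: (-abund[i], seqs[i]))
    remaining = []
    for t in thresholds:
        centroids: list[int] = []
        for i in order:
            for c in centroids:
                if ident[i, c] >= t:
                    break
            else:
                centroids.append(i)
        remaining.append(len(centroids) / len(seqs))
    return ResilienceCurve(cset.set_id, list(thresholds), remaining, len(seqs))


def threshold_grid(start: float = 1.0, stop: float = 0.75, step: float = 0.005) -> list[float]:
    """Decreasing identity grid from ``start`` down to ``stop`` inclusive."""
    n = int(round((start - stop) / step))
    grid = [round(start - k * step, 10) for k in range(n + 1)]
    return [g for g in grid if g >= stop - 1e-12]
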