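"""Domain types shared by every analysis stage.

The unit of data is a feature table (OTU/ASV/taxon counts per sample); a
*cluster set* bundles one clustering method's table with its centroid
sequences, taxonomy assignments and cluster origins. Three such sets --
conventionally ``01_OTU_97``, ``02_OTU_99`` and ``03_ASV`` -- are compared
throughout the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("concord16s")

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
N_RANKS = 7

VALID_ORIGINS = ("reference", "de_novo", "unknown")
DNA_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an external artifact violates a structural invariant."""


@dataclass(frozen=True)
class TaxonomyString:
    """An ordered seven-rank lineage (kingdom ... species).

    Labels may be empty; canonical form requires that once a rank is empty
    every deeper rank is empty too (an ambiguous node truncates the lineage).
    """

    ranks: tuple[str, ...]

    def __post_init__(self):
        if len(self.ranks) != N_RANKS:
            raise FormatError(f"taxonomy must have exactly {N_RANKS} ranks, got {len(self.ranks)}")
        seen_empty = False
        for label in self.ranks:
            if seen_empty and label:
                raise FormatError(
                    "non-canonical taxonomy: label below an empty rank "
                    f"in {self.ranks!r}; use TaxonomyString.canonicalize"
                )
            if not label:
                seen_empty = True

    @classmethod
    def canonicalize(cls, labels: list[str] | tuple[str, ...]) -> "TaxonomyString":
        """Pad to 7 ranks and truncate every label below the first empty one."""
        labels = list(labels) + [""] * (N_RANKS - len(labels))
        if len(labels) > N_RANKS:
            raise FormatError(f"more than {N_RANKS} ranks: {labels!r}")
        out, truncating = [], False
        for label in labels:
            if truncating or not label:
                if label:
                    log.warning("dropping label %r below an empty rank in %r", label, labels)
                out.append("")
                truncating = truncating or not label
            else:
                out.append(label)
        return cls(tuple(out))

    @property
    def depth(self) -> int:
        """Number of leading non-empty ranks (0-7)."""
        for i, label in enumerate(self.ranks):
            if not label:
                return i
        return N_RANKS

    def prefix(self, level: int) -> tuple[str, ...]:
        """Lineage prefix through ``level`` (1-based rank index)."""
        if not 1 <= level <= N_RANKS:
            raise ValueError(f"level must be in 1..{N_RANKS}, got {level}")
        return self.ranks[:level]

    def is_informative(self, level: int) -> bool:
        """True iff the label AT ``level`` is a non-empty, unambiguous tag."""
        return bool(self.prefix(level)[-1])


@dataclass
class FeatureTable:
    """Features x samples integer count matrix with identifiers."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples), integer dtype

    allow_empty: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("non-integer count in feature table")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise FormatError(f"duplicate feature id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise FormatError("negative count in feature table")
        if not self.allow_empty:
            if len(self.feature_ids) == 0 or len(self.sample_ids) == 0:
                raise FormatError("empty feature table")
            if (self.sample_totals() == 0).any():
                empty = [s for s, t in zip(self.sample_ids, self.sample_totals()) if t == 0]
                log.warning("samples with zero total reads: %s", empty)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.sum())

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def select_features(self, keep: list[str] | np.ndarray, allow_empty: bool = False) -> "FeatureTable":
        """New table restricted to ``keep`` (ids or boolean mask), order preserved."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in keep], dtype=int)
        return FeatureTable(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :] if len(idx) else np.zeros((0, self.n_samples), dtype=np.int64),
            allow_empty=allow_empty or len(idx) == 0,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids), list(self.sample_ids), self.counts.copy(),
            allow_empty=self.allow_empty,
        )


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase, RNA->DNA; any residue outside ACGT is rejected."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise FormatError(f"empty {context}")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise FormatError(f"ambiguous base {sorted(bad)!r} in {context}")
    return s


@dataclass
class ClusterSet:
    """One clustering method's output: table + centroids + taxonomy + origins."""

    set_id: str
    table: FeatureTable
    centroids: dict[str, str]
    taxonomy: dict[str, TaxonomyString] = field(default_factory=dict)
    origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for fid in self.table.feature_ids:
            if fid not in self.centroids:
                raise FormatError(f"feature {fid!r} in table of {self.set_id} has no centroid")
        self.centroids = {
            f: normalize_sequence(s, context=f"centroid {f!r}") for f, s in self.centroids.items()
        }
        for fid in self.table.feature_ids:
            o = self.origin.setdefault(fid, "unknown")
            if o not in VALID_ORIGINS:
                raise FormatError(f"invalid origin {o!r} for feature {fid!r}")

    def feature_reads(self) -> dict[str, int]:
        """Total reads per feature (summed over samples)."""
        totals = self.table.feature_totals()
        return {f: int(t) for f, t in zip(self.table.feature_ids, totals)}

    def total_reads(self) -> int:
        return self.table.total_reads()


@dataclass
class SampleMetadata:
    """Per-sample grouping factors: organ, pond and their cross product."""

    sample_ids: list[str]
    organ: dict[str, str]
    pond: dict[str, str]

    def __post_init__(self):
        for sid in self.sample_ids:
            if sid not in self.organ or sid not in self.pond:
                raise FormatError(f"sample {sid!r} missing organ/pond metadata")
            if not self.organ[sid] or not self.pond[sid]:
                raise FormatError(f"empty organ/pond category for sample {sid!r}")

    def organ_pond(self, sample_id: str) -> str:
        return f"{self.organ[sample_id]}{self.pond[sample_id]}"

    def groups(self, grouping: str, sample_ids: list[str]) -> list[str]:
        """Group label per sample for grouping in {organ, pond, organ_pond}."""
        missing = [s for s in sample_ids if s not in self.organ]
        if missing:
            raise FormatError(f"samples without metadata: {missing}")
        if grouping == "organ":
            return [self.organ[s] for s in sample_ids]
        if grouping == "pond":
            return [self.pond[s] for s in sample_ids]
        if grouping == "organ_pond":
            return [self.organ_pond(s) for s in sample_ids]
        raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class PhyloTree:
    """A rooted tree over feature ids with finite non-negative branch lengths.

    Wraps a ``skbio.TreeNode``; the root's own length may be absent, every
    other branch must carry an explicit finite length >= 0 (a missing length
    is an error, never a silent zero).
    """

    tree: "object"  # skbio.TreeNode

    def __post_init__(self):
        leaves = [t.name for t in self.tree.tips()]
        if len(set(leaves)) != len(leaves):
            raise FormatError(f"duplicate leaf label: {_first_duplicate(leaves)!r}")
        for node in self.tree.traverse(include_self=False):
            if node.length is None or not math.isfinite(node.length):
                raise FormatError(f"branch without a finite length at node {node.name!r}")
            if node.length < 0:
                raise FormatError(f"negative branch length at node {node.name!r}")

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.traverse(include_self=False)))

    def sheared(self, names: list[str]) -> "PhyloTree":
        """Subtree spanning ``names``; branch lengths of retained edges are kept."""
        sub = self.tree.shear(names)
        # shear can leave the new root with a residual length; discard it so the
        # result is a clean rooted tree over the requested leaves.
        sub.length = None
        return PhyloTree(sub)
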