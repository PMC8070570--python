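"""Feature filters and taxonomic collapsing.

Two filters are applied, in this order, to every cluster set before any
cross-set comparison:

1. sample-singleton removal -- a feature seen with a single read within a
   sample is treated as noise in that sample (cell zeroed); features left
   with no reads anywhere are dropped;
2. the tailored abundance filter -- a feature is kept only if it reaches at
   least ``threshold`` (default 0.1%) of the total reads in *some* sample,
   with per-sample totals taken from the input table in a single pass.

Threshold comparisons use exact rational arithmetic (``count * denom >=
num * sample_total``) so boundary cases like exactly 0.1% are inclusive and
float-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .types import FeatureTable, TaxonomyString

#: Default minimum per-sample relative abundance (0.1%).
DEFAULT_MIN_FRAC = Fraction(1, 1000)


@dataclass
class FilterReport:
    """Read/feature bookkeeping for one filter application."""

    reads_before: int
    reads_after: int
    features_before: int
    features_after: int
    removed_feature_ids: list[str] = field(default_factory=list)
    emptied: bool = False

    @property
    def reads_lost(self) -> int:
        return self.reads_before - self.reads_after

    @property
    def percent_reads_lost(self) -> float:
        if self.reads_before == 0:
            return 0.0
        return 100.0 * self.reads_lost / self.reads_before

    def to_dict(self) -> dict:
        return {
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "features_before": self.features_before,
            "features_after": self.features_after,
            "removed_feature_ids": list(self.removed_feature_ids),
            "percent_reads_lost": self.percent_reads_lost,
            "emptied": self.emptied,
        }


def remove_sample_singletons(
    table: FeatureTable, mode: str = "per_cell"
) -> tuple[FeatureTable, FilterReport]:
    """Remove sample-singletons.

    ``per_cell`` (default): every cell equal to 1 is zeroed, then all-zero
    features are dropped. ``whole_table``: features whose total read count
    over all samples is 1 are dropped outright.
    """
    counts = table.counts.copy()
    if mode == "per_cell":
        counts[counts == 1] = 0
    elif mode == "whole_table":
        counts[counts.sum(axis=1) == 1, :] = 0
    else:
        raise ValueError(f"unknown singleton mode {mode!r}")
    keep = counts.sum(axis=1) > 0
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    out = FeatureTable(
        kept_ids,
        list(table.sample_ids),
        counts[keep, :] if keep.any() else np.zeros((0, table.n_samples), dtype=np.int64),
        allow_empty=True,
    )
    report = FilterReport(
        reads_before=table.total_reads(),
        reads_after=out.total_reads(),
        features_before=table.n_features,
        features_after=out.n_features,
        removed_feature_ids=removed,
        emptied=out.n_features == 0,
    )
    return out, report


def abundance_filter(
    table: FeatureTable, threshold: float | Fraction = DEFAULT_MIN_FRAC
) -> tuple[FeatureTable, FilterReport]:
    """Keep features reaching >= ``threshold`` of some sample's total reads.

    Per-sample totals are those of the input table (single pass); kept
    features retain every count. A zero-total sample contributes no
    qualifying ratio.
    """
    thr = threshold if isinstance(threshold, Fraction) else Fraction(str(threshold))
    if not 0 < thr < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    totals = table.sample_totals()
    # count/total >= num/den  <=>  count*den >= num*total; vacuous for total==0
    qualifies = (table.counts * thr.denominator) >= (thr.numerator * totals[np.newaxis, :])
    qualifies &= totals[np.newaxis, :] > 0
    keep = qualifies.any(axis=1)
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    out = table.select_features(keep, allow_empty=True)
    report = FilterReport(
        reads_before=table.total_reads(),
        reads_after=out.total_reads(),
        features_before=table.n_features,
        features_after=out.n_features,
        removed_feature_ids=removed,
        emptied=out.n_features == 0,
    )
    return out, report


def standard_filter_pipeline(
    table: FeatureTable,
    threshold: float | Fraction = DEFAULT_MIN_FRAC,
    singleton_mode: str = "per_cell",
) -> tuple[FeatureTable, dict[str, FilterReport]]:
    """Fixed filter order: sample-singletons first, abundance filter once after."""
    t1, rep_singletons = remove_sample_singletons(table, mode=singleton_mode)
    t2, rep_abund = abundance_filter(t1, threshold=threshold)
    return t2, {"singletons": rep_singletons, "abundance": rep_abund}


def lineage_key(t: TaxonomyString, level: int) -> str:
    """Collapse key: lineage prefix through ``level`` joined with '|'.

    Empty labels are kept in place, so lineages truncated at different
    depths form distinct keys ('unassigned at level' rows stay separate).
    """
    return "|".join(t.prefix(level))


def collapse_taxonomy(
    table: FeatureTable, taxonomy: dict[str, TaxonomyString], level: int
) -> FeatureTable:
    """Sum features sharing an identical lineage prefix through ``level``.

    Output rows are keyed by the prefix (first-appearance order); total
    reads are conserved exactly.
    """
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features without taxonomy: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    keys: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for i, fid in enumerate(table.feature_ids):
        key = lineage_key(taxonomy[fid], level)
        if key not in rows:
            keys.append(key)
            rows[key] = table.counts[i, :].copy()
        else:
            rows[key] += table.counts[i, :]
    return FeatureTable(keys, list(table.sample_ids), np.array([rows[k] for k in keys]))
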