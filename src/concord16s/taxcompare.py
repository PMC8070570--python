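"""Taxonomy-resolution and taxonomic-composition concordance across sets.

A taxon tag is *informative* at a rank when its label at that rank is
non-empty after canonicalization (an empty terminal node marks an ambiguous
assignment -- typically an LCA truncation by the classifier, or a reference
lineage with no label at that depth). The analyses here quantify, per
cluster set: how many reads carry informative tags at each rank, why
species labels are missing (LCA vs unlabeled reference), which taxa are
shared between sets, how well shared taxa correlate in abundance
(Spearman), and which taxa are differentially represented between a
reference set and the others (the <33% ratio screen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .filtering import collapse_taxonomy
from .seqcompare import OverlapPartition, exact_overlap
from .types import N_RANKS, RANK_NAMES, ClusterSet, FeatureTable, TaxonomyString

log = logging.getLogger("concord16s")


def is_informative(t: TaxonomyString, level: int) -> bool:
    """True iff the lineage carries a non-empty tag at ``level`` (1..7)."""
    return t.is_informative(level)


@dataclass
class ResolutionProfile:
    """Per-rank informative-tag resolution of one cluster set."""

    set_id: str
    n_informative_taxa: dict[int, int]  # level -> distinct informative lineage prefixes
    pct_reads_informative: dict[int, float]  # level -> % of reads
    total_reads: int
    flagged_empty: bool = False


def resolution_profile(cset: ClusterSet) -> ResolutionProfile:
    """Reads carrying informative tags at each rank, plus distinct-taxa counts."""
    total = cset.total_reads()
    reads = cset.feature_reads()
    n_taxa: dict[int, int] = {}
    pct: dict[int, float] = {}
    any_taxonomy = any(t.depth > 0 for t in cset.taxonomy.values())
    for level in range(1, N_RANKS + 1):
        informative_reads = 0
        taxa = set()
        for fid in cset.table.feature_ids:
            t = cset.taxonomy[fid]
            if t.is_informative(level):
                informative_reads += reads[fid]
                taxa.add(t.prefix(level))
        n_taxa[level] = len(taxa)
        pct[level] = 100.0 * informative_reads / total if total else 0.0
    if not any_taxonomy:
        log.warning("set %s has no taxonomy labels at all", cset.set_id)
    return ResolutionProfile(cset.set_id, n_taxa, pct, total, flagged_empty=not any_taxonomy)


@dataclass
class LcaAttribution:
    """Why species labels are missing: classifier LCA truncation vs
    reference lineages that simply carry no species label. Read-weighted;
    the two fractions sum to 1 over reads lacking a species tag."""

    set_id: str
    pct_missing_due_to_lca: float
    pct_missing_due_to_no_label: float
    reads_missing_species: int


def lca_attribution(
    cset: ClusterSet, reference_labels: dict[tuple[str, ...], bool]
) -> LcaAttribution:
    """Attribute species-missing reads to LCA truncation or unlabeled references.

    ``reference_labels`` maps a terminal (non-empty) lineage prefix to
    whether the reference taxonomy carries a species label under it. A
    feature whose terminal lineage is absent from the reference is counted
    as LCA (conservative) with a warning.
    """
    reads = cset.feature_reads()
    lca_reads = 0
    nolabel_reads = 0
    for fid in cset.table.feature_ids:
        t = cset.taxonomy[fid]
        if t.is_informative(N_RANKS):
            continue  # species assigned
        terminal = t.ranks[: t.depth]
        if terminal not in reference_labels:
            log.warning("lineage %r absent from reference; attributed to LCA", terminal)
            lca_reads += reads[fid]
        elif reference_labels[terminal]:
            lca_reads += reads[fid]
        else:
            nolabel_reads += reads[fid]
    missing = lca_reads + nolabel_reads
    if missing == 0:
        return LcaAttribution(cset.set_id, 0.0, 0.0, 0)
    return LcaAttribution(
        cset.set_id,
        100.0 * lca_reads / missing,
        100.0 * nolabel_reads / missing,
        missing,
    )


def collapse_set(cset: ClusterSet, level: int) -> FeatureTable:
    """The set's table collapsed to lineage-prefix rows at ``level``."""
    return collapse_taxonomy(cset.table, cset.taxonomy, level)


def taxa_overlap(sets: list[ClusterSet], level: int) -> OverlapPartition:
    """Venn partition of the sets' taxa (lineage prefixes) at one rank."""
    collapsed = []
    for cs in sets:
        table = collapse_set(cs, level)
        collapsed.append(
            ClusterSet(
                cs.set_id,
                table,
                # lineage keys act as both feature ids and 'sequences' here
                {k: "A" for k in table.feature_ids},
            )
        )
    return exact_overlap(collapsed, items="feature_id")


@dataclass
class CorrelationResult:
    level: int
    set_pair: tuple[str, str]
    rho: float
    n_taxa: int
    flagged: str = ""

    @property
    def level_name(self) -> str:
        return RANK_NAMES[self.level - 1]


def _informative_abundances(cset: ClusterSet, level: int) -> dict[str, float]:
    """Relative abundance (vs the set's total reads) per informative lineage key."""
    collapsed = collapse_set(cset, level)
    total = collapsed.total_reads()
    out: dict[str, float] = {}
    for key, row_total in zip(collapsed.feature_ids, collapsed.feature_totals()):
        if key.split("|")[-1]:  # terminal label at this level non-empty
            out[key] = row_total / total if total else 0.0
    return out


def cross_set_correlation(a: ClusterSet, b: ClusterSet, level: int) -> CorrelationResult:
    """Spearman's rho between two sets' informative-taxa abundance profiles.

    Profiles are set-wide relative abundances over the union of the two
    sets' informative taxa at the rank (absent taxon -> 0); ties receive
    average ranks.
    """
    abund_a = _informative_abundances(a, level)
    abund_b = _informative_abundances(b, level)
    union = sorted(set(abund_a) | set(abund_b))
    if len(union) < 3:
        log.warning("fewer than 3 informative taxa at level %d for (%s, %s)", level, a.set_id, b.set_id)
        return CorrelationResult(level, (a.set_id, b.set_id), float("nan"), len(union), flagged="undefined")
    x = np.array([abund_a.get(k, 0.0) for k in union])
    y = np.array([abund_b.get(k, 0.0) for k in union])
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(level, (a.set_id, b.set_id), rho, len(union))


@dataclass
class DifferentialTaxon:
    key: str
    ref_abundance: float
    other_abundances: dict[str, float]
    flag: str = ""


@dataclass
class DifferentialTaxaResult:
    level: int
    reference_set: str
    ratio: float
    reference_predominant: list[DifferentialTaxon] = field(default_factory=list)
    shared_or_other_predominant: list[DifferentialTaxon] = field(default_factory=list)


def differential_taxa(
    reference_set: ClusterSet,
    other_sets: list[ClusterSet],
    level: int,
    ratio: float = 1.0 / 3.0,
) -> DifferentialTaxaResult:
    """Screen taxa whose abundance in the other sets falls below ``ratio``
    of the reference set's abundance (reference-predominant taxa) vs the
    complement. Abundances are set-wide relative abundances at ``level``;
    with several other sets their mean is compared.
    """
    ref = _informative_abundances(reference_set, level)
    others = {cs.set_id: _informative_abundances(cs, level) for cs in other_sets}
    universe = sorted(set(ref) | set().union(*others.values()))
    result = DifferentialTaxaResult(level, reference_set.set_id, ratio)
    for key in universe:
        ref_a = ref.get(key, 0.0)
        per_set = {sid: abund.get(key, 0.0) for sid, abund in others.items()}
        mean_other = float(np.mean(list(per_set.values())))
        entry = DifferentialTaxon(key, ref_a, per_set)
        if ref_a == 0.0:
            entry.flag = "ref-absent"
            result.shared_or_other_predominant.append(entry)
        elif mean_other < ratio * ref_a:
            result.reference_predominant.append(entry)
        else:
            result.shared_or_other_predominant.append(entry)
    return result
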