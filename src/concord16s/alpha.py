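"""Rarefaction-based within-sample (alpha) diversity.

Each sample is repeatedly rarefied (subsampled without replacement, i.e. a
multivariate-hypergeometric draw) to a common depth -- by convention the
smallest sample's total -- and three estimators are computed per draw:

* observed features: count of features with at least one read;
* Shannon entropy, in nats: H = -sum p_i ln p_i;
* bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)), with F1/F2
  the singleton/doubleton feature counts of the rarefied vector.

Point estimates are means over iterations. Groups (organ, pond,
organ x pond) are compared nonparametrically: Wilcoxon-Mann-Whitney for
two-level factors (exact p for small groups) and Kruskal-Wallis for the
four organ-pond groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import FeatureTable, SampleMetadata

log = logging.getLogger("concord16s")

METRICS = ("observed", "shannon", "chao1")
EXACT_RANKSUM_MAX_N = 10


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Subsample one sample's feature counts to ``depth`` reads without replacement.

    With ``size`` given, returns ``size`` independent draws (rows).
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if size is None:
        return rng.multivariate_hypergeometric(counts, depth)
    return rng.multivariate_hypergeometric(counts, depth, size=size)


def observed_features(counts: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(counts)
    return (counts > 0).sum(axis=1)


def shannon(counts: np.ndarray) -> np.ndarray | float:
    """Shannon entropy in nats; 0*ln 0 := 0. Scalar in, scalar out."""
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero count vector has no entropy")
    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    return h if np.asarray(counts).ndim == 2 else float(h[0])


def chao1(counts: np.ndarray) -> np.ndarray | float:
    """Bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1))."""
    arr = np.atleast_2d(counts)
    s_obs = (arr > 0).sum(axis=1)
    f1 = (arr == 1).sum(axis=1)
    f2 = (arr == 2).sum(axis=1)
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return est if np.asarray(counts).ndim == 2 else float(est[0])


@dataclass
class AlphaEstimates:
    """Per-sample, per-iteration alpha metrics with Chao1 audit counts."""

    sample_id: str
    depth: int
    values: dict[str, np.ndarray]  # metric -> (iterations,)
    f1: np.ndarray
    f2: np.ndarray

    def point_estimate(self, metric: str) -> float:
        return float(self.values[metric].mean())


@dataclass
class GroupComparison:
    grouping: str
    metric: str
    statistic: float
    p_value: float
    test: str
    group_medians: dict[str, float]
    significant_at_05: bool = field(init=False)

    def __post_init__(self):
        self.significant_at_05 = bool(self.p_value < 0.05)


def sample_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic independent streams, one per sample, from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def rarefied_alpha(
    table: FeatureTable, depth: int, iterations: int, seed: int
) -> list[AlphaEstimates]:
    """Alpha estimators per sample over ``iterations`` rarefied draws."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rngs = sample_seeds(seed, table.n_samples)
    out = []
    for j, sid in enumerate(table.sample_ids):
        try:
            draws = rarefy(table.counts[:, j], depth, rngs[j], size=iterations)
        except ValueError as err:
            raise ValueError(f"sample {sid!r}: {err}") from None
        out.append(
            AlphaEstimates(
                sample_id=sid,
                depth=depth,
                values={
                    "observed": observed_features(draws).astype(float),
                    "shannon": shannon(draws),
                    "chao1": chao1(draws).astype(float),
                },
                f1=(draws == 1).sum(axis=1),
                f2=(draws == 2).sum(axis=1),
            )
        )
    return out


def _two_group_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    method = "exact" if max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), f"mann-whitney ({method})"


def compare_groups(
    estimates: list[AlphaEstimates], metadata: SampleMetadata, grouping: str
) -> list[GroupComparison]:
    """Nonparametric comparison of per-sample point estimates for one grouping."""
    sample_ids = [e.sample_id for e in estimates]
    labels = metadata.groups(grouping, sample_ids)
    out = []
    for metric in METRICS:
        values = np.array([e.point_estimate(metric) for e in estimates])
        by_group: dict[str, np.ndarray] = {}
        for lab in sorted(set(labels)):
            by_group[lab] = values[np.array([l == lab for l in labels])]
        small = [g for g, v in by_group.items() if len(v) < 2]
        if len(by_group) < 2:
            log.info("grouping %s skipped for %s: only one group present", grouping, metric)
            continue
        if small:
            log.warning("grouping %s skipped for %s: groups too small (%s)", grouping, metric, small)
            continue
        medians = {g: float(np.median(v)) for g, v in by_group.items()}
        groups = list(by_group.values())
        if np.ptp(values) == 0:
            # every sample identical: no discrimination possible, p := 1
            out.append(GroupComparison(grouping, metric, 0.0, 1.0, "degenerate (all tied)", medians))
            continue
        if len(groups) == 2:
            stat, p, test = _two_group_test(groups[0], groups[1])
        else:
            res = stats.kruskal(*groups)
            stat, p, test = float(res.statistic), float(res.pvalue), "kruskal-wallis"
        out.append(GroupComparison(grouping, metric, stat, p, test, medians))
    return out


def alpha_pipeline(
    table: FeatureTable,
    metadata: SampleMetadata,
    iterations: int = 10_000,
    seed: int = 0,
    depth: int | None = None,
) -> tuple[list[AlphaEstimates], list[GroupComparison]]:
    """Full alpha stage: rarefy to the smallest sample, estimate, compare groups."""
    if depth is None:
        depth = int(table.sample_totals().min())
    estimates = rarefied_alpha(table, depth, iterations, seed)
    comparisons = []
    for grouping in ("organ", "pond", "organ_pond"):
        comparisons.extend(compare_groups(estimates, metadata, grouping))
    return estimates, comparisons
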