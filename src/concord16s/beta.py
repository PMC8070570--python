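"""Between-sample (beta) diversity: standardized tables, distance matrices,
PCoA ordination and ANOSIM group testing.

Tables are standardized by *average rarefaction*: the elementwise mean of
many independent rarefied draws at a common depth, kept real-valued.
Distances offered are Jaccard (presence/absence), Bray-Curtis (abundance)
and unweighted / weighted (raw or normalized) UniFrac over a rooted feature
phylogeny. Ordination is classical PCoA (Gower double-centering +
eigendecomposition; negative eigenvalues are reported, not corrected).
Group structure is tested with Clarke's ANOSIM on distance ranks --
R = (mean between-group rank - mean within-group rank) / (n(n-1)/4) -- with
a permutation p-value (exhaustive enumeration whenever the grouping admits
few enough distinct label assignments) and Benjamini-Hochberg-adjusted
pairwise post hoc tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

from .alpha import rarefy, sample_seeds
from .types import FeatureTable, PhyloTree, SampleMetadata

log = logging.getLogger("concord16s")

EXHAUSTIVE_LIMIT = 20_000


def average_rarefied_table(
    table: FeatureTable, depth: int, n_draws: int = 100, seed: int = 0
) -> tuple[np.ndarray, list[str], list[str]]:
    """Elementwise mean of ``n_draws`` independent rarefactions per sample.

    Returns (matrix features x samples, feature_ids, sample_ids); each
    column sums to ``depth`` exactly (means are kept as reals).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rngs = sample_seeds(seed, table.n_samples)
    out = np.empty((table.n_features, table.n_samples))
    for j in range(table.n_samples):
        draws = rarefy(table.counts[:, j], depth, rngs[j], size=n_draws)
        out[:, j] = draws.mean(axis=0)
    return out, list(table.feature_ids), list(table.sample_ids)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def jaccard_binary(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard dissimilarity on presence/absence (> 0)."""
    px, py = np.asarray(x) > 0, np.asarray(y) > 0
    union = (px | py).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two all-zero vectors")
    return float(1.0 - (px & py).sum() / union)


def _branch_table(tree: PhyloTree, feature_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch x feature descendant-membership matrix).

    One row per non-root branch of the tree sheared to ``feature_ids``.
    """
    missing = [f for f in feature_ids if f not in set(tree.leaf_names())]
    if missing:
        raise KeyError(f"features missing from tree: {missing}")
    sub = tree.sheared(feature_ids)
    idx = {f: i for i, f in enumerate(feature_ids)}
    lengths, membership = [], []
    for node in sub.tree.traverse(include_self=False):
        row = np.zeros(len(feature_ids), dtype=bool)
        for tip in node.tips(include_self=True):
            row[idx[tip.name]] = True
        lengths.append(node.length)
        membership.append(row)
    return np.array(lengths), np.array(membership)


def unifrac(
    tree: PhyloTree,
    x: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    mode: str = "unweighted",
) -> float:
    """UniFrac distance between two samples over a shared feature phylogeny.

    unweighted: unique branch length / total observed branch length;
    weighted_raw: sum_b l_b |p_b(x) - p_b(y)| with p_b a sample's read
    fraction descending from branch b; weighted_normalized divides by
    sum_b l_b (p_b(x) + p_b(y)).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    observed = [f for f, xv, yv in zip(feature_ids, x, y) if xv > 0 or yv > 0]
    if not observed:
        raise ValueError("UniFrac undefined: both samples empty")
    keep = np.array([(xv > 0 or yv > 0) for xv, yv in zip(x, y)])
    lengths, member = _branch_table(tree, observed)
    xs, ys = x[keep], y[keep]
    in_x = member @ (xs > 0)
    in_y = member @ (ys > 0)
    if mode == "unweighted":
        either = (in_x > 0) | (in_y > 0)
        unique = (in_x > 0) ^ (in_y > 0)
        denom = lengths[either].sum()
        return float(lengths[unique].sum() / denom) if denom else 0.0
    px = member @ (xs / xs.sum()) if xs.sum() else np.zeros(len(lengths))
    py = member @ (ys / ys.sum()) if ys.sum() else np.zeros(len(lengths))
    raw = float((lengths * np.abs(px - py)).sum())
    if mode == "weighted_raw":
        return raw
    if mode == "weighted_normalized":
        denom = float((lengths * (px + py)).sum())
        return raw / denom if denom else 0.0
    raise ValueError(f"unknown UniFrac mode {mode!r}")


METRIC_CHOICES = ("jaccard", "braycurtis", "unweighted_unifrac", "weighted_unifrac")


def distance_matrix(
    matrix: np.ndarray,
    sample_ids: list[str],
    metric: str,
    feature_ids: list[str] | None = None,
    tree: PhyloTree | None = None,
    weighted_mode: str = "weighted_normalized",
) -> DistanceMatrix:
    """Pairwise sample distances for a features x samples abundance matrix."""
    n = matrix.shape[1]
    dm = np.zeros((n, n))
    if metric in ("unweighted_unifrac", "weighted_unifrac") and tree is None:
        raise ValueError(f"{metric} requires a tree")
    for i in range(n):
        for j in range(i + 1, n):
            x, y = matrix[:, i], matrix[:, j]
            if metric == "jaccard":
                d = jaccard_binary(x, y)
            elif metric == "braycurtis":
                d = bray_curtis(x, y)
            elif metric == "unweighted_unifrac":
                d = unifrac(tree, x, y, feature_ids, mode="unweighted")
            elif metric == "weighted_unifrac":
                d = unifrac(tree, x, y, feature_ids, mode=weighted_mode)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=sample_ids)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # over positive eigenvalues
    n_negative: int
    negative_magnitude: float


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical PCoA: Gower-center -1/2 D^2, eigendecompose, scale by sqrt(eig)."""
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals)) * 1e-12 if len(eigvals) else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    negative = eigvals < -tol
    pos_sum = eigvals[positive].sum()
    return Ordination(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive],
        n_negative=int(negative.sum()),
        negative_magnitude=float(-eigvals[negative].sum()),
    )


@dataclass
class AnosimResult:
    grouping: str
    r: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    pairwise: list[dict] = field(default_factory=list)


def _rank_matrix(dm: np.ndarray) -> np.ndarray:
    """Square matrix of average ranks of the off-diagonal distances."""
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm[iu])
    out = np.zeros((n, n))
    out[iu] = ranks
    return out + out.T


def _anosim_r(rank_mat: np.ndarray, labels: np.ndarray) -> float:
    n = rank_mat.shape[0]
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_mat[iu][same[iu]]
    between = rank_mat[iu][~same[iu]]
    m = n * (n - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2))


def _distinct_assignments(labels: list) -> int:
    n = len(labels)
    total = math.factorial(n)
    for _, g in itertools.groupby(sorted(labels)):
        total //= math.factorial(len(list(g)))
    return total


def anosim(
    dm: DistanceMatrix,
    groups: list[str],
    n_permutations: int = 999,
    seed: int = 0,
    posthoc: bool = True,
    grouping: str = "",
    exhaustive: str | bool = "auto",
) -> AnosimResult:
    """Clarke's ANOSIM with permutation p-value and pairwise post hoc tests.

    The null distribution is enumerated exhaustively when the label multiset
    admits at most 20,000 distinct assignments (then p is exact: the
    fraction of assignments with R >= observed); otherwise ``n_permutations``
    random relabelings give p = (1 + #{R_perm >= R_obs}) / (1 + B).
    ``exhaustive`` may force either path (``True`` errors if infeasible).
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    singletons = [u for u, c in zip(uniq, counts) if c < 2]
    if singletons:
        raise ValueError(f"singleton group(s): {singletons}")
    rank_mat = _rank_matrix(dm.data)
    r_obs = _anosim_r(rank_mat, labels)

    n_assign = _distinct_assignments(list(labels))
    if exhaustive is True and n_assign > EXHAUSTIVE_LIMIT:
        raise ValueError(f"exhaustive enumeration infeasible: {n_assign} assignments")
    if exhaustive is not False and n_assign <= EXHAUSTIVE_LIMIT:
        codes = np.unique(labels, return_inverse=True)[1]
        hits = total = 0
        for perm in _multiset_permutations(list(codes)):
            total += 1
            if _anosim_r(rank_mat, np.asarray(perm)) >= r_obs - 1e-12:
                hits += 1
        p = hits / total
        result = AnosimResult(grouping, r_obs, p, total, True)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if _anosim_r(rank_mat, rng.permutation(labels)) >= r_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        result = AnosimResult(grouping, r_obs, p, n_permutations, False)

    if posthoc and len(uniq) > 2:
        raw = []
        for g1, g2 in itertools.combinations(uniq, 2):
            mask = (labels == g1) | (labels == g2)
            sub = DistanceMatrix(dm.data[np.ix_(mask, mask)], ids=[i for i, m in zip(dm.ids, mask) if m])
            r = anosim(sub, list(labels[mask]), n_permutations, seed, posthoc=False)
            raw.append({"pair": (str(g1), str(g2)), "r": r.r, "p_value": r.p_value})
        adjusted = stats.false_discovery_control([e["p_value"] for e in raw])
        for entry, adj in zip(raw, adjusted):
            entry["p_adjusted"] = float(adj)
        result.pairwise = raw
    return result


def _multiset_permutations(items: list[int]):
    """Distinct permutations of a label multiset, lexicographic order."""
    from sympy.utilities.iterables import multiset_permutations

    yield from multiset_permutations(items)


def beta_pipeline(
    table: FeatureTable,
    metadata: SampleMetadata,
    metrics: list[str] = list(METRIC_CHOICES),
    tree: PhyloTree | None = None,
    depth: int | None = None,
    n_draws: int = 100,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, dict]:
    """Full beta stage: standardize, distance matrices, PCoA, ANOSIM per grouping."""
    if depth is None:
        depth = int(table.sample_totals().min())
    matrix, feature_ids, sample_ids = average_rarefied_table(table, depth, n_draws, seed)
    out: dict[str, dict] = {}
    for metric in metrics:
        dm = distance_matrix(matrix, sample_ids, metric, feature_ids=feature_ids, tree=tree)
        ordination = pcoa(dm)
        tests = {}
        for grouping in ("organ", "pond", "organ_pond"):
            labels = metadata.groups(grouping, sample_ids)
            tests[grouping] = anosim(dm, labels, n_permutations, seed, grouping=grouping)
        out[metric] = {"distance_matrix": dm, "pcoa": ordination, "anosim": tests}
    return out
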