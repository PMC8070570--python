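import itertools

import numpy as np
import pytest

from concord16s.seqcompare import (
    difference_profile,
    exact_overlap,
    expected_identity,
    origin_breakdown,
    pairwise_changes,
    resilience_curve,
    threshold_grid,
)
from concord16s.types import ClusterSet

from conftest import make_table


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook unit-cost global alignment DP (independent oracle)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def dp_match_bounds(a: str, b: str):
    """(min, max) matching columns achievable by any optimal alignment."""
    n, m = len(a), len(b)
    INF = 10**9
    # state: (distance, matches); track per-cell the set of (dist, matches)
    # pareto values with dist minimal
    best_min = [[(INF, INF)] * (m + 1) for _ in range(n + 1)]
    best_max = [[(INF, -INF)] * (m + 1) for _ in range(n + 1)]
    for g in (best_min, best_max):
        g[0][0] = (0, 0)
        for i in range(1, n + 1):
            g[i][0] = (i, 0)
        for j in range(1, m + 1):
            g[0][j] = (j, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            for g, pick in ((best_min, min), (best_max, max)):
                cands = []
                d, k = g[i - 1][j - 1]
                cands.append((d + (not match), k + match))
                d, k = g[i - 1][j]
                cands.append((d + 1, k))
                d, k = g[i][j - 1]
                cands.append((d + 1, k))
                dmin = min(c[0] for c in cands)
                g[i][j] = (dmin, pick(c[1] for c in cands if c[0] == dmin))
    return best_min[n][m][1], best_max[n][m][1]


class TestPairwiseChanges:
    @pytest.mark.parametrize(
        "a,b,changes,identity",
        [
            ("ACGT", "ACGT", 0, 1.0),
            ("ACGT", "ACGA", 1, 0.75),
            ("ACGTA", "ACGT", 1, 4 / 5),
        ],
    )
    def test_examples(self, a, b, changes, identity):
        assert pairwise_changes(a, b) == (changes, pytest.approx(identity))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_changes("", "ACGT")

    def test_against_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 25)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 25)))
            changes, ident = pairwise_changes(a, b)
            assert changes == dp_edit_distance(a, b)
            lo, hi = dp_match_bounds(a, b)
            # identity = matches / (matches + changes) for one optimal alignment
            assert ident == pytest.approx(hi / (hi + changes)) or (
                lo / (lo + changes) - 1e-12 <= ident <= hi / (hi + changes) + 1e-12
            )

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(6)]
        for a, b in itertools.combinations(seqs, 2):
            assert pairwise_changes(a, b)[0] == pairwise_changes(b, a)[0]
        for a, b, c in itertools.permutations(seqs[:4], 3):
            assert pairwise_changes(a, c)[0] <= pairwise_changes(a, b)[0] + pairwise_changes(b, c)[0]


def tiny_set(set_id, centroid_reads: dict[str, int], origin=None) -> ClusterSet:
    """ClusterSet with one feature per (sequence, reads) pair."""
    fids = [f"{set_id}_f{i}" for i in range(len(centroid_reads))]
    seqs = dict(zip(fids, centroid_reads.keys()))
    counts = np.array([[r] for r in centroid_reads.values()])
    table = make_table(counts, feature_ids=fids)
    return ClusterSet(set_id, table, seqs, origin=origin or {})


SEQ = {name: seq for name, seq in zip("sxyz", ["ACGTACGTAC", "TTGGCCAATT", "GGGGTTTTCC", "CACACACATG"])}


class TestExactOverlap:
    def test_full_overlap_single_compartment(self):
        sets = [tiny_set(s, {SEQ["s"]: r}) for s, r in [("A", 10), ("B", 20), ("C", 30)]]
        part = exact_overlap(sets)
        comp = frozenset("ABC")
        assert part.n_sequences == {comp: 1}
        assert part.n_reads[comp] == 60
        assert part.pct_reads(comp) == 100.0

    def test_disjoint_sets(self):
        part = exact_overlap([tiny_set("A", {SEQ["s"]: 10}), tiny_set("B", {SEQ["x"]: 20})])
        assert part.n_reads[frozenset("A")] == 10
        assert part.n_reads[frozenset("B")] == 20

    def test_chained_overlap_matches_enumeration(self):
        a = tiny_set("A", {SEQ["x"]: 5})
        b = tiny_set("B", {SEQ["x"]: 5, SEQ["y"]: 5})
        c = tiny_set("C", {SEQ["y"]: 5})
        part = exact_overlap([a, b, c])
        assert part.n_sequences == {frozenset("AB"): 1, frozenset("BC"): 1}
        assert part.n_reads == {frozenset("AB"): 10, frozenset("BC"): 10}

    def test_read_conservation_on_bundle(self, bundle):
        part = exact_overlap(list(bundle.sets.values()))
        assert sum(part.n_reads.values()) == sum(c.total_reads() for c in bundle.sets.values())
        assert part.total_reads == sum(part.n_reads.values())

    def test_duplicate_centroids_merged(self):
        s = tiny_set("A", {SEQ["s"]: 5})
        # add a second feature with the same centroid
        t = make_table(np.array([[5], [7]]), feature_ids=["f1", "f2"])
        dup = ClusterSet("A", t, {"f1": SEQ["s"], "f2": SEQ["s"]})
        part = exact_overlap([dup, tiny_set("B", {SEQ["s"]: 1})])
        assert part.n_reads[frozenset("AB")] == 13


class TestOriginBreakdown:
    def test_all_reference(self):
        s = tiny_set("A", {SEQ["s"]: 10, SEQ["x"]: 5}, origin={"A_f0": "reference", "A_f1": "reference"})
        brk = origin_breakdown(s)
        assert brk.pct_reads("reference") == 100.0

    def test_half_half_by_reads(self):
        s = tiny_set("A", {SEQ["s"]: 10, SEQ["x"]: 10}, origin={"A_f0": "reference", "A_f1": "de_novo"})
        brk = origin_breakdown(s)
        assert brk.pct_reads("reference") == 50.0
        assert brk.n_sequences == {"reference": 1, "de_novo": 1}

    def test_sums_equal_totals_on_bundle(self, bundle):
        for cset in bundle.sets.values():
            brk = origin_breakdown(cset)
            assert sum(brk.n_reads.values()) == cset.total_reads()
            assert sum(brk.n_sequences.values()) == cset.table.n_features


def mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = swap[chars[p]]
    return "".join(chars)


class TestDifferenceProfile:
    def test_mutually_one_apart(self):
        base = "ATGCCTAGAAGTGTGTGATC"
        seqs = {base: 5, mutate(base, [0]): 5, mutate(base, [1]): 5}
        prof = difference_profile(tiny_set("A", seqs))
        assert prof.cum_fraction(1) == 1.0

    def test_step_at_ten_changes(self):
        # 10 scattered substitutions over 50 nt: identity 0.8, passes the gate
        base = "TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACA"
        seqs = {base: 5, mutate(base, [1, 6, 11, 17, 22, 28, 33, 38, 43, 48]): 5}
        prof = difference_profile(tiny_set("A", seqs), max_changes=12)
        assert prof.cum_fraction(9) == 0.0
        assert prof.cum_fraction(10) == 1.0

    def test_min_identity_gate_excludes_distant_neighbours(self):
        base = "ATGCCTAGAAGTGTGTGATC"  # 20 nt; 10 changes -> identity 0.5 < 0.75
        seqs = {base: 5, mutate(base, range(10)): 5}
        prof = difference_profile(tiny_set("A", seqs), max_changes=15, min_identity=0.75)
        assert prof.cum_fraction(15) == 0.0  # no qualifying neighbour at all

    def test_single_sequence_stratum_flagged_empty(self):
        prof = difference_profile(tiny_set("A", {SEQ["s"]: 5}))
        assert prof.flagged_empty

    def test_matches_all_pairs_oracle_on_designed_fixture(self):
        base = "GCATTGCTGCCAAGTATTCGATGCATCT"
        seqs = [base, mutate(base, [0]), mutate(base, [0, 5, 9]),
                mutate(base, range(7)), mutate(base, range(14))]
        cs = tiny_set("A", {s: 10 - i for i, s in enumerate(seqs)})
        prof = difference_profile(cs, max_changes=20, min_identity=0.75)
        # oracle: all-pairs nearest neighbour with the identity gate
        nearest = {}
        for i, a in enumerate(seqs):
            cands = []
            for j, b in enumerate(seqs):
                if i != j:
                    ch, ident = pairwise_changes(a, b)
                    if ident >= 0.75:
                        cands.append(ch)
            if cands:
                nearest[i] = min(cands)
        for n in range(1, 21):
            expect = sum(1 for d in nearest.values() if d <= n) / len(seqs)
            assert prof.cum_fraction(n) == pytest.approx(expect)

    def test_origin_strata_partition_the_set(self, bundle):
        # raw 99%-OTU-like set: reference = true taxa, de_novo = satellites
        cs = bundle.sets["02_OTU_99"]
        ref = difference_profile(cs, max_changes=10, stratum="reference")
        dn = difference_profile(cs, max_changes=10, stratum="de_novo")
        assert ref.n_centroids + dn.n_centroids == cs.table.n_features
        # satellites sit 1-2 nt from their parent, but parents are in the
        # other stratum; whole-set profile sees them at 1-2 changes
        whole = difference_profile(cs, max_changes=10)
        assert whole.cum_fraction(2) > ref.cum_fraction(2)

    def test_cumulative_curve_non_decreasing(self, filtered_sets):
        prof = difference_profile(filtered_sets["03_ASV"], max_changes=15)
        fracs = [f for _, f in prof.curve()]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestExpectedIdentity:
    @pytest.mark.parametrize(
        "length,changes,expected",
        [(135, 0, 1.0), (100, 3, 0.97), (127, 1, 126 / 127)],
    )
    def test_values(self, length, changes, expected):
        assert expected_identity(length, changes) == pytest.approx(expected)

    def test_changes_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            expected_identity(10, 11)


class TestResilienceCurve:
    def test_nothing_merges_below_gate(self):
        rng = np.random.default_rng(2)
        seqs = {"".join(rng.choice(list("ACGT"), size=30)): 10 - i for i in range(4)}
        cs = tiny_set("A", seqs)
        curve = resilience_curve(cs, [0.9])
        assert curve.remaining_fraction == [1.0]

    def test_threshold_straddles_pair_identity(self):
        base = "ATGCCTAGAAGTGTGTGATC"  # 20 nt, 2 changes -> identity 0.9
        cs = tiny_set("A", {base: 10, mutate(base, [0, 1]): 5})
        curve = resilience_curve(cs, [0.95, 0.85])
        assert curve.remaining_fraction == [1.0, 0.5]

    def test_distinct_sequences_intact_at_full_identity(self, filtered_sets):
        cs = filtered_sets["03_ASV"]
        curve = resilience_curve(cs, [1.0])
        assert curve.remaining_fraction == [1.0]

    def test_monotone_and_matches_greedy_replay_oracle(self):
        base = "GTTACCCAGAGGTGCTCCTCACTACAGCCAGGTCAT"
        seqs = [base, mutate(base, [0]), mutate(base, [0, 1, 2]), mutate(base, range(6)),
                mutate(base, range(12)), mutate(base, range(20))]
        cs = tiny_set("A", {s: 20 - i for i, s in enumerate(seqs)})
        grid = threshold_grid(1.0, 0.5, 0.05)
        curve = resilience_curve(cs, grid)
        fracs = curve.remaining_fraction
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))  # non-increasing as t drops
        # oracle: replay the greedy rule independently at each threshold
        reads = {s: 20 - i for i, s in enumerate(seqs)}
        order = sorted(seqs, key=lambda s: (-reads[s], s))
        for t, frac in zip(grid, fracs):
            centroids = []
            for s in order:
                if not any(pairwise_changes(s, c)[1] >= t for c in centroids):
                    centroids.append(s)
            assert frac == pytest.approx(len(centroids) / len(seqs))
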