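"""Marker evaluation: K2P distances, UPGMA trees, Rf, gap, ranking.

Independent oracles: direct formula evaluation on classified sites for
K2P, an exhaustive edit-graph recursion for pairwise alignment scores,
hand-executed merges for UPGMA, and clade enumeration for Rf.
"""

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anserdiet.io_core import SeqRecord, Taxon, TaxonomyMap
from anserdiet.markers import (
    SATURATED,
    AlignedPair,
    DistanceMatrix,
    DivergenceSummary,
    MarkerReport,
    align_pairwise,
    barcoding_gap,
    divergence_summary,
    k2p_distance,
    pairwise_distances,
    rank_markers,
    resolution_rate,
    upgma,
)

# ---------------------------------------------------------------------------
# oracles


def k2p_oracle(seq_a: str, seq_b: str):
    """Independent site classification + formula evaluation."""
    purines = set("AG")
    comparable = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        comparable += 1
        if a == b:
            continue
        if (a in purines) == (b in purines):
            ts += 1
        else:
            tv += 1
    p, q = ts / comparable, tv / comparable
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return None
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def best_global_score(a: str, b: str) -> float:
    """Exhaustive recursion over the alignment graph (affine gaps,
    match +1 / mismatch -2 / open -5 / extend -2, end gaps penalized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = 1 if a[i] == b[j] else -2
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, (-2 if state == 1 else -5) + rec(i + 1, j, 1))
        if j < len(b):
            best = max(best, (-2 if state == 2 else -5) + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def score_aligned_pair(pair: AlignedPair) -> float:
    score = 0.0
    prev = None  # None | "a" | "b"
    for ca, cb in zip(pair.seq_a, pair.seq_b):
        if ca == "-":
            score += -2 if prev == "a" else -5
            prev = "a"
        elif cb == "-":
            score += -2 if prev == "b" else -5
            prev = "b"
        else:
            score += 1 if ca == cb else -2
            prev = None
    return score


def random_ultrametric(rng: np.random.Generator, n: int):
    """Random ultrametric distance matrix via recursive partition."""
    d = np.zeros((n, n))

    def build(idx: list[int], hmax: float) -> None:
        if len(idx) == 1:
            return
        cut = int(rng.integers(1, len(idx)))
        h = hmax * float(rng.uniform(0.3, 0.95))
        left, right = idx[:cut], idx[cut:]
        for i in left:
            for j in right:
                d[i, j] = d[j, i] = 2 * h
        build(left, h)
        build(right, h)

    order = list(rng.permutation(n))
    build(order, 1.0)
    return d


# ---------------------------------------------------------------------------
# K2P


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p_distance(AlignedPair("A" * 20, "A" * 20)) == 0.0

    def test_worked_example(self):
        # 20 sites, 2 transitions (A<->G), 1 transversion (A<->C)
        a = "A" * 20
        b = "G" * 2 + "C" + "A" * 17
        d = k2p_distance(AlignedPair(a, b))
        assert d == pytest.approx(0.170181, abs=1e-6)

    def test_saturation_flag(self):
        # 10 sites, 5 transitions: 1 - 2P - Q = 0
        a = "A" * 10
        b = "G" * 5 + "A" * 5
        assert k2p_distance(AlignedPair(a, b)) is SATURATED

    def test_zero_comparable_sites_error(self):
        with pytest.raises(ValueError):
            k2p_distance(AlignedPair("NNN", "ACG"))

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_k2p_at_least_p_distance(self, data):
        n = data.draw(st.integers(10, 60))
        ts = data.draw(st.integers(0, n // 4))
        tv = data.draw(st.integers(0, n // 4))
        a = "A" * n
        b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
        d = k2p_distance(AlignedPair(a, b))
        p_dist = (ts + tv) / n
        assert d is not SATURATED
        assert d >= p_dist - 1e-12
        if ts + tv == 0:
            assert d == 0.0
        else:
            assert d > p_dist - 1e-12 and d != pytest.approx(0.0)


class TestPairwiseDistances:
    def test_identical_set_all_zero(self):
        recs = [SeqRecord(f"s{i}", "ACGTACGTAC") for i in range(3)]
        m = pairwise_distances(recs)
        assert np.allclose(m.d, 0.0)

    def test_symmetry_and_identity(self):
        recs = [SeqRecord("a", "ACGT"), SeqRecord("b", "ACGA"),
                SeqRecord("c", "ACGT")]
        m = pairwise_distances(recs)
        assert m["a", "c"] == 0.0
        assert m["a", "b"] == m["b", "c"]
        assert np.allclose(m.d, m.d.T)

    def test_matches_site_classification_oracle(self, rng):
        # moderately diverged relatives of one ancestor, plus one
        # unrelated sequence that saturates against the rest
        bases = np.array(list("ACGT"))
        root = bases[rng.integers(0, 4, 200)]
        recs = []
        for i in range(4):
            seq = root.copy()
            pos = rng.choice(200, size=int(rng.integers(0, 40)), replace=False)
            seq[pos] = bases[rng.integers(0, 4, len(pos))]
            recs.append(SeqRecord(f"r{i}", "".join(seq)))
        recs.append(SeqRecord("far", "".join(bases[rng.integers(0, 4, 200)])))
        m = pairwise_distances(recs)
        saw_saturation = False
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                expected = k2p_oracle(recs[i].sequence, recs[j].sequence)
                if expected is None:
                    assert m.saturated[i, j]
                    saw_saturation = True
                else:
                    assert m.d[i, j] == pytest.approx(expected, abs=1e-12)
        assert saw_saturation

    def test_pairwise_deletion_of_n_sites(self):
        # N columns are deleted per pair, not globally
        recs = [SeqRecord("a", "ACGTN"), SeqRecord("b", "ACGTA")]
        m = pairwise_distances(recs)
        assert m.d[0, 1] == 0.0


class TestAlignPairwise:
    def test_identical_no_gaps(self):
        pair = align_pairwise("ACGT", "ACGT")
        assert pair.comparable_sites == 4
        assert "-" not in pair.seq_a + pair.seq_b

    def test_single_gap(self):
        pair = align_pairwise("ACGT", "AGT")
        assert pair.seq_b.count("-") == 1
        assert pair.comparable_sites == 3

    def test_all_mismatch_gapless(self):
        pair = align_pairwise("ACGT", "TTTT")
        assert "-" not in pair.seq_a + pair.seq_b
        assert pair.comparable_sites == 4

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_pairwise("", "ACGT")

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_optimal_score_matches_exhaustive_recursion(self, data):
        seqs = st.text(alphabet="ACGT", min_size=1, max_size=5)
        a, b = data.draw(seqs), data.draw(seqs)
        pair = align_pairwise(a, b)
        assert score_aligned_pair(pair) == best_global_score(a, b)


# ---------------------------------------------------------------------------
# divergence summaries


def _matrix(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(labels), d, np.zeros((n, n)),
                          np.zeros((n, n)), np.zeros((n, n), dtype=bool))


def _tax(mapping):
    tax = TaxonomyMap()
    for seq_id, (fam, gen, sp) in mapping.items():
        tax[seq_id] = Taxon(fam, gen, sp)
    return tax


class TestDivergenceSummary:
    def test_single_pair(self):
        m = _matrix(["x", "y"], {("x", "y"): 0.027})
        tax = _tax({"x": ("F", "G", "G a"), "y": ("F", "G", "G b")})
        s = divergence_summary(m, tax, "G", "genus")
        assert s.max == s.min == s.mean == 0.027
        assert s.sd == 0.0 and s.n_pairs == 1
        assert s.intra_max is None

    def test_single_species_group_errors(self):
        m = _matrix(["x", "y"], {("x", "y"): 0.01})
        tax = _tax({"x": ("F", "G", "G a"), "y": ("F", "G", "G a")})
        with pytest.raises(ValueError, match="no inter-specific"):
            divergence_summary(m, tax, "G", "genus")

    def test_planted_distances_match_pair_enumeration(self, rng):
        # 3 species x 2 sequences: 12 inter-specific + 3 intra pairs
        labels = [f"{sp}{k}" for sp in "abc" for k in (1, 2)]
        entries = {}
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                entries[(x, y)] = round(float(rng.uniform(0.001, 0.2)), 6)
        m = _matrix(labels, entries)
        tax = _tax({l: ("F", "G", f"G {l[0]}") for l in labels})
        s = divergence_summary(m, tax, "G", "genus")
        inter = [v for (x, y), v in entries.items() if x[0] != y[0]]
        intra = [v for (x, y), v in entries.items() if x[0] == y[0]]
        assert s.n_pairs == 12 and len(intra) == 3
        assert s.max == max(inter) and s.min == min(inter)
        assert s.mean == pytest.approx(np.mean(inter))
        assert s.sd == pytest.approx(np.std(inter))
        assert s.intra_max == max(intra)

    def test_absent_group_errors(self):
        m = _matrix(["x"], {})
        with pytest.raises(ValueError, match="absent"):
            divergence_summary(m, _tax({"x": ("F", "G", "G a")}),
                               "H", "genus")


class TestBarcodingGap:
    def test_gap_present(self):
        s = DivergenceSummary("G", "genus", 0.05, 0.02, 0.03, 0.01, 3,
                              intra_max=0.01)
        assert barcoding_gap(s) is True

    def test_strict_inequality(self):
        s = DivergenceSummary("G", "genus", 0.0, 0.0, 0.0, 0.0, 1,
                              intra_max=0.0)
        assert barcoding_gap(s) is False

    def test_missing_intra_indeterminate(self):
        s = DivergenceSummary("G", "genus", 0.05, 0.02, 0.03, 0.01, 3)
        assert barcoding_gap(s) is None


# ---------------------------------------------------------------------------
# UPGMA and Rf


class TestUpgma:
    def test_two_leaves_cherry_height(self):
        m = _matrix(["A", "B"], {("A", "B"): 0.4})
        tree = upgma(m)
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.root.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        m = _matrix(["A", "B", "C"],
                    {("A", "B"): 2.0, ("A", "C"): 6.0, ("B", "C"): 6.0})
        tree = upgma(m)
        assert tree.root.height == pytest.approx(3.0)
        inner = [c for c in tree.root.children if c.children is not None]
        assert len(inner) == 1 and inner[0].height == pytest.approx(1.0)
        assert sorted(inner[0].leaves()) == ["A", "B"]

    def test_refuses_saturated_matrix(self):
        m = _matrix(["A", "B"], {("A", "B"): 0.4})
        m.saturated[0, 1] = True
        with pytest.raises(ValueError, match="saturated"):
            upgma(m)

    def test_refuses_single_leaf(self):
        with pytest.raises(ValueError):
            upgma(_matrix(["A"], {}))

    def test_reconstructs_random_ultrametric_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            d = random_ultrametric(rng, n)
            labels = [f"L{i}" for i in range(n)]
            m = DistanceMatrix(labels, d, np.zeros_like(d), np.zeros_like(d),
                               np.zeros_like(d, dtype=bool))
            coph = upgma(m).cophenetic()
            assert np.allclose(coph.d, d, atol=1e-12, rtol=0)

    def test_output_always_ultrametric(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            d = np.zeros((n, n))
            upper = rng.uniform(0.01, 1.0, size=(n, n))
            d = np.triu(upper, 1)
            d = d + d.T
            labels = [f"L{i}" for i in range(n)]
            m = DistanceMatrix(labels, d, np.zeros_like(d), np.zeros_like(d),
                               np.zeros_like(d, dtype=bool))
            tree = upgma(m)
            heights = tree.leaf_heights_from_root()
            vals = list(heights.values())
            assert max(vals) - min(vals) < 1e-9
            # newick serializes every leaf
            nwk = tree.newick()
            assert all(l in nwk for l in labels)


class TestResolutionRate:
    def _tree(self, entries, labels):
        return upgma(_matrix(labels, entries))

    def test_perfectly_sorted_100(self):
        labels = ["a1", "a2", "b1", "b2"]
        entries = {("a1", "a2"): 0.1, ("b1", "b2"): 0.1}
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                entries[(x, y)] = 1.0
        tree = self._tree(entries, labels)
        rf = resolution_rate(tree, {l: l[0] for l in labels})
        assert rf == 100.0

    def test_interleaved_0(self):
        labels = ["a1", "b1", "a2", "b2"]
        entries = {("a1", "b1"): 0.1, ("a2", "b2"): 0.1}
        for x in ("a1", "b1"):
            for y in ("a2", "b2"):
                entries[(x, y)] = 1.0
        tree = self._tree(entries, labels)
        assert resolution_rate(tree, {l: l[0] for l in labels}) == 0.0

    def test_three_sorted_one_interleaved_75(self):
        # species a,b,c sorted; species d split across two clades
        labels = ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"]
        entries = {}
        cherries = [("a1", "a2"), ("b1", "b2"), ("c1", "c2"), ("d1", "d2")]
        for x, y in [("a1", "a2"), ("b1", "b2"), ("c1", "c2")]:
            entries[(x, y)] = 0.1
        entries[("d1", "a1")] = entries[("d1", "a2")] = 0.2
        entries[("d2", "b1")] = entries[("d2", "b2")] = 0.2
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                entries.setdefault((x, y), 2.0)
        tree = self._tree(entries, labels)
        rf = resolution_rate(tree, {l: l[0] for l in labels})
        assert rf == 75.0

    def test_singletons_excluded(self):
        labels = ["a1", "a2", "b1"]
        entries = {("a1", "a2"): 0.1, ("a1", "b1"): 1.0, ("a2", "b1"): 1.0}
        tree = self._tree(entries, labels)
        # only species 'a' enters the calculation
        assert resolution_rate(tree, {l: l[0] for l in labels}) == 100.0

    def test_undefined_when_all_singletons(self):
        labels = ["a1", "b1"]
        tree = self._tree({("a1", "b1"): 1.0}, labels)
        assert resolution_rate(tree, {l: l[0] for l in labels}) is None

    def test_invariant_under_leaf_relabelling_order(self, rng):
        labels = ["a1", "a2", "b1", "b2", "c1"]
        entries = {("a1", "a2"): 0.1, ("b1", "b2"): 0.3}
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                entries.setdefault((x, y), 1.0 + 0.01 * i)
        base = None
        for _ in range(5):
            perm = list(rng.permutation(labels))
            m = _matrix(labels, entries).submatrix(perm)
            rf = resolution_rate(upgma(m), {l: l[0] for l in labels})
            base = rf if base is None else base
            assert rf == base


# ---------------------------------------------------------------------------
# marker ranking


class TestRankMarkers:
    def _report(self, gene, success, means=(), gaps=()):
        summaries = [
            DivergenceSummary(g, "genus", m, m, m, 0.0, 1) for g, m in means
        ]
        return MarkerReport(gene=gene, amplification_success=success,
                            summaries=summaries,
                            gap_ok={g: ok for g, ok in gaps})

    def test_amplification_success_dominates(self):
        trnl = self._report("trnL", 1.00)
        matk = self._report("matK", 0.43)
        ordered, audit = rank_markers([matk, trnl])
        assert [r.gene for r in ordered] == ["trnL", "matK"]
        assert list(audit["gene"]) == ["trnL", "matK"]

    def test_tied_markers_alphabetical(self):
        a = self._report("geneB", 0.9)
        b = self._report("geneA", 0.9)
        ordered, _ = rank_markers([a, b])
        assert [r.gene for r in ordered] == ["geneA", "geneB"]

    def test_single_marker(self):
        r = self._report("trnL", 1.0)
        ordered, _ = rank_markers([r])
        assert ordered == [r]

    def test_mean_divergence_wins_break_ties(self):
        x = self._report("x", 0.9, means=[("Carex", 0.03), ("Poa", 0.02)])
        y = self._report("y", 0.9, means=[("Carex", 0.01), ("Poa", 0.05)])
        ordered, audit = rank_markers([x, y])
        # each wins one group; gap counts equal; alphabetical fallback
        assert [r.gene for r in ordered] == ["x", "y"]
        assert list(audit["n_groups_largest_mean_divergence"]) == [1, 1]

    def test_total_order_deterministic(self):
        reports = [self._report(g, s) for g, s in
                   [("a", 0.5), ("b", 0.7), ("c", 0.7), ("d", 0.2)]]
        ordered1, _ = rank_markers(reports)
        ordered2, _ = rank_markers(list(reversed(reports)))
        assert [r.gene for r in ordered1] == [r.gene for r in ordered2] == \
            ["b", "c", "a", "d"]
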