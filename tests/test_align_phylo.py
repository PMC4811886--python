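import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genefam.align_phylo import (
    DistanceMatrix,
    Msa,
    PhyloTree,
    TreeNode,
    assign_groups,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    pairwise_align,
    progressive_msa,
)
from genefam.genome_io import SequenceSet

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# brute-force global affine alignment oracle (gap of length k costs
# open + (k-1)*extend, matching the implementation's stated convention)
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(row_a: str, row_b: str, gap_open=10.0, gap_extend=0.5) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += BLOSUM62[x, y]
            in_gap_a = in_gap_b = False
    return score


class TestPairwiseAlign:
    def test_identical_sequences(self):
        row_a, row_b, ident, _ = pairwise_align("MKLV", "MKLV")
        assert ident == 1.0 and "-" not in row_a + row_b

    @pytest.mark.parametrize("a,b", [("ACDE", "ACE"), ("MKLW", "MW"), ("AC", "CA")])
    def test_optimal_score_matches_exhaustive_enumeration(self, a, b):
        _, _, _, score = pairwise_align(a, b)
        best = max(
            score_alignment(ra, rb) for ra, rb in enumerate_alignments(a, b)
        )
        assert score == pytest.approx(best)

    def test_disjoint_alphabet_identity_zero(self):
        _, _, ident, _ = pairwise_align("AAAA", "WWWW")
        assert ident == 0.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_align("", "MK")


class TestProgressiveMsa:
    def test_identical_sequences_gapless(self):
        seqs = SequenceSet({f"s{i}": "MKLVWA" for i in range(3)}, alphabet="protein")
        msa = progressive_msa(seqs)
        assert all(r == "MKLVWA" for r in msa.rows)

    def test_degapped_rows_equal_inputs(self):
        seqs = SequenceSet(
            {"a": "MKLVWAQ", "b": "MKLWAQ", "c": "MKLVWQ", "d": "MALVWAQ"},
            alphabet="protein",
        )
        msa = progressive_msa(seqs)
        for i, sid in enumerate(msa.ids):
            assert msa.degapped(i) == seqs[sid]

    def test_two_sequences_reduce_to_pairwise(self):
        seqs = SequenceSet({"a": "MKLVW", "b": "MKVW"}, alphabet="protein")
        msa = progressive_msa(seqs)
        row_a, row_b, _, _ = pairwise_align("MKLVW", "MKVW")
        assert msa.rows == [row_a, row_b]

    def test_single_indel_placed_consistently(self):
        seqs = SequenceSet(
            {"a": "MKWA", "b": "MKWA", "c": "MKA"}, alphabet="protein"
        )
        msa = progressive_msa(seqs)
        assert msa.n_cols == 4
        gap_cols = {r.index("-") for r in msa.rows if "-" in r}
        assert len(gap_cols) == 1  # all gaps in one column


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = Msa(["a", "b"], ["MKLV", "MKLV"])
        assert distance_matrix(msa, "p").matrix[0, 1] == 0.0

    def test_half_different_p(self):
        msa = Msa(["a", "b"], ["MKLV", "MALW"])
        assert distance_matrix(msa, "p").matrix[0, 1] == 0.5

    def test_poisson_closed_form(self):
        msa = Msa(["a", "b"], ["MKLV", "MALW"])
        d = distance_matrix(msa, "poisson").matrix[0, 1]
        assert d == pytest.approx(-math.log(0.5), abs=1e-12)  # 0.6931

    def test_pairwise_deletion_skips_gap_columns(self):
        msa = Msa(["a", "b"], ["MK-V", "MKLV"])
        assert distance_matrix(msa, "p").matrix[0, 1] == 0.0

    def test_poisson_dominates_p(self):
        msa = Msa(["a", "b", "c"], ["MKLVWA", "MALWWA", "MKLWAA"])
        p = distance_matrix(msa, "p").matrix
        poi = distance_matrix(msa, "poisson").matrix
        assert (poi >= p - 1e-15).all()
        assert ((p >= 0) & (p <= 1)).all()


# ---------------------------------------------------------------------------
# random additive trees as an NJ oracle
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (adjacency, leaf names)."""
    adj: dict[str, dict[str, float]] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def blen():
        return float(rng.uniform(0.2, 1.0))

    add_edge("L0", "int0", blen())
    add_edge("L1", "int0", blen())
    add_edge("L2", "int0", blen())
    n_int = 1
    for k in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = f"int{n_int}"
        n_int += 1
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(v, mid, w * (1 - split))
        add_edge(f"L{k}", mid, blen())
    return adj, [f"L{i}" for i in range(n_leaves)]


def path_distances(adj, leaves):
    n = len(leaves)
    mat = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            mat[i, j] = dist[dst]
    return mat


def true_splits_and_lengths(adj, leaves):
    """Bipartitions (canonical side without min leaf) and per-split lengths."""
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    splits = {}
    for u in adj:
        for v, w in adj[u].items():
            if u > v:
                continue
            # leaves on v's side of edge (u, v)
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x.startswith("L"):
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            key = frozenset(side)
            if len(key) == len(all_leaves) - 1:
                key = all_leaves - key  # pendant edge keyed by its single leaf
            elif ref in key and len(key) > 1:
                key = all_leaves - key
            splits[key] = splits.get(key, 0.0) + w
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = nj_tree(dm)
        lengths = tree.edge_lengths()
        assert lengths[frozenset({"A"})] == pytest.approx(1.0)
        assert lengths[frozenset({"B"})] == pytest.approx(1.0)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(2024)
        for rep in range(60):
            n = int(rng.integers(5, 9))
            adj, leaves = random_additive_tree(n, rng)
            dm = DistanceMatrix(leaves, path_distances(adj, leaves))
            tree = nj_tree(dm)
            true = true_splits_and_lengths(adj, leaves)
            true_bps = {s for s in true if 2 <= len(s) <= n - 2}
            assert tree.bipartitions() == true_bps
            got = tree.edge_lengths()
            for split, length in true.items():
                assert got[split] == pytest.approx(length, abs=1e-9), split

    def test_star_tie_breaks_deterministically(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        t1 = nj_tree(DistanceMatrix(list("ABCD"), m))
        t2 = nj_tree(DistanceMatrix(list("ABCD"), m))
        assert t1.newick() == t2.newick()
        # lowest index pair (A, B) joined first
        assert frozenset({"C", "D"}) in t1.bipartitions()


class TestBootstrap:
    def _divergent_clade_msa(self):
        rng = np.random.default_rng(1)
        base1 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = "W" if s[i] != "W" else "Y"
            return "".join(s)

        base2 = mutate(base1, 25)  # two clear clades, distances unsaturated
        return Msa(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            [base1, mutate(base1, 3), mutate(base1, 5),
             base2, mutate(base2, 3), mutate(base2, 5)],
        )

    def test_identical_columns_full_support(self):
        msa = Msa(["a", "b", "c", "d"], ["MKLV", "MKLV", "MALV", "MALW"])
        tree = bootstrap_support(msa, n_reps=10, seed=0)
        sups = [n.support for _, n, _ in tree._edges() if not n.is_leaf and n.support is not None]
        assert sups  # at least one internal edge annotated

    def test_single_replicate_support_is_0_or_100(self):
        tree = bootstrap_support(self._divergent_clade_msa(), n_reps=1, seed=3)
        for _, node, _ in tree._edges():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_two_clades_strongly_supported(self):
        tree = bootstrap_support(self._divergent_clade_msa(), n_reps=100, seed=5)
        lengths = {frozenset({"b1", "b2", "b3"}): None}
        found = False
        for _, node, _ in tree._edges():
            if not node.is_leaf and set(node.leaf_names()) in (
                {"a1", "a2", "a3"}, {"b1", "b2", "b3"}
            ):
                found = True
                assert node.support >= 95
        assert found

    def test_supports_invariant_to_taxon_order(self):
        msa = self._divergent_clade_msa()
        perm = [3, 0, 5, 2, 4, 1]
        msa2 = Msa([msa.ids[i] for i in perm], [msa.rows[i] for i in perm])
        t1 = bootstrap_support(msa, 50, seed=9)
        t2 = bootstrap_support(msa2, 50, seed=9)

        def support_map(t):
            out = {}
            all_taxa = frozenset(t.ids)
            ref = min(all_taxa)
            for _, node, _ in t._edges():
                if node.is_leaf or node.support is None:
                    continue
                side = frozenset(node.leaf_names())
                key = side if ref not in side else all_taxa - side
                out[key] = node.support
            return out

        m1, m2 = support_map(t1), support_map(t2)
        for key in set(m1) & set(m2):
            assert m1[key] == m2[key]


class TestGroupAssignment:
    def _tree(self):
        # ((q1, refA1), (refA2, (refD1, refD2)))  with unit branches
        q1, a1, a2 = TreeNode("q1"), TreeNode("refA1"), TreeNode("refA2")
        d1, d2 = TreeNode("refD1"), TreeNode("refD2")
        left = TreeNode(children=[(q1, 1.0), (a1, 1.0)])
        dd = TreeNode(children=[(d1, 1.0), (d2, 1.0)])
        right = TreeNode(children=[(a2, 1.0), (dd, 1.0)])
        root = TreeNode(children=[(left, 1.0), (right, 1.0), (TreeNode("q2"), 4.0)])
        return PhyloTree(root, ["q1", "refA1", "refA2", "refD1", "refD2", "q2"])

    def test_sister_to_single_reference(self):
        res = assign_groups(self._tree(), {"refA1": "A", "refA2": "A",
                                           "refD1": "D", "refD2": "D"})
        assert res.labels["q1"] == "A"

    def test_query_inside_reference_clade(self):
        d1, d2, d3, q = (TreeNode(n) for n in ("r1", "r2", "r3", "q"))
        inner = TreeNode(children=[(q, 1.0), (d1, 1.0)])
        mid = TreeNode(children=[(inner, 1.0), (d2, 1.0)])
        root = TreeNode(children=[(mid, 1.0), (d3, 1.0), (TreeNode("out"), 9.0)])
        tree = PhyloTree(root, ["q", "r1", "r2", "r3", "out"])
        res = assign_groups(tree, {"r1": "D", "r2": "D", "r3": "D"})
        assert res.labels["q"] == "D"

    def test_fallback_nearest_reference_and_tie_flag(self):
        q, ra, rb = TreeNode("q"), TreeNode("refA"), TreeNode("refB")
        root = TreeNode(children=[(q, 1.0), (ra, 2.0), (rb, 2.0)])
        tree = PhyloTree(root, ["q", "refA", "refB"])
        res = assign_groups(tree, {"refA": "B", "refB": "A"})
        assert res.labels["q"] == "A"  # exact tie -> lexicographically smaller
        assert "q" in res.flagged_ties

    def test_no_references_all_unassigned(self):
        res = assign_groups(self._tree(), {})
        assert set(res.labels.values()) == {"unassigned"}

    def test_recovers_planted_groups(self, default_bundle):
        # one member per group serves as the labeled reference set
        truth = default_bundle.manifest.group_of
        members = sorted(truth)
        refs = {}
        for gid in members:
            refs.setdefault(truth[gid], gid)
        ref_labels = {gid: lab for lab, gid in refs.items()}
        seqs = {g: default_bundle.proteins[g] for g in members}
        msa = progressive_msa(SequenceSet(seqs, alphabet="protein"))
        tree = nj_tree(distance_matrix(msa))
        res = assign_groups(tree, ref_labels)
        for gid in members:
            assert res.labels[gid] == truth[gid], gid
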