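from itertools import combinations

import numpy as np
import pytest

from genefam.dup_synteny import (
    HomologPair,
    chain_anchors,
    classify_segmental,
    classify_tandem,
    find_homolog_pairs,
    ortholog_topology,
)
from genefam.genome_io import GeneModel, SequenceSet, build_chromosome_map


def _map(layout: dict[str, list[str]]):
    genes = []
    for chrom, ids in layout.items():
        for i, gid in enumerate(ids):
            start = 1000 * (i + 1)
            genes.append(
                GeneModel(gid, chrom, "+", start, start + 100, exons=[(start, start + 100)])
            )
    return build_chromosome_map(genes)


class TestHomologPairs:
    def test_identical_proteins_pair(self):
        seqs = SequenceSet({"a": "MKLVWAQRST" * 4, "b": "MKLVWAQRST" * 4},
                           alphabet="protein")
        (pair,) = find_homolog_pairs(seqs)
        assert pair.identity == 1.0 and pair.genes == ("a", "b")

    def test_unrelated_random_proteins_rejected(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKMNPQRSTVWY")
        seqs = SequenceSet(
            {f"r{i}": "".join(rng.choice(aas, size=80)) for i in range(6)},
            alphabet="protein",
        )
        assert find_homolog_pairs(seqs) == []

    def test_three_member_family_all_pairs(self):
        base = "MKLVWAQRSTYHNDCEFGIP" * 3
        seqs = SequenceSet(
            {"a": base, "b": base[:-2] + "AA", "c": "G" + base[1:]},
            alphabet="protein",
        )
        pairs = find_homolog_pairs(seqs)
        assert {p.genes for p in pairs} == {("a", "b"), ("a", "c"), ("b", "c")}


class TestTandemRule:
    @pytest.mark.parametrize(
        "intervening,expected",
        [(0, "tandem"), (1, "tandem"), (2, "unclassified"), (3, "unclassified")],
    )
    def test_intervening_truth_table(self, intervening, expected):
        ids = ["gA"] + [f"x{i}" for i in range(intervening)] + ["gB"] + ["x9"]
        cmap = _map({"chr1": ids})
        (call,) = classify_tandem([HomologPair("gA", "gB")], cmap)
        assert call.mode == expected
        assert call.intervening == intervening

    def test_cross_chromosome_never_tandem(self):
        cmap = _map({"chr1": ["gA"], "chr2": ["gB"]})
        (call,) = classify_tandem([HomologPair("gA", "gB")], cmap)
        assert call.mode == "unclassified" and call.intervening is None

    def test_symmetric_in_pair_order_and_chrom_relabeling(self):
        for chrom in ("chr1", "chrZ"):
            cmap = _map({chrom: ["gA", "gB", "gC"]})
            c1 = classify_tandem([HomologPair("gA", "gC")], cmap)[0]
            c2 = classify_tandem([HomologPair("gC", "gA")], cmap)[0]
            assert c1.mode == c2.mode == "tandem"

    def test_missing_gene_errors(self):
        with pytest.raises(KeyError):
            classify_tandem([HomologPair("gA", "gZ")], _map({"chr1": ["gA"]}))


# ---------------------------------------------------------------------------
# exhaustive chaining oracle
# ---------------------------------------------------------------------------

def oracle_best_chain_size(anchors, max_gap):
    """Largest valid chain over all subsets (both orientations)."""
    best = 0
    n = len(anchors)
    for r in range(1, n + 1):
        for sub in combinations(range(n), r):
            pts = sorted(anchors[i] for i in sub)
            for sign in (1, -1):
                ok = True
                for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                    if a2 <= a1 or a2 - a1 > max_gap:
                        ok = False
                        break
                    db = sign * (b2 - b1)
                    if db <= 0 or db > max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, r)
    return best


def _chrom_pair_setup(anchor_coords):
    """Place anchors at given (ordinal_a, ordinal_b) between chr1 and chr2."""
    n_a = max(a for a, _ in anchor_coords) + 2
    n_b = max(b for _, b in anchor_coords) + 2
    layout = {
        "chr1": [f"a{i}" for i in range(n_a)],
        "chr2": [f"b{i}" for i in range(n_b)],
    }
    cmap = _map(layout)
    pairs = [HomologPair(f"a{oa}", f"b{ob}") for oa, ob in anchor_coords]
    return pairs, cmap


class TestChaining:
    def test_perfect_ascending_run(self):
        coords = [(i, i) for i in range(5)]
        pairs, cmap = _chrom_pair_setup(coords)
        (block,) = chain_anchors(pairs, cmap, cmap, min_anchors=3, max_gap=5)
        assert block.n_anchors == 5 and block.orientation == "same"

    def test_gap_larger_than_max_breaks_chain(self):
        coords = [(i, i) for i in range(5)] + [(30, 30)]
        pairs, cmap = _chrom_pair_setup(coords)
        blocks = chain_anchors(pairs, cmap, cmap, min_anchors=3, max_gap=5)
        assert len(blocks) == 1 and blocks[0].n_anchors == 5

    def test_descending_b_gives_inverted_block(self):
        coords = [(i, 10 - i) for i in range(5)]
        pairs, cmap = _chrom_pair_setup(coords)
        (block,) = chain_anchors(pairs, cmap, cmap, min_anchors=3, max_gap=5)
        assert block.orientation == "inverted" and block.n_anchors == 5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(120):
            n = int(rng.integers(2, 9))
            coords = [
                (int(rng.integers(0, 12)), int(rng.integers(0, 12)))
                for _ in range(n)
            ]
            coords = list({c for c in coords})
            # ordinals must be unique per gene side for a clean mapping
            seen_a, seen_b, uniq = set(), set(), []
            for a, b in coords:
                if a in seen_a or b in seen_b:
                    continue
                seen_a.add(a)
                seen_b.add(b)
                uniq.append((a, b))
            if len(uniq) < 1:
                continue
            max_gap = int(rng.integers(2, 6))
            pairs, cmap = _chrom_pair_setup(uniq)
            blocks = chain_anchors(pairs, cmap, cmap, min_anchors=1, max_gap=max_gap)
            got = max((b.n_anchors for b in blocks), default=0)
            assert got == oracle_best_chain_size(uniq, max_gap), uniq

    def test_each_anchor_in_at_most_one_block(self):
        coords = [(i, i) for i in range(6)] + [(i, 20 + i) for i in range(3, 9)]
        seen_a, seen_b, uniq = set(), set(), []
        for a, b in coords:
            if a in seen_a or b in seen_b:
                continue
            seen_a.add(a), seen_b.add(b)
            uniq.append((a, b))
        pairs, cmap = _chrom_pair_setup(uniq)
        blocks = chain_anchors(pairs, cmap, cmap, min_anchors=2, max_gap=25)
        all_anchors = [p.genes for b in blocks for p in b.anchors]
        assert len(all_anchors) == len(set(all_anchors))


class TestSegmental:
    def test_cross_chromosome_anchor_is_segmental(self):
        coords = [(i, i) for i in range(4)]
        pairs, cmap = _chrom_pair_setup(coords)
        blocks = chain_anchors(pairs, cmap, cmap, min_anchors=3, max_gap=5)
        calls = classify_segmental(pairs, blocks)
        assert all(c.mode == "segmental" for c in calls)
        assert all(c.block_id == blocks[0].block_id for c in calls)

    def test_same_chromosome_block_allowed(self):
        ids = [f"g{i}" for i in range(20)]
        cmap = _map({"chr3": ids})
        pairs = [HomologPair(f"g{i}", f"g{i + 10}") for i in range(4)]
        blocks = chain_anchors(pairs, cmap, None, min_anchors=3, max_gap=5)
        assert len(blocks) == 1
        calls = classify_segmental(pairs, blocks)
        assert {c.mode for c in calls} == {"segmental"}

    def test_tandem_takes_precedence(self):
        ids = [f"g{i}" for i in range(20)]
        cmap = _map({"chr3": ids})
        pairs = [HomologPair(f"g{i}", f"g{i + 1}") for i in range(0, 8, 2)]
        tandem = classify_tandem(pairs, cmap)
        blocks = chain_anchors(pairs, cmap, None, min_anchors=3, max_gap=5)
        calls = classify_segmental(pairs, blocks, tandem)
        assert {c.mode for c in calls} == {"tandem"}

    def test_unlinked_pair_unclassified(self):
        cmap = _map({"chr1": ["gA", "x", "y", "z", "gB"]})
        (call,) = classify_segmental([HomologPair("gA", "gB")], [])
        assert call.mode == "unclassified"


class TestOrthologTopology:
    def test_single_pair(self):
        assert ortholog_topology([("a1", "b1")]).counts()["one_to_one"] == 1

    def test_one_to_many(self):
        topo = ortholog_topology([("a1", "b1"), ("a1", "b2")])
        assert topo.counts() == {
            "one_to_one": 0, "one_to_many": 1, "many_to_one": 0, "many_to_many": 0
        }

    def test_component_enumeration(self):
        topo = ortholog_topology(
            [("a1", "b1"), ("a2", "b1"), ("a3", "b2"), ("a3", "b3"), ("a4", "b4")]
        )
        assert topo.counts() == {
            "one_to_one": 1, "one_to_many": 1, "many_to_one": 1, "many_to_many": 0
        }

    def test_many_to_many(self):
        topo = ortholog_topology(
            [("a1", "b1"), ("a2", "b1"), ("a1", "b2"), ("a2", "b2")]
        )
        assert topo.counts()["many_to_many"] == 1

    def test_counts_partition_components(self):
        rng = np.random.default_rng(3)
        pairs = {
            (f"a{int(rng.integers(8))}", f"b{int(rng.integers(8))}")
            for _ in range(20)
        }
        topo = ortholog_topology(sorted(pairs))
        assert sum(topo.counts().values()) == len(topo.components)


class TestPlantedRecovery:
    def test_duplication_modes_recovered_exactly(self, dup_recovery_bundle):
        bundle = dup_recovery_bundle
        cmap = build_chromosome_map(bundle.genes)
        pairs = find_homolog_pairs(bundle.proteins)
        tandem = classify_tandem(pairs, cmap)
        blocks = chain_anchors(pairs, cmap, None)
        calls = classify_segmental(pairs, blocks, tandem)
        called = {
            c.pair.genes: c.mode for c in calls if c.mode != "unclassified"
        }
        assert called == bundle.manifest.planted_modes()
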