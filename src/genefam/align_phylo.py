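"""Progressive multiple alignment, neighbor joining, bootstrap, group labels.

The phylogenetic stage mirrors the classic protein-family workflow:
global affine-gap pairwise alignment (BLOSUM62), a progressive multiple
alignment over an NJ guide tree, Poisson- or p-distance estimation with
pairwise gap deletion, Saitou–Nei neighbor joining, bootstrap supports
from column resampling, and nearest-labeled-clade group assignment
against a reference set (e.g. *Arabidopsis* bZIP groups A–L, S).

Scoring convention for affine gaps follows Biopython's PairwiseAligner:
a gap of length k costs gap_open + (k−1)·gap_extend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import SequenceSet

log = logging.getLogger(__name__)

GAP = "-"
#: poisson distance assigned when sequences share no identical compared column
DISTANCE_CEILING = 10.0


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[str, str, float, float]:
    """Optimal global alignment of two proteins.

    Returns ``(aligned_a, aligned_b, identity, score)`` where identity is
    matches over aligned columns (a global pairwise alignment has no
    dual-gap columns).  Ties between co-optimal alignments are broken by
    the aligner's deterministic enumeration order.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    cols = sum(1 for x, y in zip(row_a, row_b) if not (x == GAP and y == GAP))
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    identity = matches / cols if cols else 0.0
    return row_a, row_b, identity, float(aln.score)


def alignment_coverage(row_a: str, row_b: str, len_a: int, len_b: int) -> tuple[float, float]:
    """Fraction of each sequence sitting in mutually aligned (gap-free) columns."""
    aligned = sum(1 for x, y in zip(row_a, row_b) if x != GAP and y != GAP)
    return aligned / len_a, aligned / len_b


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """Aligned rows (equal length, '-' gaps) keyed by taxa in fixed order."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def subset_columns(self, cols: Sequence[int]) -> "Msa":
        return Msa(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])


_AA = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}


def _blosum_array(matrix_name: str = "BLOSUM62") -> np.ndarray:
    m = substitution_matrices.load(matrix_name)
    out = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            out[i, j] = m[a, b]
    return out


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Per-column residue frequency vectors; gaps carry zero weight."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_AA)))
    for row in rows:
        for c, aa in enumerate(row):
            if aa != GAP:
                counts[c, _AA_INDEX.get(aa, _AA_INDEX["X"])] += 1
    return counts / len(rows)


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    score_matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Gotoh profile–profile alignment with expected sum-of-pairs column scores."""
    fa, fb = _profile_counts(rows_a), _profile_counts(rows_b)
    S = fa @ score_matrix @ fb.T  # column-pair scores
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            best = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best + Si[j - 1]
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
    # traceback, deterministic preference M > Ix > Iy
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            cols_a.append(i - 1)
            cols_b.append(None)
            from_open = M[i - 1, j] - gap_open
            state = 0 if from_open >= Ix[i - 1, j] - gap_extend else 1
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            from_open = M[i, j - 1] - gap_open
            state = 0 if from_open >= Iy[i, j - 1] - gap_extend else 2
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    out_a = ["".join(r[c] if c is not None else GAP for c in cols_a) for r in rows_a]
    out_b = ["".join(r[c] if c is not None else GAP for c in cols_b) for r in rows_b]
    return out_a, out_b


def progressive_msa(
    seqs: SequenceSet,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Msa:
    """Progressive multiple alignment over an NJ guide order.

    Pairwise identity distances (1 − identity) feed the Saitou–Nei
    Q-criterion; profiles are merged in guide order with expected
    sum-of-pairs BLOSUM scoring.  Deterministic: no randomness, ties by
    lowest index pair.
    """
    ids = seqs.ids()
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        log.warning("progressive_msa called with a single sequence")
        return Msa(ids, [seqs[ids[0]]])
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, ident, _ = pairwise_align(
                seqs[ids[i]], seqs[ids[j]], matrix_name, gap_open, gap_extend
            )
            dist[i, j] = dist[j, i] = 1.0 - ident
    score_matrix = _blosum_array(matrix_name)
    # active profiles: (member indices in original order, rows)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[ids[i]]]) for i in range(n)
    }
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def getd(a: int, b: int) -> float:
        return d[(a, b)] if a < b else d[(b, a)]

    while len(profiles) > 1:
        active = sorted(profiles)
        r = len(active)
        if r == 2:
            best_pair = (active[0], active[1])
        else:
            sums = {a: sum(getd(a, k) for k in active if k != a) for a in active}
            best_pair, best_q = None, math.inf
            for ai in range(r):
                for bi in range(ai + 1, r):
                    a, b = active[ai], active[bi]
                    q = (r - 2) * getd(a, b) - sums[a] - sums[b]
                    if q < best_q - 1e-12:
                        best_q, best_pair = q, (a, b)
        a, b = best_pair
        mem_a, rows_a = profiles.pop(a)
        mem_b, rows_b = profiles.pop(b)
        new_rows_a, new_rows_b = _align_profiles(
            rows_a, rows_b, score_matrix, gap_open, gap_extend
        )
        profiles[next_id] = (mem_a + mem_b, new_rows_a + new_rows_b)
        for k in list(profiles):
            if k != next_id:
                d[(min(k, next_id), max(k, next_id))] = 0.5 * (
                    getd(a, k) + getd(b, k) - getd(a, b)
                )
        next_id += 1

    members, rows = next(iter(profiles.values()))
    ordered = sorted(range(len(members)), key=lambda p: members[p])
    return Msa([ids[members[p]] for p in ordered], [rows[p] for p in ordered])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise ValueError("negative distances")
        self.matrix = m


def distance_matrix(
    msa: Msa, model: str = "poisson", gap_handling: str = "pairwise"
) -> DistanceMatrix:
    """p- or Poisson-corrected distances from an alignment.

    ``pairwise`` deletion drops gapped columns per pair; ``complete``
    drops any column gapped in any row.  Poisson: d = −ln(1 − p);
    saturated pairs (p = 1) get :data:`DISTANCE_CEILING` with a warning.
    """
    if len(msa.ids) < 2:
        raise ValueError("need >= 2 rows")
    arr = np.frombuffer("".join(msa.rows).encode(), dtype="S1").reshape(
        len(msa.rows), msa.n_cols
    )
    nongap = arr != b"-"
    if gap_handling == "complete":
        keep = nongap.all(axis=0)
        arr, nongap = arr[:, keep], nongap[:, keep]
    n = len(msa.ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                p = 1.0
            else:
                p = float((arr[i, both] != arr[j, both]).sum()) / compared
            if model == "p":
                dv = p
            elif model == "poisson":
                if p >= 1.0:
                    log.warning("saturated pair (%s, %s); distance set to ceiling", msa.ids[i], msa.ids[j])
                    dv = DISTANCE_CEILING
                else:
                    dv = -math.log(1.0 - p)
            else:
                raise ValueError(f"unknown model {model!r}")
            out[i, j] = out[j, i] = dv
    return DistanceMatrix(list(msa.ids), out)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    """Node of an (un)rooted phylogeny; children carry branch lengths."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6g}" for c, bl in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self) + ";"


class PhyloTree:
    """Unrooted NJ tree: a root node of degree ≥3 whose leaves are the taxa."""

    def __init__(self, root: TreeNode, ids: list[str]):
        self.root = root
        self.ids = list(ids)
        if sorted(root.leaf_names()) != sorted(ids):
            raise ValueError("leaf set does not match taxa")

    def newick(self) -> str:
        return self.root.newick()

    # -- edge/bipartition utilities -------------------------------------
    def _edges(self):
        """Yield (parent, child, length) over the rooted representation."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, bl in node.children:
                yield node, child, bl
                stack.append(child)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side lacking the
        lexicographically smallest taxon."""
        all_taxa = frozenset(self.ids)
        ref = min(all_taxa)
        out = set()
        n = len(all_taxa)
        for _, child, _ in self._edges():
            side = frozenset(child.leaf_names())
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def edge_lengths(self) -> dict[frozenset[str], float]:
        """Branch length per split (leaf pendant edges keyed by {leaf})."""
        all_taxa = frozenset(self.ids)
        ref = min(all_taxa)
        out: dict[frozenset[str], float] = {}
        for _, child, bl in self._edges():
            side = frozenset(child.leaf_names())
            if len(side) == 1 or len(side) == len(all_taxa) - 1:
                key = side if len(side) == 1 else all_taxa - side
            else:
                key = side if ref not in side else all_taxa - side
            out[key] = out.get(key, 0.0) + bl
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-criterion break to the lowest (i, j) node-index pair
    (creation order), negative branch lengths are clamped to zero with
    the deficit transferred to the sibling branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=t) for i, t in enumerate(dm.ids)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n

    def getd(a: int, b: int) -> float:
        return d[(a, b)] if a < b else d[(b, a)]

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {a: sum(getd(a, k) for k in active if k != a) for a in active}
        best, best_q = None, math.inf
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * getd(a, b) - sums[a] - sums[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = getd(a, b)
        la = 0.5 * dab + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[next_id] = parent
        for k in active:
            if k in (a, b):
                continue
            d[(min(k, next_id), max(k, next_id))] = max(
                0.0, 0.5 * (getd(a, k) + getd(b, k) - dab)
            )
        active = [k for k in active if k not in (a, b)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (getd(a, b) + getd(a, c) - getd(b, c))
    lb = 0.5 * (getd(a, b) + getd(b, c) - getd(a, c))
    lc = 0.5 * (getd(a, c) + getd(b, c) - getd(a, b))
    root = TreeNode(
        children=[
            (nodes[a], max(0.0, la)),
            (nodes[b], max(0.0, lb)),
            (nodes[c], max(0.0, lc)),
        ]
    )
    return PhyloTree(root, dm.ids)


def bootstrap_support(
    msa: Msa,
    n_reps: int,
    seed: int,
    model: str = "poisson",
    gap_handling: str = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Replicate r draws its columns from a stream derived from (seed, r),
    so supports are reproducible and independent of taxon input order.
    Support = percent of replicates containing each internal split of
    the full-data tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_tree(distance_matrix(msa, model, gap_handling))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    L = msa.n_cols
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, L, size=L)
        rep = msa.subset_columns(list(cols))
        try:
            rep_bps = nj_tree(distance_matrix(rep, model, gap_handling)).bipartitions()
        except ValueError:
            continue
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    # annotate internal nodes of the full tree
    all_taxa = frozenset(full.ids)
    ref = min(all_taxa)
    for _, child, _ in full._edges():
        if child.is_leaf:
            continue
        side = frozenset(child.leaf_names())
        key = side if ref not in side else all_taxa - side
        if key in counts:
            child.support = 100.0 * counts[key] / n_reps
    return full


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

GROUP_LABELS = list("ABCDEFGHIJKLS")


@dataclass
class GroupAssignment:
    labels: dict[str, str]
    flagged_ties: list[str] = field(default_factory=list)


def _adjacency(tree: PhyloTree) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {tree.root: []}
    for parent, child, bl in tree._edges():
        adj.setdefault(parent, []).append((child, bl))
        adj.setdefault(child, []).append((parent, bl))
    return adj


def assign_groups(
    tree: PhyloTree, reference_labels: Mapping[str, str]
) -> GroupAssignment:
    """Label query leaves from labeled reference leaves on the same tree.

    Each query gets the label of the smallest leaf set on its side of
    any edge whose references are non-empty and unanimously labeled;
    when no such clade exists, the nearest reference by path length
    decides (exact ties: lexicographically smaller label, flagged).
    """
    refs = {t: l for t, l in reference_labels.items() if t in set(tree.ids)}
    queries = [t for t in tree.ids if t not in refs]
    if not refs:
        log.warning("no reference leaves present; all queries unassigned")
        return GroupAssignment({q: "unassigned" for q in queries})

    # leaf sets per directed edge (child side), from the rooted representation
    sides: list[frozenset[str]] = []
    for _, child, _ in tree._edges():
        sides.append(frozenset(child.leaf_names()))
    all_taxa = frozenset(tree.ids)
    # deterministic scan order: smallest leaf sets first, lexicographic ties
    candidate_sides = sorted(
        set(sides) | {all_taxa - s for s in sides},
        key=lambda s: (len(s), tuple(sorted(s))),
    )

    # path distances between leaves
    adj = _adjacency(tree)
    leaf_nodes = {l.name: l for l in tree.root.leaves()}

    def distances_from(name: str) -> dict[str, float]:
        start = leaf_nodes[name]
        dist: dict[TreeNode, float] = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb, bl in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + bl
                    stack.append(nb)
        return {l: dv for l, dv in ((k.name, v) for k, v in dist.items() if k.is_leaf)}

    labels: dict[str, str] = dict(refs)
    flagged: list[str] = []
    for q in queries:
        # smallest unanimous clade around q; equal-size clades with
        # conflicting labels are ambiguous and fall to the distance rule
        best_label = None
        best_size = None
        ambiguous = False
        for side in candidate_sides:
            if q not in side:
                continue
            if best_size is not None and len(side) > best_size:
                break
            side_refs = {refs[t] for t in side if t in refs}
            if len(side_refs) != 1:
                continue
            label = next(iter(side_refs))
            if best_label is None:
                best_label, best_size = label, len(side)
            elif label != best_label:
                ambiguous = True
        if best_label is not None and not ambiguous:
            labels[q] = best_label
            continue
        dists = distances_from(q)
        ranked = sorted(
            ((dists[t], refs[t]) for t in refs if t in dists),
            key=lambda x: (x[0], x[1]),
        )
        labels[q] = ranked[0][1]
        if len(ranked) > 1 and math.isclose(ranked[0][0], ranked[1][0]) and ranked[0][1] != ranked[1][1]:
            flagged.append(q)
    return GroupAssignment({t: labels[t] for t in tree.ids}, flagged)
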