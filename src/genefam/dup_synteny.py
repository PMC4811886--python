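"""Homolog pairs, tandem/segmental duplication calls, synteny chaining,
and cross-species ortholog topology.

The positional logic works on gene *ordinals* (rank along a chromosome,
from :class:`~genefam.genome_io.ChromosomeMap`), not base-pair
coordinates — the convention of collinearity tools.  A tandem
duplication is a same-chromosome homolog pair with at most one
intervening gene; a segmental duplication is a homolog pair anchoring a
collinear block of at least ``min_anchors`` pairs (same-chromosome
blocks allowed).  Pairs meeting neither rule stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .align_phylo import alignment_coverage, pairwise_align
from .genome_io import UNANCHORED_CHROM, ChromosomeMap, SequenceSet


@dataclass(frozen=True)
class HomologPair:
    """Unordered homologous gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    identity: float = 1.0
    coverage_a: float = 1.0
    coverage_b: float = 1.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            ga, gb = self.gene_a, self.gene_b
            ca, cb = self.coverage_a, self.coverage_b
            object.__setattr__(self, "gene_a", gb)
            object.__setattr__(self, "gene_b", ga)
            object.__setattr__(self, "coverage_a", cb)
            object.__setattr__(self, "coverage_b", ca)
        for v in (self.identity, self.coverage_a, self.coverage_b):
            if not 0.0 <= v <= 1.0:
                raise ValueError("identity/coverage must lie in [0, 1]")

    @property
    def genes(self) -> tuple[str, str]:
        return self.gene_a, self.gene_b


@dataclass
class SyntenyBlock:
    """A chained run of collinear homolog pairs between two chromosomes."""

    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: list[HomologPair]
    orientation: str  # "same" | "inverted"
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class DuplicationCall:
    pair: HomologPair
    mode: str  # "tandem" | "segmental" | "unclassified"
    intervening: int | None = None
    block_id: int | None = None


def find_homolog_pairs(
    proteins: SequenceSet,
    min_identity: float = 0.40,
    min_coverage: float = 0.60,
    id_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[HomologPair]:
    """All-vs-all protein comparison; keeps pairs above identity and
    mutual-coverage thresholds.

    ``id_pairs`` restricts the comparison (e.g. to cross-genome pairs).
    """
    ids = proteins.ids()
    if id_pairs is None:
        if len(ids) < 2:
            raise ValueError("need >= 2 proteins")
        id_pairs = combinations(ids, 2)
    out = []
    for a, b in id_pairs:
        row_a, row_b, ident, score = pairwise_align(proteins[a], proteins[b])
        cov_a, cov_b = alignment_coverage(
            row_a, row_b, len(proteins[a]), len(proteins[b])
        )
        if ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
            out.append(
                HomologPair(a, b, identity=ident, coverage_a=cov_a,
                            coverage_b=cov_b, score=score)
            )
    return sorted(out, key=lambda p: p.genes)


def classify_tandem(
    pairs: Iterable[HomologPair], cmap: ChromosomeMap
) -> list[DuplicationCall]:
    """Apply the tandem rule: same chromosome, ≤1 intervening gene.

    Genes on the unanchored pseudo-chromosome never yield tandem calls.
    """
    calls = []
    for pair in pairs:
        for g in pair.genes:
            if g not in cmap:
                raise KeyError(f"gene {g!r} absent from chromosome map")
        ca, cb = cmap.chrom_of[pair.gene_a], cmap.chrom_of[pair.gene_b]
        if ca == cb and ca != UNANCHORED_CHROM:
            intervening = abs(cmap.ordinal[pair.gene_a] - cmap.ordinal[pair.gene_b]) - 1
            mode = "tandem" if intervening <= 1 else "unclassified"
            calls.append(DuplicationCall(pair, mode, intervening=intervening))
        else:
            calls.append(DuplicationCall(pair, "unclassified"))
    return calls


def _valid_chain(
    chain: Sequence[tuple[int, int]], ascending: bool, max_gap: int
) -> bool:
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        if a2 <= a1 or a2 - a1 > max_gap:
            return False
        if ascending and (b2 <= b1 or b2 - b1 > max_gap):
            return False
        if not ascending and (b2 >= b1 or b1 - b2 > max_gap):
            return False
    return True


def _best_chain(
    anchors: list[tuple[int, int, int]], ascending: bool, max_gap: int
) -> list[int]:
    """Max-anchor-count chain by DP over anchors sorted by (oa, ob).

    Returns indices into ``anchors``; ties go to the earlier anchor
    chain (stable DP).  O(n²).
    """
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k][0], anchors[k][1]))
    n = len(order)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        oa_i, ob_i, _ = anchors[order[i]]
        for j in range(i):
            oa_j, ob_j, _ = anchors[order[j]]
            if oa_i <= oa_j or oa_i - oa_j > max_gap:
                continue
            if ascending and not (ob_j < ob_i <= ob_j + max_gap):
                continue
            if not ascending and not (ob_i < ob_j <= ob_i + max_gap):
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -i))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def chain_anchors(
    pairs: Iterable[HomologPair],
    map_a: ChromosomeMap,
    map_b: ChromosomeMap | None = None,
    min_anchors: int = 3,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into collinear blocks per chromosome pair.

    Within a genome pass ``map_b=None``; the pair's two genes are then
    placed by their own ordinals (same-chromosome pairs oriented with
    the smaller ordinal on the A side).  Chains are scored by anchor
    count, both orientations tried, overlaps resolved greedily by score
    (each anchor ends up in at most one block); blocks below
    ``min_anchors`` are dropped.
    """
    same_genome = map_b is None
    if map_b is None:
        map_b = map_a
    # bucket anchors by (chrom_a, chrom_b)
    buckets: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for pair in pairs:
        ga, gb = pair.genes
        if not (ga in map_a and gb in map_b):
            if gb in map_a and ga in map_b:
                ga, gb = gb, ga  # cross-genome pair stored in the other order
            else:
                continue
        ca, cb = map_a.chrom_of[ga], map_b.chrom_of[gb]
        if UNANCHORED_CHROM in (ca, cb):
            continue
        oa, ob = map_a.ordinal[ga], map_b.ordinal[gb]
        if same_genome and (cb, ob) < (ca, oa):
            ca, cb, oa, ob = cb, ca, ob, oa
        buckets.setdefault((ca, cb), []).append((oa, ob, pair))

    blocks: list[SyntenyBlock] = []
    block_id = 0
    for (ca, cb) in sorted(buckets):
        remaining = sorted(buckets[(ca, cb)], key=lambda t: (t[0], t[1], t[2].genes))
        while True:
            anchors = [(oa, ob, i) for i, (oa, ob, _) in enumerate(remaining)]
            if len(anchors) < min_anchors:
                break
            best_idx: list[int] = []
            best_orient = "same"
            for ascending, orient in ((True, "same"), (False, "inverted")):
                idx = _best_chain(anchors, ascending, max_gap)
                if len(idx) > len(best_idx):
                    best_idx, best_orient = idx, orient
            if len(best_idx) < min_anchors:
                break
            chosen = [remaining[i] for i in best_idx]
            blocks.append(
                SyntenyBlock(
                    block_id=block_id,
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=[p for _, _, p in chosen],
                    orientation=best_orient,
                    score=float(len(chosen)),
                )
            )
            block_id += 1
            chosen_set = set(best_idx)
            remaining = [t for i, t in enumerate(remaining) if i not in chosen_set]
    return blocks


def classify_segmental(
    pairs: Iterable[HomologPair],
    blocks: Iterable[SyntenyBlock],
    tandem_calls: Iterable[DuplicationCall] | None = None,
) -> list[DuplicationCall]:
    """Final duplication-mode call per homolog pair.

    Tandem takes precedence; otherwise a pair anchoring any block is
    segmental (same-chromosome blocks included); the rest stay
    unclassified.
    """
    anchor_of: dict[tuple[str, str], int] = {}
    for block in blocks:
        for p in block.anchors:
            anchor_of.setdefault(p.genes, block.block_id)
    tandem_modes = {}
    if tandem_calls is not None:
        tandem_modes = {c.pair.genes: c for c in tandem_calls}
    out = []
    for pair in pairs:
        prior = tandem_modes.get(pair.genes)
        if prior is not None and prior.mode == "tandem":
            out.append(prior)
        elif pair.genes in anchor_of:
            out.append(
                DuplicationCall(pair, "segmental", block_id=anchor_of[pair.genes])
            )
        elif prior is not None:
            out.append(prior)
        else:
            out.append(DuplicationCall(pair, "unclassified"))
    return out


@dataclass
class OrthologTopology:
    """Degree pattern of cross-species syntenic pairs."""

    one_to_one: int = 0
    one_to_many: int = 0
    many_to_one: int = 0
    many_to_many: int = 0
    components: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "one_to_one": self.one_to_one,
            "one_to_many": self.one_to_many,
            "many_to_one": self.many_to_one,
            "many_to_many": self.many_to_many,
        }


def ortholog_topology(cross_pairs: Iterable[tuple[str, str]]) -> OrthologTopology:
    """Classify connected components of the bipartite (genome A, genome B)
    ortholog-pair graph by side sizes: 1:1, 1:many, many:1, many:many."""
    adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for a, b in cross_pairs:
        na, nb = ("A", a), ("B", b)
        adj.setdefault(na, set()).add(nb)
        adj.setdefault(nb, set()).add(na)
    topo = OrthologTopology()
    seen: set[tuple[str, str]] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        side_a = sorted(n for s, n in comp if s == "A")
        side_b = sorted(n for s, n in comp if s == "B")
        topo.components.append((side_a, side_b))
        if len(side_a) == 1 and len(side_b) == 1:
            topo.one_to_one += 1
        elif len(side_a) == 1:
            topo.one_to_many += 1
        elif len(side_b) == 1:
            topo.many_to_one += 1
        else:
            topo.many_to_many += 1
    return topo


def calls_table(calls: Iterable[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": c.pair.gene_a,
                "gene_b": c.pair.gene_b,
                "identity": round(c.pair.identity, 4),
                "mode": c.mode,
                "intervening": c.intervening,
                "block_id": c.block_id,
            }
            for c in calls
        ]
    )


def blocks_table(blocks: Iterable[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "orientation": b.orientation,
                "n_anchors": b.n_anchors,
                "anchors": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.anchors),
            }
            for b in blocks
        ]
    )


def circos_links(blocks: Iterable[SyntenyBlock], genes: dict[str, tuple[str, int, int]]) -> pd.DataFrame:
    """Two-region link rows (chrom, start, end per side) for external plotting.

    ``genes`` maps gene_id → (chromosome, start, end).
    """
    rows = []
    for b in blocks:
        coords_a = [genes[p.gene_a] for p in b.anchors]
        coords_b = [genes[p.gene_b] for p in b.anchors]
        rows.append(
            {
                "chrom_a": b.chrom_a,
                "start_a": min(c[1] for c in coords_a),
                "end_a": max(c[2] for c in coords_a),
                "chrom_b": b.chrom_b,
                "start_b": min(c[1] for c in coords_b),
                "end_b": max(c[2] for c in coords_b),
                "block_id": b.block_id,
            }
        )
    return pd.DataFrame(rows)
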