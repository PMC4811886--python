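"""bZIP domain scanner.

bZIP transcription factors carry a basic DNA-binding region with an
invariant asparagine followed seven residues later by an arginine or
lysine (N-x7-R/K), and, downstream, a leucine-zipper dimerization helix:
leucines (or other bulky hydrophobic residues) repeating every seven
positions.  The scanner anchors on the N-x7-R/K motif and then extends
the longest heptad run downstream; a protein is called a family member
("complete" domain) when the run reaches ``min_heptads`` leucine
periods.

This is a transparent, fully configurable pattern scan — not a
profile-HMM — so every call can be traced to explicit residue positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import SequenceSet


@dataclass(frozen=True)
class ScanConfig:
    """Tunables of the domain scan.

    min_heptads: leucine periods required for a complete zipper.
    hydrophobic_set: residues accepted at heptad positions besides L.
    max_mismatch_heptads: how many heptad positions may be non-leucine
        (but hydrophobic) within one run.
    zipper_search_window: residues downstream of the basic-region anchor
        in which a zipper may start.
    domain_len_bounds: soft annotation bounds (aa) on the basic-start →
        last-heptad span; out-of-bounds hits are flagged, not dropped.
    """

    min_heptads: int = 3
    hydrophobic_set: frozenset[str] = frozenset("IVMF")
    max_mismatch_heptads: int = 1
    zipper_search_window: int = 60
    domain_len_bounds: tuple[int, int] = (40, 80)

    def __post_init__(self) -> None:
        if self.min_heptads < 2:
            raise ValueError("min_heptads must be >= 2")
        if self.zipper_search_window <= 0:
            raise ValueError("zipper_search_window must be > 0")


@dataclass
class DomainHit:
    """Located bZIP domain: basic-region anchors plus the heptad run."""

    protein_id: str
    anchor_N_pos: int
    anchor_RK_pos: int
    zipper_positions: list[int]
    status: str  # "complete" | "incomplete"
    length_flag: bool = False  # span outside the expected 40-80 aa window

    def __post_init__(self) -> None:
        assert self.anchor_RK_pos == self.anchor_N_pos + 8
        for a, b in zip(self.zipper_positions, self.zipper_positions[1:]):
            assert b - a == 7, "heptad positions must be spaced by exactly 7"

    @property
    def n_heptads(self) -> int:
        return len(self.zipper_positions)

    @property
    def basic_start(self) -> int:
        return self.anchor_N_pos

    @property
    def basic_end(self) -> int:
        return self.anchor_RK_pos + 1


def find_basic_regions(protein: str) -> list[tuple[int, int]]:
    """All positions where protein[i] == 'N' and protein[i+8] in {R, K}.

    Overlapping hits are all reported, left to right.  'X' and gap
    characters never match.
    """
    hits = []
    for i in range(len(protein) - 8):
        if protein[i] == "N" and protein[i + 8] in ("R", "K"):
            hits.append((i, i + 8))
    return hits


def find_zipper(protein: str, from_pos: int, cfg: ScanConfig) -> list[int]:
    """Longest heptad (period-7) leucine run starting within the window.

    Each run position must hold L or a residue from ``hydrophobic_set``;
    at most ``max_mismatch_heptads`` positions per run may be non-L.
    Runs shorter than 2 are not reported.  Ties on length go to the
    earliest start.
    """
    if not 0 <= from_pos < len(protein):
        raise ValueError("from_pos out of range")
    best: list[int] = []
    upper = min(from_pos + cfg.zipper_search_window, len(protein))
    for start in range(from_pos, upper):
        run: list[int] = []
        mismatches = 0
        pos = start
        while pos < len(protein):
            aa = protein[pos]
            if aa == "L":
                run.append(pos)
            elif aa in cfg.hydrophobic_set and mismatches < cfg.max_mismatch_heptads:
                run.append(pos)
                mismatches += 1
            else:
                break
            pos += 7
        if len(run) > len(best):
            best = run
    return best if len(best) >= 2 else []


def scan_bzip(
    protein: str, cfg: ScanConfig = ScanConfig(), protein_id: str = ""
) -> DomainHit | None:
    """Scan one protein for a bZIP domain.

    For every basic-region anchor the zipper is sought downstream; the
    anchor maximizing the heptad count wins (ties: leftmost anchor).
    Returns None when no N-x7-R/K anchor exists; a hit with
    status="incomplete" when anchors exist but the best run is shorter
    than ``min_heptads``.
    """
    anchors = find_basic_regions(protein)
    if not anchors:
        return None
    best_anchor = anchors[0]
    best_run: list[int] = []
    for n_pos, rk_pos in anchors:
        run = find_zipper(protein, rk_pos + 1, cfg) if rk_pos + 1 < len(protein) else []
        if len(run) > len(best_run):
            best_run, best_anchor = run, (n_pos, rk_pos)
    status = "complete" if len(best_run) >= cfg.min_heptads else "incomplete"
    span = (best_run[-1] - best_anchor[0] + 1) if best_run else 0
    lo, hi = cfg.domain_len_bounds
    return DomainHit(
        protein_id=protein_id,
        anchor_N_pos=best_anchor[0],
        anchor_RK_pos=best_anchor[1],
        zipper_positions=best_run,
        status=status,
        length_flag=bool(best_run) and not (lo <= span <= hi),
    )


@dataclass
class FamilyRoster:
    """Survey result: complete-domain members plus an audit of near-misses."""

    members: list[DomainHit] = field(default_factory=list)
    incomplete: list[DomainHit] = field(default_factory=list)
    no_domain: list[str] = field(default_factory=list)

    def member_ids(self) -> list[str]:
        return [h.protein_id for h in self.members]


def survey_family(proteins: SequenceSet, cfg: ScanConfig = ScanConfig()) -> FamilyRoster:
    """Scan a proteome; the roster holds exactly the complete-domain proteins.

    Proteins with a basic region but a short (or no) zipper are kept in
    the ``incomplete`` audit list; proteins with no anchor in
    ``no_domain``.  Input iteration order is preserved, so the result is
    deterministic for a given set and config.
    """
    roster = FamilyRoster()
    for pid, seq in proteins.items():
        hit = scan_bzip(seq, cfg, protein_id=pid)
        if hit is None:
            roster.no_domain.append(pid)
        elif hit.status == "complete":
            roster.members.append(hit)
        else:
            roster.incomplete.append(hit)
    return roster
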