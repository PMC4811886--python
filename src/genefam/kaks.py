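"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction, plus
protein-guided codon back-translation.

NG86 counts, per codon, the fraction of the nine single-nucleotide
mutations that are synonymous (fractional site counts, s + n = 3), and
classifies observed codon differences by averaging synonymous /
nonsynonymous step counts over all mutational pathways between the two
codons, excluding pathways that pass through a stop codon (with
renormalization over the remaining ones).  Proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes–Cantor formula
d = −(3/4)·ln(1 − (4/3)p).  Ka/Ks < 1 indicates purifying selection,
= 1 neutral evolution, > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)
SENSE_CODONS = sorted(CODON_TABLE)

#: numerical tolerance for calling a ratio exactly neutral
NEUTRAL_TOL = 1e-9


class KaKsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# codon alignment (PAL2NAL semantics)
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Pair of codon-level rows; gaps are whole '---' codons."""

    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b) or len(self.row_a) % 3 != 0:
            raise KaKsError("codon rows must be equal length, divisible by 3")

    def codon_columns(self) -> list[tuple[str, str]]:
        return [
            (self.row_a[i : i + 3], self.row_b[i : i + 3])
            for i in range(0, len(self.row_a), 3)
        ]

    def ungapped_columns(self) -> list[tuple[str, str]]:
        """Codon columns with neither gaps nor ambiguous bases on either side."""
        ok = set(NUCLEOTIDES)
        return [
            (ca, cb)
            for ca, cb in self.codon_columns()
            if set(ca) <= ok and set(cb) <= ok
        ]


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def backtranslate(
    prot_row_a: str, prot_row_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Thread CDS codons onto an aligned protein pair (PAL2NAL semantics).

    Every aligned residue is replaced by its source codon; protein gaps
    become '---'.  Terminal stop codons are stripped before mapping.
    Raises :class:`KaKsError` naming the row and column on any
    translation mismatch or length inconsistency.
    """
    if len(prot_row_a) != len(prot_row_b):
        raise KaKsError("protein rows must have equal length")
    rows_out = []
    for label, prot_row, cds in (("a", prot_row_a, cds_a), ("b", prot_row_b, cds_b)):
        cds = _strip_terminal_stop(cds.upper())
        n_res = sum(1 for c in prot_row if c != "-")
        if len(cds) != 3 * n_res:
            raise KaKsError(
                f"row {label}: CDS length {len(cds)} != 3 x {n_res} residues"
            )
        out = []
        k = 0
        for col, aa in enumerate(prot_row):
            if aa == "-":
                out.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = CODON_TABLE.get(codon, "X")
            if trans != aa.upper():
                raise KaKsError(
                    f"row {label}, column {col}: codon {codon} translates to "
                    f"{trans}, protein says {aa}"
                )
            out.append(codon)
            k += 1
        rows_out.append("".join(out))
    return CodonAlignment(rows_out[0], rows_out[1])


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _is_synonymous(c1: str, c2: str) -> bool:
    return CODON_TABLE[c1] == CODON_TABLE[c2]


def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Over the nine single-nucleotide mutations: each position contributes
    the fraction of its three changes that are synonymous; changes to a
    stop codon count as nonsynonymous.  s + n = 3 exactly.
    """
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise KaKsError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _is_synonymous(codon, mutant):
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) differences between two codons.

    Averages step classifications over all orderings of the differing
    positions; pathways whose intermediate codons are stops are excluded
    and the average renormalized over the valid ones.  If every pathway
    is blocked (possible only via stop intermediates), all pathways are
    used.  Symmetric in its arguments.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in CODON_TABLE:
            raise KaKsError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:  # endpoint is sense, so this is an intermediate
                ok = False
                break
            if _is_synonymous(current, nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        (valid if ok else blocked).append((sd, nd))
    pool = valid if valid else [
        p for p in _all_pathways_counting_stops(codon_a, codon_b, diff_pos)
    ]
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def _all_pathways_counting_stops(codon_a, codon_b, diff_pos):
    """Fallback step counting that tolerates stop intermediates
    (classifying a step into/out of a stop as nonsynonymous)."""
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if (
                current in CODON_TABLE
                and nxt in CODON_TABLE
                and _is_synonymous(current, nxt)
            ):
                sd += 1
            else:
                nd += 1
            current = nxt
        yield sd, nd


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = −(3/4)·ln(1 − (4/3)p).

    Undefined (NaN) at p ≥ 0.75.
    """
    if p < 0:
        raise KaKsError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float
    Ks: float
    ratio: float  # NaN when undefined
    selection: str  # positive | neutral | purifying | undefined
    flags: list[str]


def classify_selection(ratio: float) -> str:
    """>1 positive, =1 (±1e−9) neutral, <1 purifying; NaN → undefined."""
    if ratio is None or math.isnan(ratio):
        return "undefined"
    if abs(ratio - 1.0) <= NEUTRAL_TOL:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


def kaks_pair(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks over one codon alignment.

    Gap/ambiguous codon columns are dropped pairwise.  Site totals are
    the mean of the two sequences' per-codon counts; differences are
    summed over columns.  Ks = 0 (or an out-of-range JC argument) leaves
    the ratio undefined with a flag.
    """
    cols = aln.ungapped_columns()
    if not cols:
        raise KaKsError("no ungapped codon columns")
    for ca, cb in cols:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise KaKsError("internal stop codon in alignment")
    S_a = N_a = S_b = N_b = Sd = Nd = 0.0
    for ca, cb in cols:
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = ng86_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = 0.5 * (S_a + S_b)
    N = 0.5 * (N_a + N_b)
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    Ks = jc_correct(pS) if not math.isnan(pS) else math.nan
    Ka = jc_correct(pN) if not math.isnan(pN) else math.nan
    flags = []
    if math.isnan(Ks):
        flags.append("Ks_undefined")
    if math.isnan(Ka):
        flags.append("Ka_undefined")
    if not math.isnan(Ks) and Ks == 0.0:
        flags.append("Ks_zero")
        ratio = math.nan
    elif math.isnan(Ks) or math.isnan(Ka):
        ratio = math.nan
    else:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ka=Ka, Ks=Ks,
        ratio=ratio, selection=classify_selection(ratio), flags=flags,
    )
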