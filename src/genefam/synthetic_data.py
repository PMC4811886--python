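"""Synthetic genomes with planted ground truth.

The generator emulates the inputs of a genome-wide transcription-factor
family survey at desk scale: multi-chromosome gene orders with planted
tandem pairs (at most one intervening gene) and segmental block copies,
family proteins carrying a real bZIP architecture (N-x7-R/K basic
region followed by a leucine heptad zipper), background genes that are
random ORFs guaranteed to lack a complete bZIP domain, exon/intron
structures with a controlled intronless fraction, coding pairs diverged
under a specified dN/dS, and replicated Ct tables with a constant
reference gene.

Everything is driven by a single integer seed; two runs with the same
spec produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_scan import ScanConfig, scan_bzip
from .genome_io import (
    UNANCHORED_CHROM,
    GeneModel,
    SequenceSet,
    reverse_complement,
    write_fasta,
)
from .kaks import CODON_TABLE, STOP_CODONS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


class SimError(ValueError):
    pass


@dataclass
class SimSpec:
    """Study conditions for one synthetic genome.

    Defaults are a desk-scale rendition of a plant TF-family survey:
    a handful of chromosomes, a family of ~10 members over five
    phylogenetic groups, an intronless share matching the 23/112 seen
    in the apple family, a few tandem events (0 or 1 intervening gene)
    and segmental blocks of ≥3 anchors, all diverged under purifying
    selection (ω = 0.2) at modest distance.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 25
    family_size: int = 10
    group_labels: tuple[str, ...] = ("A", "D", "F", "I", "S")
    intronless_fraction: float = 23.0 / 112.0
    within_group_divergence: float = 0.08
    tandem_events: tuple[tuple[str, int], ...] = (("chr1", 0), ("chr2", 1))
    segmental_events: tuple[tuple[str, str, int], ...] = (("chr1", "chr4", 4),)
    omega_per_pair: tuple[float, ...] = (0.2,)
    divergence_t: float = 0.3
    n_unanchored_family: int = 0
    group_seeds: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 4:
            raise SimError("need >= 1 chromosome with >= 4 genes")
        if self.family_size < 1:
            raise SimError("family_size must be positive")
        if any(o <= 0 for o in self.omega_per_pair):
            raise SimError("omega must be > 0")
        for chrom, intervening in self.tandem_events:
            if intervening not in (0, 1):
                raise SimError("planted tandem intervening count must be 0 or 1")
        for src, dst, size in self.segmental_events:
            if size > self.genes_per_chromosome:
                raise SimError(f"block of {size} larger than chromosome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    mode: str  # "tandem" | "segmental"
    omega: float
    family: bool


@dataclass
class TruthManifest:
    """What was planted, for end-to-end recovery checks."""

    family_ids: list[str]
    group_of: dict[str, str]
    intron_count: dict[str, int]
    duplication_pairs: list[PlantedPair]
    unanchored: list[str] = field(default_factory=list)
    ct_true_folds: dict[str, float] = field(default_factory=dict)

    def planted_modes(self, family_only: bool = False) -> dict[tuple[str, str], str]:
        out = {}
        for p in self.duplication_pairs:
            if family_only and not p.family:
                continue
            key = tuple(sorted((p.gene_a, p.gene_b)))
            out[key] = p.mode
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "family_ids": self.family_ids,
                    "group_of": self.group_of,
                    "intron_count": self.intron_count,
                    "duplication_pairs": [asdict(p) for p in self.duplication_pairs],
                    "unanchored": self.unanchored,
                    "ct_true_folds": self.ct_true_folds,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["duplication_pairs"] = [PlantedPair(**p) for p in d["duplication_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_decoy_protein(rng: np.random.Generator, cfg: ScanConfig) -> str:
    """Random ORF protein guaranteed not to carry a complete bZIP domain."""
    while True:
        p = _random_protein(rng, int(rng.integers(60, 101)))
        hit = scan_bzip(p, cfg)
        if hit is None or hit.status != "complete":
            return p


def make_bzip_seed_protein(rng: np.random.Generator, n_heptads: int = 5) -> str:
    """A protein with a planted basic region (N-x7-R/K) and leucine zipper.

    The N→last-leucine span lands inside the canonical 40–80 aa domain
    window (linker 6 aa, five heptads).
    """
    flank1 = _random_protein(rng, int(rng.integers(12, 21)))
    basic = "".join(rng.choice(list("KRKRE"), size=5))
    x7 = _random_protein(rng, 7).replace("N", "Q")
    anchor = "N" + x7 + str(rng.choice(["R", "K"]))
    linker = _random_protein(rng, 6).replace("L", "A")
    zipper = "".join(
        "L" + _random_protein(rng, 6).replace("L", "S") for _ in range(n_heptads)
    )
    flank2 = _random_protein(rng, int(rng.integers(15, 31)))
    return flank1 + basic + anchor + linker + zipper + flank2


def _domain_span(protein: str, cfg: ScanConfig | None = None) -> tuple[int, int]:
    """(start, end) protein positions of the planted domain (N anchor to last heptad)."""
    hit = scan_bzip(protein, cfg or ScanConfig())
    if hit is None or not hit.zipper_positions:
        raise SimError("protein lacks the planted domain")
    return hit.anchor_N_pos, hit.zipper_positions[-1]


def mutate_protein_outside(
    protein: str, rng: np.random.Generator, rate: float, keep: tuple[int, int]
) -> str:
    """Point-mutate a protein at ``rate`` per site, leaving ``keep`` untouched."""
    out = list(protein)
    lo, hi = keep
    for i in range(len(out)):
        if lo <= i <= hi:
            continue
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(out)


def backtranslate_random(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with uniformly random synonymous codons + TAA stop."""
    return "".join(
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))] for aa in protein
    ) + "TAA"


def evolve_codon_pair(
    cds: str,
    omega: float,
    t: float,
    seed: int | np.random.Generator,
    frozen_codons: frozenset[int] = frozenset(),
    allow_positive: bool = False,
) -> tuple[str, str]:
    """Duplicate an ancestral CDS and diverge both copies under dN/dS = ω.

    Mutation model: each branch receives a Poisson(t/2 per codon) number
    of proposed single-nucleotide changes at uniformly random positions;
    a proposal is accepted with probability 1 if synonymous and ω if
    nonsynonymous (ω ≤ 1), rejecting changes that create stop codons.
    ``t`` is thus the expected proposal density per codon site for the
    pair, and the realized substitution density scales with it.
    For ω > 1 the complementary scheme (accept nonsynonymous always,
    synonymous with probability 1/ω) must be enabled explicitly.
    """
    if omega <= 0:
        raise SimError("omega must be > 0")
    if omega > 1 and not allow_positive:
        raise SimError(
            "omega > 1 uses the complementary acceptance scheme; pass "
            "allow_positive=True to enable it"
        )
    if t < 0:
        raise SimError("t must be >= 0")
    cds = cds.upper()
    has_stop = len(cds) >= 3 and cds[-3:] in STOP_CODONS
    body = cds[:-3] if has_stop else cds
    if len(body) % 3 != 0 or any(
        body[i : i + 3] not in CODON_TABLE for i in range(0, len(body), 3)
    ):
        raise SimError("cds must be a sense-codon ORF")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_codons = len(body) // 3

    def branch(seq: list[str]) -> list[str]:
        n_prop = rng.poisson(0.5 * t * n_codons)
        for _ in range(n_prop):
            ci = int(rng.integers(n_codons))
            if ci in frozen_codons:
                continue
            codon = "".join(seq[3 * ci : 3 * ci + 3])
            pos = int(rng.integers(3))
            alts = [n for n in "ACGT" if n != codon[pos]]
            nt = alts[int(rng.integers(3))]
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            syn = CODON_TABLE[codon] == CODON_TABLE[mutant]
            if omega <= 1:
                accept = syn or rng.random() < omega
            else:
                accept = (not syn) or rng.random() < 1.0 / omega
            if accept:
                seq[3 * ci + pos] = nt
        return seq

    a = "".join(branch(list(body)))
    b = "".join(branch(list(body)))
    tail = cds[-3:] if has_stop else ""
    return a + tail, b + tail


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _GeneDraft:
    gene_id: str
    protein: str
    cds: str  # includes terminal stop
    is_family: bool
    group: str | None = None
    intronless: bool | None = None
    n_exons: int | None = None


@dataclass
class SyntheticGenome:
    """In-memory bundle: genome, annotation, sequences, and the truth."""

    genome: SequenceSet
    genes: list[GeneModel]
    proteins: SequenceSet
    cds: SequenceSet
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fna",
            "gff": outdir / "annotation.gff3",
            "proteins": outdir / "proteins.faa",
            "cds": outdir / "cds.fna",
            "manifest": outdir / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chromosome}\tgenefam_sim\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                mrna = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.chromosome}\tgenefam_sim\tmRNA\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chromosome}\tgenefam_sim\texon\t{s}\t{e}\t.\t"
                        f"{g.strand}\t.\tParent={mrna}\n"
                    )
                tx_order = (
                    g.cds_regions if g.strand == "+" else list(reversed(g.cds_regions))
                )
                cum = 0
                phases = {}
                for s, e in tx_order:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s + 1
                for s, e in g.cds_regions:
                    fh.write(
                        f"{g.chromosome}\tgenefam_sim\tCDS\t{s}\t{e}\t.\t"
                        f"{g.strand}\t{phases[(s, e)]}\tParent={mrna}\n"
                    )
        self.manifest.to_json(paths["manifest"])
        return paths


def _split_lengths(total: int, n_parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` bp into n_parts pieces of >= 6 bp each."""
    if n_parts == 1 or total < 6 * n_parts:
        return [total]
    extra = rng.multinomial(total - 6 * n_parts, [1.0 / n_parts] * n_parts)
    return [6 + int(e) for e in extra]


def generate_genome(spec: SimSpec) -> SyntheticGenome:
    """Realize a :class:`SimSpec` into genome + annotation + truth.

    Deterministic for a given spec (all draws flow from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    cfg = ScanConfig()
    chroms = spec.chrom_names()
    labels = list(spec.group_labels)

    # --- group seed proteins -------------------------------------------
    if spec.group_seeds is not None:
        seeds = dict(spec.group_seeds)
    else:
        seeds = {lab: make_bzip_seed_protein(rng) for lab in labels}
    for lab, p in seeds.items():
        hit = scan_bzip(p, cfg)
        if hit is None or hit.status != "complete":
            raise SimError(f"group seed {lab!r} lacks a complete bZIP domain")

    # --- family founders -------------------------------------------------
    founders: list[_GeneDraft] = []
    n_anchored = spec.family_size - spec.n_unanchored_family
    if n_anchored < 0:
        raise SimError("n_unanchored_family exceeds family_size")
    n_intronless = round(spec.intronless_fraction * spec.family_size)
    for k in range(spec.family_size):
        lab = labels[k % len(labels)]
        seed_prot = seeds[lab]
        span = _domain_span(seed_prot, cfg)
        prot = mutate_protein_outside(
            seed_prot, rng, spec.within_group_divergence, span
        )
        founders.append(
            _GeneDraft(
                gene_id=f"fam{k:03d}",
                protein=prot,
                cds=backtranslate_random(prot, rng),
                is_family=True,
                group=lab,
                intronless=k < n_intronless,
            )
        )
    # shuffle which founders are intronless (deterministically)
    perm = rng.permutation(len(founders))
    flags = [founders[int(p)].intronless for p in perm]
    for f, flag in zip(founders, flags):
        f.intronless = flag
        f.n_exons = 1 if flag else int(rng.integers(2, 6))

    # --- chromosome gene orders ------------------------------------------
    per_chrom: dict[str, list[_GeneDraft]] = {c: [] for c in chroms}
    bg_counter = 0
    for ci, chrom in enumerate(chroms):
        for _ in range(spec.genes_per_chromosome):
            prot = _random_decoy_protein(rng, cfg)
            per_chrom[chrom].append(
                _GeneDraft(
                    gene_id=f"bg{bg_counter:04d}",
                    protein=prot,
                    cds=backtranslate_random(prot, rng),
                    is_family=False,
                    n_exons=int(rng.integers(1, 5)),
                )
            )
            bg_counter += 1
    # spread anchored founders over interior slots, >= 3 background genes apart
    anchored = founders[:n_anchored]
    by_chrom_count: dict[str, int] = {c: 0 for c in chroms}
    for i, f in enumerate(anchored):
        by_chrom_count[chroms[i % len(chroms)]] += 1
    idx = 0
    for chrom in chroms:
        k = by_chrom_count[chrom]
        if k == 0:
            continue
        n_bg = len(per_chrom[chrom])
        # interior, evenly spaced insertion slots (ascending so later
        # insertions do not disturb earlier ones)
        slots = [2 + round(j * (n_bg - 4) / max(k - 1, 1)) for j in range(k)]
        slots = sorted(set(slots))
        while len(slots) < k:  # tiny chromosomes: fall back to consecutive slots
            slots.append(slots[-1] + 4)
        for off, slot in enumerate(sorted(slots, reverse=True)):
            per_chrom[chrom].insert(min(slot, len(per_chrom[chrom])), anchored[idx + k - 1 - off])
        idx += k

    # --- planted duplications --------------------------------------------
    manifest_pairs: list[PlantedPair] = []
    omega_cycle = list(spec.omega_per_pair)
    omega_i = 0

    def next_omega() -> float:
        nonlocal omega_i
        o = omega_cycle[omega_i % len(omega_cycle)]
        omega_i += 1
        return o

    def diverge_copy(src: _GeneDraft, copy_id: str, omega: float) -> _GeneDraft:
        frozen: frozenset[int] = frozenset()
        if src.is_family:
            lo, hi = _domain_span(src.protein, cfg)
            frozen = frozenset(range(lo, hi + 1))
        _, evolved = evolve_codon_pair(
            src.cds, omega, spec.divergence_t, rng, frozen_codons=frozen
        )
        body = evolved[:-3]
        prot = "".join(CODON_TABLE[body[i : i + 3]] for i in range(0, len(body), 3))
        return _GeneDraft(
            gene_id=copy_id,
            protein=prot,
            cds=evolved,
            is_family=src.is_family,
            group=src.group,
            intronless=src.intronless,
            n_exons=src.n_exons,
        )

    tandem_rotation: dict[str, int] = {}
    for chrom, intervening in spec.tandem_events:
        fam_here = [g for g in per_chrom[chrom] if g.is_family]
        if not fam_here:
            raise SimError(f"no family gene on {chrom} for a tandem event")
        pick = tandem_rotation.get(chrom, 0) % len(fam_here)
        tandem_rotation[chrom] = pick + 1
        src = fam_here[pick]
        omega = next_omega()
        copy = diverge_copy(src, src.gene_id + "td", omega)
        pos = per_chrom[chrom].index(src)
        insert_at = min(pos + 1 + intervening, len(per_chrom[chrom]))
        if insert_at - pos - 1 < intervening:
            raise SimError(f"not enough genes after {src.gene_id} on {chrom}")
        per_chrom[chrom].insert(insert_at, copy)
        manifest_pairs.append(
            PlantedPair(src.gene_id, copy.gene_id, "tandem", omega, True)
        )

    # genes already involved in a duplication event; segmental windows avoid
    # them so every homologous pair maps to exactly one planted event
    involved = {p for pr in manifest_pairs for p in (pr.gene_a, pr.gene_b)}
    for ev_i, (src_chrom, dst_chrom, size) in enumerate(spec.segmental_events):
        order = per_chrom[src_chrom]
        window = None
        for start in range(0, len(order) - size + 1):
            cand = order[start : start + size]
            if not any(g.is_family for g in cand):
                continue
            if any(g.gene_id in involved for g in cand):
                continue
            window = cand
            break
        if window is None:
            raise SimError(
                f"no clean {size}-gene window with a family gene on {src_chrom}"
            )
        omega = next_omega()
        copies = []
        for g in window:
            copy = diverge_copy(g, f"{g.gene_id}sg{ev_i}", omega)
            copies.append(copy)
            manifest_pairs.append(
                PlantedPair(g.gene_id, copy.gene_id, "segmental", omega, g.is_family)
            )
            involved.update((g.gene_id, copy.gene_id))
        per_chrom[dst_chrom].extend(copies)

    # --- unanchored family genes ------------------------------------------
    unanchored = founders[n_anchored:]
    if unanchored:
        per_chrom[UNANCHORED_CHROM] = list(unanchored)

    # --- realize sequences & coordinates ----------------------------------
    genome_seqs: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_seqs: dict[str, str] = {}
    intron_count: dict[str, int] = {}
    for chrom, drafts in per_chrom.items():
        pieces: list[str] = []
        cursor = 0
        for draft in drafts:
            spacer_len = int(rng.integers(100, 301))
            pieces.append("".join(rng.choice(list("ACGT"), size=spacer_len)))
            cursor += spacer_len
            n_ex = draft.n_exons or 1
            strand = "+" if rng.random() < 0.5 else "-"
            genomic_cds = (
                draft.cds if strand == "+" else reverse_complement(draft.cds)
            )
            ex_lens = _split_lengths(len(genomic_cds), n_ex, rng)
            exons = []
            gpos = cursor + 1  # 1-based
            off = 0
            for j, ln in enumerate(ex_lens):
                exons.append((gpos, gpos + ln - 1))
                pieces.append(genomic_cds[off : off + ln])
                off += ln
                gpos += ln
                if j < len(ex_lens) - 1:
                    intron_len = int(rng.integers(50, 151))
                    pieces.append(
                        "".join(rng.choice(list("ACGT"), size=intron_len))
                    )
                    gpos += intron_len
            cursor = gpos - 1
            gene_models.append(
                GeneModel(
                    gene_id=draft.gene_id,
                    chromosome=chrom,
                    strand=strand,
                    start=exons[0][0],
                    end=exons[-1][1],
                    exons=exons,
                    cds_regions=list(exons),
                    cds_seq=draft.cds,
                )
            )
            proteins[draft.gene_id] = draft.protein
            cds_seqs[draft.gene_id] = draft.cds
            if draft.is_family:
                intron_count[draft.gene_id] = len(exons) - 1
        genome_seqs[chrom] = "".join(pieces)

    family_ids = sorted(intron_count)
    group_of = {}
    for drafts in per_chrom.values():
        for d in drafts:
            if d.is_family:
                group_of[d.gene_id] = d.group
    manifest = TruthManifest(
        family_ids=family_ids,
        group_of=group_of,
        intron_count=intron_count,
        duplication_pairs=manifest_pairs,
        unanchored=[g.gene_id for g in unanchored],
    )
    return SyntheticGenome(
        genome=SequenceSet(genome_seqs, alphabet="dna"),
        genes=gene_models,
        proteins=SequenceSet(proteins, alphabet="protein"),
        cds=SequenceSet(cds_seqs, alphabet="dna"),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    true_folds: Mapping[str, float],
    noise_sd: float,
    n_reps: int,
    seed: int,
    reference_gene: str = "EF1a",
    control: str = "control",
    treated: str = "treated",
    base_ct: float = 20.0,
    ref_ct: float = 15.0,
) -> pd.DataFrame:
    """Long-format Ct table realizing given treated/control fold changes.

    The reference gene is constant across samples; each target's treated
    Ct is offset by −log2(fold) plus Gaussian noise per replicate.
    """
    if n_reps < 2:
        raise SimError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        for sample in (control, treated):
            rows.append(
                {"gene": reference_gene, "sample": sample, "replicate": rep,
                 "ct": ref_ct}
            )
    for gene, fold in sorted(true_folds.items()):
        if fold <= 0:
            raise SimError("fold changes must be positive")
        for rep in range(1, n_reps + 1):
            rows.append(
                {"gene": gene, "sample": control, "replicate": rep,
                 "ct": base_ct + rng.normal(0.0, noise_sd)}
            )
        for rep in range(1, n_reps + 1):
            rows.append(
                {"gene": gene, "sample": treated, "replicate": rep,
                 "ct": base_ct - math.log2(fold) + rng.normal(0.0, noise_sd)}
            )
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
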