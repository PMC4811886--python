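"""Genome I/O and the positional gene-order model.

Reads FASTA and GFF3 into :class:`SequenceSet` and :class:`GeneModel`
objects and builds the per-chromosome gene-order index
(:class:`ChromosomeMap`) that every positional analysis downstream
(tandem calls, synteny chaining, chromosome distribution) consumes.

Coordinates follow GFF3 conventions: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: chromosome name reserved for genes that could not be anchored to a
#: chromosome; excluded from tandem/synteny calls, reported separately
#: in distribution tables.
UNANCHORED_CHROM = "chrUn"


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF input or inconsistent gene model."""


@dataclass
class GeneModel:
    """One gene: location, strand, ordered exons and (optionally) its CDS.

    ``exons`` are 1-based inclusive ``(start, end)`` pairs, pairwise
    disjoint and sorted in genomic order.  ``cds_regions``, when the
    annotation provides CDS features, hold the coding segments in the
    same convention and are preferred for intron statistics.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_regions: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise GenomeIOError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise GenomeIOError(f"{self.gene_id}: exon start > end")
            if s < self.start or e > self.end:
                raise GenomeIOError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene bounds "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise GenomeIOError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceSet:
    """Unique-id sequence collection with an alphabet tag ('dna'/'protein')."""

    sequences: dict[str, str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise GenomeIOError(f"empty sequence for id {sid!r}")

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class ChromosomeMap:
    """Gene order per chromosome: ordinal rank (0-based) along each chromosome."""

    order: dict[str, list[str]]
    ordinal: dict[str, int]
    chrom_of: dict[str, str]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ordinal

    def genes_on(self, chromosome: str) -> list[str]:
        return self.order.get(chromosome, [])


def read_fasta(path: str | Path, alphabet: str = "dna") -> SequenceSet:
    """Read FASTA; ids are the first whitespace token, sequence upper-cased.

    Raises :class:`GenomeIOError` on duplicate ids or empty records.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise GenomeIOError(f"duplicate FASTA id: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeIOError(f"empty FASTA record: {rec.id!r}")
        seqs[rec.id] = seq
    return SequenceSet(seqs, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _pick_transcript(db: gffutils.FeatureDB, gene) -> tuple[list, list]:
    """Return (exons, cds) of the transcript with the longest summed CDS.

    Falls back to summed exon length when no transcript has CDS features;
    exons attached directly to the gene are used when there is no mRNA.
    """
    mrnas = list(db.children(gene, featuretype="mRNA"))
    if not mrnas:
        exons = list(db.children(gene, featuretype="exon"))
        cds = list(db.children(gene, featuretype="CDS"))
        return exons, cds

    def key(m):
        cds_len = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
        exon_len = sum(e.end - e.start + 1 for e in db.children(m, featuretype="exon"))
        return (cds_len, exon_len)

    best = max(mrnas, key=key)
    return (
        list(db.children(best, featuretype="exon")),
        list(db.children(best, featuretype="CDS")),
    )


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 into :class:`GeneModel` objects.

    Only gene/mRNA/exon/CDS features are consumed; other feature types are
    ignored with a log line.  A gene with several mRNAs collapses to the
    transcript with the longest summed CDS.  Exons outside gene bounds and
    exon/CDS features with an unknown Parent raise :class:`GenomeIOError`.
    """
    known = {"gene", "mRNA", "exon", "CDS"}
    seen_types: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ftype = line.split("\t")[2]
            if ftype not in known:
                seen_types.add(ftype)
    if seen_types:
        log.info("ignoring GFF feature types: %s", ", ".join(sorted(seen_types)))

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    # detect orphan Parent references early
    gene_ids = {g.id for g in db.features_of_type("gene")}
    mrna_ids = {m.id for m in db.features_of_type("mRNA")}
    for ftype in ("mRNA", "exon", "CDS"):
        for feat in db.features_of_type(ftype):
            for parent in feat.attributes.get("Parent", []):
                if parent not in gene_ids and parent not in mrna_ids:
                    raise GenomeIOError(
                        f"{ftype} {feat.id or '?'} references unknown Parent "
                        f"{parent!r}"
                    )

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exon_feats, cds_feats = _pick_transcript(db, g)
        exons = sorted((f.start, f.end) for f in exon_feats)
        cds = sorted((f.start, f.end) for f in cds_feats)
        if not exons:
            exons = cds if cds else [(g.start, g.end)]
        for s, e in exons:
            if s < g.start or e > g.end:
                raise GenomeIOError(
                    f"gene {g.id}: exon ({s},{e}) outside gene bounds "
                    f"({g.start},{g.end})"
                )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=g.start,
                end=g.end,
                exons=exons,
                cds_regions=cds,
            )
        )
    return genes


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(gene: GeneModel, genome: SequenceSet, use_cds: bool = True) -> str:
    """Concatenate a gene's coding segments from the genome sequence.

    Uses ``cds_regions`` when present (and ``use_cds``), else exons.
    Reverse-complemented for '-' strand genes so the result reads 5'→3'
    in transcript orientation.
    """
    if gene.chromosome not in genome:
        raise GenomeIOError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome")
    chrom_seq = genome[gene.chromosome]
    parts = gene.cds_regions if (use_cds and gene.cds_regions) else gene.exons
    pieces = []
    for s, e in sorted(parts):
        if e > len(chrom_seq) or s < 1:
            raise GenomeIOError(
                f"{gene.gene_id}: segment ({s},{e}) beyond chromosome "
                f"{gene.chromosome} length {len(chrom_seq)}"
            )
        pieces.append(chrom_seq[s - 1 : e])
    seq = "".join(pieces)
    return reverse_complement(seq) if gene.strand == "-" else seq


class InternalStopError(GenomeIOError):
    """CDS contains a premature stop codon."""


def translate(cds: str, truncate_at_stop: bool = False) -> str:
    """Translate a CDS with the standard code; strips one trailing stop.

    An internal stop raises :class:`InternalStopError` unless
    ``truncate_at_stop`` is set, in which case translation stops there.
    """
    if len(cds) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        if truncate_at_stop:
            return prot[: prot.index("*")]
        raise InternalStopError(
            f"internal stop codon at protein position {prot.index('*')}"
        )
    return prot


def build_chromosome_map(genes: Iterable[GeneModel]) -> ChromosomeMap:
    """Rank genes along each chromosome by (start, gene_id); 0-based ordinals."""
    by_chrom: dict[str, list[GeneModel]] = {}
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise GenomeIOError(f"duplicate gene id: {g.gene_id!r}")
        seen.add(g.gene_id)
        by_chrom.setdefault(g.chromosome, []).append(g)
    order: dict[str, list[str]] = {}
    ordinal: dict[str, int] = {}
    chrom_of: dict[str, str] = {}
    for chrom in sorted(by_chrom):
        ranked = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        order[chrom] = [g.gene_id for g in ranked]
        for i, g in enumerate(ranked):
            ordinal[g.gene_id] = i
            chrom_of[g.gene_id] = chrom
    return ChromosomeMap(order=order, ordinal=ordinal, chrom_of=chrom_of)


def round_half_up(x: float) -> int:
    """Round with ties away from zero upward (10.5 → 11), as in integer-percent tables."""
    import math

    return int(math.floor(x + 0.5))


def chromosome_distribution(
    cmap: ChromosomeMap, family: set[str] | Sequence[str]
) -> pd.DataFrame:
    """Per-chromosome counts and integer percents of a gene family.

    Genes on the reserved unanchored pseudo-chromosome, or absent from the
    map entirely, are reported under the ``"unanchored"`` key.  Percents are
    100·count/|family| rounded half-up.
    """
    family = set(family)
    if not family:
        raise GenomeIOError("empty family")
    counts: dict[str, int] = {}
    for gid in family:
        chrom = cmap.chrom_of.get(gid, UNANCHORED_CHROM)
        key = "unanchored" if chrom == UNANCHORED_CHROM else chrom
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "chromosome": chrom,
            "count": n,
            "percent": round_half_up(100.0 * n / len(family)),
        }
        for chrom, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chromosome", "count", "percent"])
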