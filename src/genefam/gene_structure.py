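"""Exon/intron structure statistics.

Intron counts are taken from the coding part of the gene model (CDS
segments) when the annotation provides them, falling back to exons
otherwise; each record notes which source was used.  Introns are the
gaps between consecutive non-overlapping segments, so for segments
(s1,e1),(s2,e2) the intron length is s2 − e1 − 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genome_io import GeneModel, round_half_up


class StructureError(ValueError):
    pass


@dataclass
class StructureRecord:
    gene_id: str
    n_exons: int
    n_introns: int
    intron_lengths: list[int]
    intronless: bool
    source: str = "exon"  # "cds" when CDS segments were used

    def __post_init__(self) -> None:
        assert self.n_introns == self.n_exons - 1
        assert self.intronless == (self.n_introns == 0)


def count_introns(gene: GeneModel) -> StructureRecord:
    """Intron count and lengths for one gene model."""
    if gene.cds_regions:
        parts, source = sorted(gene.cds_regions), "cds"
    else:
        parts, source = sorted(gene.exons), "exon"
    if not parts:
        raise StructureError(f"{gene.gene_id}: no exons")
    lengths = []
    for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
        if s2 <= e1:
            raise StructureError(f"{gene.gene_id}: overlapping segments")
        lengths.append(s2 - e1 - 1)
    return StructureRecord(
        gene_id=gene.gene_id,
        n_exons=len(parts),
        n_introns=len(parts) - 1,
        intron_lengths=lengths,
        intronless=len(parts) == 1,
        source=source,
    )


def intronless_fraction(records: Iterable[StructureRecord]) -> tuple[int, int]:
    """(count, integer percent) of intronless genes; percent rounds half-up."""
    records = list(records)
    if not records:
        raise StructureError("no structure records")
    count = sum(r.intronless for r in records)
    return count, round_half_up(100.0 * count / len(records))


def group_intron_range(
    records: Iterable[StructureRecord], group_map: Mapping[str, str]
) -> dict[str, tuple[int, int]]:
    """Per-group (min, max) of intron counts; every gene must be mapped."""
    ranges: dict[str, tuple[int, int]] = {}
    for r in records:
        if r.gene_id not in group_map:
            raise StructureError(f"gene {r.gene_id} missing from group map")
        g = group_map[r.gene_id]
        if g in ranges:
            lo, hi = ranges[g]
            ranges[g] = (min(lo, r.n_introns), max(hi, r.n_introns))
        else:
            ranges[g] = (r.n_introns, r.n_introns)
    return ranges


def structure_table(records: Iterable[StructureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_exons": r.n_exons,
                "n_introns": r.n_introns,
                "intronless": r.intronless,
                "source": r.source,
            }
            for r in records
        ]
    )
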