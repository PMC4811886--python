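"""End-to-end survey orchestration.

``run_survey`` chains the full workflow — family identification,
chromosome distribution, gene structure, phylogeny and group labels,
duplication and synteny classification, Ka/Ks selection inference, and
(optionally) cross-species ortholog topology and qPCR quantification —
and writes one table per stage plus a reproducibility manifest.
Every stage is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align_phylo import (
    assign_groups,
    bootstrap_support,
    pairwise_align,
    progressive_msa,
)
from .domain_scan import ScanConfig, survey_family
from .dup_synteny import (
    blocks_table,
    calls_table,
    chain_anchors,
    circos_links,
    classify_segmental,
    classify_tandem,
    find_homolog_pairs,
    ortholog_topology,
)
from .expression_quant import CtTable, expression_table
from .gene_structure import count_introns, intronless_fraction, structure_table
from .genome_io import (
    SequenceSet,
    build_chromosome_map,
    chromosome_distribution,
    extract_cds,
    read_fasta,
    read_gff,
    translate,
)
from .kaks import backtranslate, kaks_pair

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class GenomeInput:
    genome_fasta: str
    gff: str
    proteins_fasta: str | None = None  # derived from the genome when absent
    cds_fasta: str | None = None


@dataclass
class PipelineConfig:
    genome_a: GenomeInput
    genome_b: GenomeInput | None = None
    reference_proteins_fasta: str | None = None
    reference_labels_tsv: str | None = None  # columns: id, group
    ct_table_tsv: str | None = None
    ct_reference_gene: str = "EF1a"
    ct_control_sample: str = "control"
    ct_treated_sample: str = "treated"
    min_heptads: int = 3
    min_identity: float = 0.40
    min_coverage: float = 0.60
    min_anchors: int = 3
    max_gap: int = 25
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    seed: int = 17
    outdir: str = "survey_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genome_a"] = GenomeInput(**raw["genome_a"])
        if raw.get("genome_b"):
            raw["genome_b"] = GenomeInput(**raw["genome_b"])
        return cls(**raw)

    def validate(self) -> None:
        inputs = [self.genome_a] + ([self.genome_b] if self.genome_b else [])
        for gi in inputs:
            for p in (gi.genome_fasta, gi.gff, gi.proteins_fasta, gi.cds_fasta):
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"configuration: missing input file {p!r}")
        for p in (
            self.reference_proteins_fasta,
            self.reference_labels_tsv,
            self.ct_table_tsv,
        ):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configuration: missing input file {p!r}")


@dataclass
class GenomeData:
    genes: list
    cmap: object
    proteins: SequenceSet
    cds: SequenceSet


def _load_genome(gi: GenomeInput, stage: str) -> GenomeData:
    try:
        genome = read_fasta(gi.genome_fasta)
        genes = read_gff(gi.gff)
        cmap = build_chromosome_map(genes)
        if gi.cds_fasta:
            cds = read_fasta(gi.cds_fasta)
        else:
            cds = SequenceSet(
                {g.gene_id: extract_cds(g, genome) for g in genes}, alphabet="dna"
            )
        if gi.proteins_fasta:
            proteins = read_fasta(gi.proteins_fasta, alphabet="protein")
        else:
            proteins = SequenceSet(
                {gid: translate(s) for gid, s in cds.items()}, alphabet="protein"
            )
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(f"stage {stage}: {exc}") from exc
    return GenomeData(genes=genes, cmap=cmap, proteins=proteins, cds=cds)


def run_survey(cfg: PipelineConfig) -> dict:
    """Run the whole survey; returns the report bundle as a dict of
    DataFrames/objects and writes TSV/Newick/JSON files under
    ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    gen_a = _load_genome(cfg.genome_a, "load_genome_a")
    scan_cfg = ScanConfig(min_heptads=cfg.min_heptads)

    # --- family identification -----------------------------------------
    roster = survey_family(gen_a.proteins, scan_cfg)
    family = roster.member_ids()
    gene_by_id = {g.gene_id: g for g in gen_a.genes}
    roster_df = pd.DataFrame(
        [
            {
                "gene_id": h.protein_id,
                "chromosome": gene_by_id[h.protein_id].chromosome
                if h.protein_id in gene_by_id
                else "NA",
                "basic_start": h.basic_start,
                "anchor_N": h.anchor_N_pos,
                "anchor_RK": h.anchor_RK_pos,
                "n_heptads": h.n_heptads,
                "status": h.status,
                "cds_length": len(gen_a.cds[h.protein_id])
                if h.protein_id in gen_a.cds
                else None,
                "protein_length": len(gen_a.proteins[h.protein_id]),
            }
            for h in roster.members
        ]
    )
    report["roster"] = roster_df
    report["n_family"] = len(family)
    report["n_incomplete"] = len(roster.incomplete)
    report["n_no_domain"] = len(roster.no_domain)
    roster_df.to_csv(outdir / "family_roster.tsv", sep="\t", index=False)

    if not family:
        raise PipelineError("stage survey: no family members found")

    # --- chromosome distribution -----------------------------------------
    dist = chromosome_distribution(gen_a.cmap, set(family))
    report["chromosome_distribution"] = dist
    dist.to_csv(outdir / "chromosome_distribution.tsv", sep="\t", index=False)

    # --- gene structure -----------------------------------------------
    records = [count_introns(gene_by_id[g]) for g in family if g in gene_by_id]
    count, pct = intronless_fraction(records)
    report["structure"] = structure_table(records)
    report["intronless"] = {"count": count, "percent": pct, "n": len(records)}
    report["structure"].to_csv(outdir / "gene_structure.tsv", sep="\t", index=False)

    # --- phylogeny + groups -----------------------------------------------
    ref_labels: dict[str, str] = {}
    phylo_seqs = {g: gen_a.proteins[g] for g in family}
    if cfg.reference_proteins_fasta and cfg.reference_labels_tsv:
        refs = read_fasta(cfg.reference_proteins_fasta, alphabet="protein")
        lab = pd.read_csv(cfg.reference_labels_tsv, sep="\t")
        ref_labels = dict(zip(lab["id"], lab["group"]))
        phylo_seqs.update({k: v for k, v in refs.items()})
    if len(phylo_seqs) >= 3:
        msa = progressive_msa(SequenceSet(phylo_seqs, alphabet="protein"))
        tree = bootstrap_support(
            msa, cfg.bootstrap_reps, cfg.seed, model=cfg.distance_model
        )
        (outdir / "family_tree.nwk").write_text(tree.newick() + "\n")
        report["tree"] = tree
        if ref_labels:
            groups = assign_groups(tree, ref_labels)
            group_df = pd.DataFrame(
                [
                    {"gene_id": g, "group": groups.labels[g]}
                    for g in family
                    if g in groups.labels
                ]
            )
            report["groups"] = group_df
            group_df.to_csv(outdir / "group_assignments.tsv", sep="\t", index=False)

    # --- duplications & synteny (within genome A) ----------------------
    pairs = find_homolog_pairs(
        gen_a.proteins, min_identity=cfg.min_identity, min_coverage=cfg.min_coverage
    )
    tandem_calls = classify_tandem(pairs, gen_a.cmap)
    blocks = chain_anchors(
        pairs, gen_a.cmap, None, min_anchors=cfg.min_anchors, max_gap=cfg.max_gap
    )
    calls = classify_segmental(pairs, blocks, tandem_calls)
    fam_set = set(family)
    family_calls = [
        c for c in calls if c.pair.gene_a in fam_set or c.pair.gene_b in fam_set
    ]
    report["duplication_calls"] = calls_table(family_calls)
    report["blocks"] = blocks_table(blocks)
    report["duplication_calls"].to_csv(
        outdir / "duplication_calls.tsv", sep="\t", index=False
    )
    report["blocks"].to_csv(outdir / "synteny_blocks.tsv", sep="\t", index=False)
    links = circos_links(
        blocks, {g.gene_id: (g.chromosome, g.start, g.end) for g in gen_a.genes}
    )
    links.to_csv(outdir / "circos_links.tsv", sep="\t", index=False)

    # --- Ka/Ks over classified duplicate pairs ---------------------------
    kaks_rows = []
    for c in family_calls:
        if c.mode not in ("tandem", "segmental"):
            continue
        a, b = c.pair.genes
        try:
            row_a, row_b, _, _ = pairwise_align(gen_a.proteins[a], gen_a.proteins[b])
            res = kaks_pair(backtranslate(row_a, row_b, gen_a.cds[a], gen_a.cds[b]))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage kaks: pair ({a}, {b}): {exc}") from exc
        kaks_rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "mode": c.mode,
                "S": res.S,
                "N": res.N,
                "Sd": res.Sd,
                "Nd": res.Nd,
                "pS": res.pS,
                "pN": res.pN,
                "Ka": res.Ka,
                "Ks": res.Ks,
                "ratio": res.ratio,
                "selection": res.selection,
            }
        )
    report["kaks"] = pd.DataFrame(kaks_rows)
    report["kaks"].to_csv(outdir / "kaks.tsv", sep="\t", index=False)

    # --- cross-species synteny / ortholog topology ----------------------
    if cfg.genome_b is not None:
        gen_b = _load_genome(cfg.genome_b, "load_genome_b")
        roster_b = survey_family(gen_b.proteins, scan_cfg)
        fam_b = set(roster_b.member_ids())
        cross_id_pairs = [
            (a, b) for a in gen_a.proteins.ids() for b in gen_b.proteins.ids()
            if a in fam_set or b in fam_b
        ]
        merged = SequenceSet(
            {**gen_a.proteins.sequences, **gen_b.proteins.sequences},
            alphabet="protein",
        )
        cross_pairs = find_homolog_pairs(
            merged,
            min_identity=cfg.min_identity,
            min_coverage=cfg.min_coverage,
            id_pairs=cross_id_pairs,
        )
        cross_blocks = chain_anchors(
            cross_pairs,
            gen_a.cmap,
            gen_b.cmap,
            min_anchors=cfg.min_anchors,
            max_gap=cfg.max_gap,
        )
        a_ids = set(gen_a.proteins.ids())
        syntenic = []
        for blk in cross_blocks:
            for p in blk.anchors:
                ga, gb = p.genes
                if ga not in a_ids:
                    ga, gb = gb, ga
                if ga in fam_set or gb in fam_b:
                    syntenic.append((ga, gb))
        topo = ortholog_topology(syntenic)
        report["ortholog_topology"] = topo
        report["cross_blocks"] = blocks_table(cross_blocks)
        report["cross_blocks"].to_csv(
            outdir / "cross_synteny_blocks.tsv", sep="\t", index=False
        )
        pd.DataFrame([topo.counts()]).to_csv(
            outdir / "ortholog_topology.tsv", sep="\t", index=False
        )

    # --- expression -----------------------------------------------------
    if cfg.ct_table_tsv:
        ct = CtTable.read_tsv(cfg.ct_table_tsv, cfg.ct_reference_gene)
        genes = sorted(set(ct.data["gene"]) - {cfg.ct_reference_gene})
        expr = expression_table(
            ct, genes, cfg.ct_treated_sample, cfg.ct_control_sample
        )
        report["expression"] = expr
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    manifest = {
        "genefam_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if not isinstance(v, dict) or k in ("genome_a", "genome_b")
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    report["manifest"] = manifest
    return report
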