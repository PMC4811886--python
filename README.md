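# genefam

A tested, reusable pipeline for genome-wide surveys of the bZIP
transcription-factor family (and, with a different domain pattern, other
gene families): domain-based family identification, chromosome
distribution, exon/intron statistics, neighbor-joining phylogeny with
bootstrap and reference-group labeling, tandem/segmental duplication
classification via collinearity chaining, Ka/Ks selection inference, and
qPCR ΔΔCt expression quantification. It is aimed at researchers who run
this style of family survey on a newly annotated plant genome and want
every step scripted, seeded, and testable — including on synthetic
genomes with planted ground truth, so the whole chain can be validated
without any external downloads.

## The methods at the core

**Family identification.** bZIP proteins carry a basic DNA-binding
region with an invariant **N-x7-R/K** motif followed by a leucine
zipper: leucines (or other bulky hydrophobics) repeating every 7
residues. `genefam.domain_scan` anchors on N-x7-R/K and extends the
longest period-7 heptad run downstream; a protein with ≥ 3 heptads is a
family member ("complete" domain), one with an anchor but a short run is
audited as "incomplete".

**Duplication modes.** A homologous pair (global affine-gap alignment,
identity ≥ 0.40 over ≥ 0.60 mutual coverage by default) is **tandem**
when both genes sit on one chromosome with at most one intervening gene,
and **segmental** when the pair anchors a collinear block — a chain of
homolog pairs with monotone gene ordinals on both chromosomes (≥ 3
anchors, ordinal gaps ≤ 25), found by dynamic programming.

**Selection.** For a codon alignment (protein-guided back-translation,
PAL2NAL semantics), Nei–Gojobori (1986) counting gives synonymous and
nonsynonymous sites per codon (s + n = 3, fractional) and classifies
observed differences by averaging over mutational pathways (stop-codon
pathways excluded). Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p), and Ka/Ks < 1, = 1, > 1 is read as purifying,
neutral, positive selection.

**Phylogeny.** Progressive multiple alignment (BLOSUM62, NJ guide
order), Poisson-corrected distances with pairwise gap deletion,
Saitou–Nei neighbor joining, bootstrap supports from column resampling,
and group labels transferred from the smallest unanimously labeled
clade around each query (nearest reference by path length as fallback).

**Expression.** ΔΔCt with a designated reference gene:
fold = 2^(−ΔΔCt), replicate spread carried on the ΔCt scale, two-sample
t-tests starred at P < 0.05 (\*) and P < 0.01 (\*\*).

## Worked example

`analysis/` holds the numbered survey over a simulated genome (5
chromosomes, a 10-member family over groups A/D/F/I/S expanded by 2
tandem and 4 segmental duplications under ω = 0.2):

```bash
python analysis/01_simulate_genome.py
python analysis/02_identify_family.py
...
python analysis/07_expression_qpcr.py
```

Script 02 prints

```
8 complete-domain proteins (40 incomplete, 88 without domain)
recall 100%, precision 100% against the planted family
```

— every planted family member and nothing else passes the domain scan.
Script 05 reports `6 homolog pairs, 1 collinear blocks` and
`planted events recovered: 6/6; spurious calls: 0`: both tandem pairs
(0 and 1 intervening genes) and all four anchors of the chr3→chr5 block
are classified correctly. Script 06 shows the estimator's calibration,
e.g. `omega 0.2: mean NG86 ratio 0.198 ± 0.055 (n=50)` on 600-codon
pairs, with every defined duplicate-pair ratio < 1 (purifying, as
simulated). Script 07 recovers the planted fold changes:
`fam000: fold 4.46 (p=0.0000**)` against a true fold of 4.0 with Ct
noise 0.1.

The same functionality is exposed as a CLI (`genefam simulate`,
`genefam scan`, `genefam structure`, `genefam qpcr`,
`genefam run --config survey.yaml` for the end-to-end survey on real
FASTA/GFF3 inputs).

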