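#!/usr/bin/env python
"""Generate the synthetic study genome with planted ground truth.

Emits a desk-scale genome (5 chromosomes, 10-founder bZIP family over
five groups, two tandem events, one 4-gene segmental block, ω = 0.2) and
a 3-replicate qPCR Ct table, all under results/data/.
"""

from pathlib import Path

from genefam.synthetic_data import SimSpec, generate_ct_table, generate_genome

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 23

spec = SimSpec(
    seed=SEED,
    family_size=5,
    tandem_events=(("chr1", 0), ("chr2", 1)),
    segmental_events=(("chr3", "chr5", 4),),
)


def main() -> None:
    bundle = generate_genome(spec)
    paths = bundle.write(OUT)

    # reference labels: one founder per group, mimicking a labeled
    # reference proteome (e.g. Arabidopsis groups A-L, S)
    refs: dict[str, str] = {}
    for gid in sorted(bundle.manifest.family_ids):
        refs.setdefault(bundle.manifest.group_of[gid], gid)
    with open(OUT / "reference_labels.tsv", "w") as fh:
        fh.write("id\tgroup\n")
        for lab, gid in sorted(refs.items()):
            fh.write(f"{gid}\t{lab}\n")
    with open(OUT / "reference_proteins.faa", "w") as fh:
        for lab, gid in sorted(refs.items()):
            fh.write(f">{gid}\n{bundle.proteins[gid]}\n")

    ct = generate_ct_table({"fam000": 4.0, "fam001": 0.5}, 0.1, 3, seed=SEED)
    ct.to_csv(OUT / "ct_table.tsv", sep="\t", index=False)

    m = bundle.manifest
    print(f"wrote {len(paths) + 3} files under {OUT}")
    print(f"family: {len(m.family_ids)} genes over groups "
          f"{sorted(set(m.group_of.values()))}")
    print(f"planted duplications: "
          f"{sum(p.mode == 'tandem' for p in m.duplication_pairs)} tandem, "
          f"{sum(p.mode == 'segmental' for p in m.duplication_pairs)} segmental")


if __name__ == "__main__":
    main()
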