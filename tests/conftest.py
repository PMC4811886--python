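import textwrap

import pytest

from genefam.synthetic_data import SimSpec, generate_genome


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(content: str, name: str = "seqs.fa"):
        p = tmp_path / name
        p.write_text(textwrap.dedent(content))
        return p

    return _write


@pytest.fixture
def write_gff_file(tmp_path):
    def _write(rows: list[str], name: str = "genes.gff3"):
        p = tmp_path / name
        p.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")
        return p

    return _write


@pytest.fixture(scope="session")
def default_bundle():
    """One deterministically generated genome shared across tests."""
    return generate_genome(SimSpec(seed=11))


@pytest.fixture(scope="session")
def dup_recovery_bundle():
    """Genome built for duplication recovery: one founder lineage per group,
    so every homologous pair traces to exactly one planted event."""
    spec = SimSpec(
        seed=23,
        family_size=5,
        group_labels=("A", "D", "F", "I", "S"),
        tandem_events=(("chr1", 0), ("chr2", 1)),
        segmental_events=(("chr3", "chr5", 4),),
    )
    return generate_genome(spec)
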