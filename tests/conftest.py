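import pytest

from wgdbench.model import Orthogroup, ProteinRecord, SimilarityHit, SpeciesMap


def make_hit(query, subject, bitscore=100.0, evalue=1e-20, aln_length=100,
             pident=90.0, mismatch=10, gapopen=0):
    return SimilarityHit(
        query_id=query, subject_id=subject, pident=pident,
        aln_length=aln_length, mismatch=mismatch, gapopen=gapopen,
        qstart=1, qend=aln_length, sstart=1, send=aln_length,
        evalue=evalue, bitscore=bitscore,
    )


def make_group(*genes, group_id=None, multi_copy=False):
    return Orthogroup(group_id or min(genes), frozenset(genes), multi_copy)


@pytest.fixture
def toy_map():
    """Genes a1.. of species a, b1.. of species b, etc."""
    sm = SpeciesMap()
    for sp in "abcdef":
        for i in range(1, 5):
            sm.add(f"{sp}{i}", sp)
    return sm


@pytest.fixture
def toy_records():
    seqs = {
        "a1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "b1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA",
        "c1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIECC",
    }
    return {g: ProteinRecord(g, g[0], s) for g, s in seqs.items()}
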