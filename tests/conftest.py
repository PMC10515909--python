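import pytest

from entorip.io_core import DomainAnnotationRecord


def annot(genome, protein, accession, db="Pfam", n=1, secreted=None):
    return DomainAnnotationRecord(
        genome_id=genome, protein_id=protein, domain_accession=accession,
        domain_db=db, n_instances=n, secreted=secreted)


@pytest.fixture
def small_annotations():
    """Two genomes; PF00145 in both, PF01764 only in g1, GH5 (CAZy) in g2."""
    return [
        annot("g1", "p1", "PF00145", n=2),
        annot("g1", "p2", "PF00145"),
        annot("g1", "p2", "PF01764"),
        annot("g2", "p1", "PF00145"),
        annot("g2", "p2", "GH5", db="CAZy"),
    ]


@pytest.fixture
def small_totals():
    return {"g1": 10, "g2": 10}
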