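import networkx as nx
import pytest

from phive.fixtures import FixtureConfig, make_toy_world
from phive.io_formats import GeneModel


@pytest.fixture(scope="session")
def toy_world():
    return make_toy_world(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def toy_resources(toy_world):
    return toy_world.resources()


@pytest.fixture()
def simple_transcript():
    """Plus-strand transcript: two exons, CDS covering codons split by an intron.

    chrom T: exon1 11-40, exon2 51-80; CDS 14-77 (64 coding bases -> trimmed
    to 60 by construction below). Reference designed by the tests that use it.
    """
    return GeneModel(
        gene="TOY1",
        transcript="TOY1.t1",
        strand="+",
        exons=((11, 40), (51, 80)),
        cds_start=14,
        cds_end=73,
        chrom="T",
    )


@pytest.fixture()
def tiny_ontologies():
    """Hand-built two-species DAG for phenotype-match arithmetic.

    Human:  hroot <- h1 <- h11 ; hroot <- h2
    Mouse:  mroot <- m1 <- m11 ; mroot <- m2
    Bridge: h1 == m1.
    """
    hpo = nx.DiGraph()
    hpo.add_edges_from([("h1", "hroot"), ("h11", "h1"), ("h2", "hroot")])
    mpo = nx.DiGraph()
    mpo.add_edges_from([("m1", "mroot"), ("m11", "m1"), ("m2", "mroot")])
    return hpo, mpo, [("h1", "m1")]
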