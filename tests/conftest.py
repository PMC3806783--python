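import math

import pytest
from hypothesis import settings

from phenolink.iodata import (
    AssociationTable,
    DomainProfile,
    GeneId,
    InteractionNetwork,
    OrthologPair,
    OrthologyMap,
    PhenotypeId,
    PhenotypeSimilarityTable,
    PpiEdge,
    World,
)
from phenolink.synthdata import WorldConfig, generate_world

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


# A hand-checkable world: human query gene g1 with partners p1/p2 and one
# mouse ortholog o1; every expected score below is a one-line hand sum.
#   raw_ppi(g1, HP:A) = 0.6 + 0.9 = 1.5      raw_ppi(g1, HP:B) = 0.6
#   s_orth(g1, o1) = cos({PF1:1, PF2:1}, {PF1:1}) = 1/sqrt(2)
#   raw_orth(g1, HP:A) = (1/sqrt(2)) * 0.8
@pytest.fixture
def toy_world():
    g1 = GeneId("human", "g1")
    p1 = GeneId("human", "p1")
    p2 = GeneId("human", "p2")
    o1 = GeneId("mouse", "o1")
    ph_a = PhenotypeId("human", "HP:A")
    ph_b = PhenotypeId("human", "HP:B")
    ph_x = PhenotypeId("mouse", "MP:X")

    net = InteractionNetwork([
        PpiEdge(g1, p1, 0.6),
        PpiEdge(g1, p2, 0.9),
    ])
    domains = {
        g1: DomainProfile(g1, {"PF1": 1, "PF2": 1}),
        o1: DomainProfile(o1, {"PF1": 1}),
    }
    orth = OrthologyMap([OrthologPair(g1, o1, 1.0 / math.sqrt(2.0))])
    assoc = AssociationTable([
        (p1, ph_a), (p2, ph_a), (p1, ph_b), (o1, ph_x),
    ])
    phenet = PhenotypeSimilarityTable()
    phenet.add(ph_x, ph_a, 0.8)
    world = World(net=net, orth=orth, domains=domains, assoc=assoc, phenet=phenet)
    world.ids = dict(g1=g1, p1=p1, p2=p2, o1=o1, ph_a=ph_a, ph_b=ph_b, ph_x=ph_x)
    return world


#: small-world config for brute-force comparisons
SMALL = WorldConfig(
    n_species=2, genes_per_species=10, phenotypes_per_species=8,
    n_domains=12, mean_module_size=3.0,
)


@pytest.fixture
def small_world():
    return generate_world(SMALL)


@pytest.fixture
def default_world():
    return generate_world(WorldConfig(seed=1))
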