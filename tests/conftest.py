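import dendropy
import pytest

from quartetcf.treeio import GeneTreeSet, parse_newick


def trees_from_newicks(newicks):
    ns = dendropy.TaxonNamespace()
    return [parse_newick(s, taxon_namespace=ns) for s in newicks]


@pytest.fixture
def half_half_loci():
    """Eight single-tree loci: 4 support H+A, 4 support H+B, none A+B."""
    newicks = ["((H,A),(B,O));"] * 4 + ["((H,B),(A,O));"] * 4
    return GeneTreeSet.from_trees(trees_from_newicks(newicks))


@pytest.fixture
def k2_network_text():
    """Two independent hybrid leaves with gammas 0.7 and 0.9."""
    return ("(((A,(HA)#H1:::0.7),(#H1,B)),"
            "((C,(HC)#H2:::0.9),(#H2,D)));")


@pytest.fixture
def k3_network_text():
    """Three independent hybrid leaves (gammas 0.7, 0.9, 0.6)."""
    return ("(((A,(HA)#H1:::0.7),(#H1,B)),"
            "((C,(HC)#H2:::0.9),(#H2,D)),"
            "((E,(HE)#H3:::0.6),(#H3,F)));")
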