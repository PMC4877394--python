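import pytest

from plastcomp.characters import load_tree
from plastcomp.simulate import (SimulationConfig, evolve_on_tree,
                                simulate_ancestor)

SIX_LEAF_NEWICK = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"

# Minimal hand-written GenBank record: 1 kb circular sequence with a
# forward single-exon gene (101..220), a reverse tRNA (301..372) and a
# two-exon CDS spanning the origin (join 951..1000,1..60).
TWO_GENE_GENBANK = """\
LOCUS       testrec                 1000 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  synthetic two-gene fixture.
ACCESSION   testrec
VERSION     testrec.1
FEATURES             Location/Qualifiers
     source          1..1000
     CDS             101..220
                     /gene="rbcL"
     tRNA            complement(301..372)
                     /gene="trnK-UUU"
     CDS             join(951..1000,1..60)
                     /gene="psbA"
ORIGIN
{origin}
//
"""


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        spaced = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {spaced}")
    return "\n".join(lines)


@pytest.fixture(scope="session")
def fixture_sequence():
    import random
    rng = random.Random(99)
    return "".join(rng.choice("ACGT") for _ in range(1000))


@pytest.fixture(scope="session")
def genbank_fixture(tmp_path_factory, fixture_sequence):
    path = tmp_path_factory.mktemp("gb") / "two_gene.gb"
    path.write_text(
        TWO_GENE_GENBANK.format(origin=_origin_block(fixture_sequence.lower())))
    return path


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic six-leaf simulated history shared across tests."""
    cfg = SimulationConfig(seed=11)
    tree = load_tree(SIX_LEAF_NEWICK)
    ancestor = simulate_ancestor(cfg)
    leaves, truth = evolve_on_tree(ancestor, tree, cfg)
    return {"cfg": cfg, "tree": tree, "ancestor": ancestor,
            "leaves": leaves, "truth": truth}


@pytest.fixture(scope="session")
def ancestor_genome(sim_bundle):
    return sim_bundle["ancestor"].render()
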