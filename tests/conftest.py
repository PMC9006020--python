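import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phylodissect import build_model
from phylodissect.simulate import simulate_alignment
from phylodissect.supermatrix import GeneAlignment
from phylodissect.treeops import PhyloTree


@pytest.fixture(scope="session")
def lg_g4():
    return build_model("LG", k=4, alpha=0.8)


@pytest.fixture(scope="session")
def poisson_k1():
    return build_model("Poisson", k=1)


@pytest.fixture(scope="session")
def tree5():
    return PhyloTree.from_newick(
        "((A:0.2,B:0.3):0.15,C:0.25,(D:0.1,E:0.4):0.3);"
    )


@pytest.fixture(scope="session")
def tree6():
    return PhyloTree.from_newick(
        "((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05,(E:0.3,F:0.2):0.1);"
    )


@pytest.fixture(scope="session")
def aln5(tree5, lg_g4):
    """Small fixed simulated alignment on the 5-taxon tree."""
    aln, _ = simulate_alignment(tree5, lg_g4, 60, seed=7)
    return aln


@pytest.fixture(scope="session")
def aln6(tree6, lg_g4):
    """2000-site alignment on the 6-taxon tree (strong signal)."""
    aln, _ = simulate_alignment(tree6, lg_g4, 2000, seed=42)
    return aln


@pytest.fixture()
def tiny_gene():
    return GeneAlignment(
        "tiny",
        ["A", "B", "C", "D", "E"],
        ["ARN-C", "RRQXW", "AANDC", "YRNDC", "ARKDC"],
    )
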