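import numpy as np
import pytest

from morphoshift import PhyloTree, simulate_tree


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    """(A:1,(B:0.5,C:0.5):0.5); C = [[1,0,0],[0,1,.5],[0,.5,1]]."""
    return PhyloTree.from_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture
def four_tip_tree() -> PhyloTree:
    """((A:0.8,B:0.8):0.2,(C:0.9,D:0.9):0.1); nested clades at ages 0.2, 0.1."""
    return PhyloTree.from_newick("((A:0.8,B:0.8):0.2,(C:0.9,D:0.9):0.1);")


def star_tree(n: int, depth: float = 1.0) -> PhyloTree:
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return PhyloTree.from_newick(f"({tips});")


@pytest.fixture
def medium_tree() -> PhyloTree:
    return simulate_tree(40, seed=7)


def random_shapes(rng: np.random.Generator, n: int, k: int = 6,
                  scale: float = 1.0) -> np.ndarray:
    return rng.standard_normal((n, k, 3)) * scale
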