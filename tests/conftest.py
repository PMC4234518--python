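from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from rbpmine.interactions import InteractionMatrix
from rbpmine.ontology import OntologyDAG

DATA = Path(__file__).parent / "data"


@pytest.fixture
def block_matrix() -> InteractionMatrix:
    """Two disjoint 2-factor x 2-target rank-1 blocks."""
    C = np.array(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=bool
    )
    return InteractionMatrix(C, ["t1", "t2", "t3", "t4"], ["f1", "f2", "f3", "f4"])


@pytest.fixture
def three_chain_dag() -> OntologyDAG:
    """root <-is_a- A ; root <-is_a- B (two siblings under one root)."""
    g = nx.DiGraph()
    for t in ("GO:R", "GO:A", "GO:B"):
        g.add_node(t, name=t, namespace="BP")
    g.add_edge("GO:A", "GO:R", relation="is_a")
    g.add_edge("GO:B", "GO:R", relation="is_a")
    return OntologyDAG(g)


@pytest.fixture
def two_level_dag() -> OntologyDAG:
    """root <- parent <- child chain used by the elim toy scenario."""
    g = nx.DiGraph()
    for t in ("GO:R", "GO:P", "GO:C"):
        g.add_node(t, name=t, namespace="BP")
    g.add_edge("GO:P", "GO:R", relation="is_a")
    g.add_edge("GO:C", "GO:P", relation="is_a")
    return OntologyDAG(g)


def random_boolean_matrix(rng: np.random.Generator, max_side: int = 6) -> InteractionMatrix:
    n = int(rng.integers(2, max_side + 1))
    m = int(rng.integers(2, max_side + 1))
    C = rng.random((n, m)) < rng.uniform(0.2, 0.8)
    # avoid degenerate all-zero matrices
    if not C.any():
        C[0, 0] = True
    return InteractionMatrix(
        C, [f"t{i}" for i in range(n)], [f"f{j}" for j in range(m)]
    )
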