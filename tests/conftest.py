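import numpy as np
import pandas as pd
import pytest

from moadecon.network import SignedNetwork


@pytest.fixture
def chain_network() -> SignedNetwork:
    """h -activates-> a -inhibits-> b, plus a side branch h -| c."""
    return SignedNetwork.from_edges(
        [("h", "a", 1), ("a", "b", -1), ("h", "c", -1)]
    )


@pytest.fixture
def diamond_network() -> SignedNetwork:
    """Two equal-length paths from h to a with conflicting signs."""
    return SignedNetwork.from_edges(
        [("h", "x", 1), ("h", "y", -1), ("x", "a", 1), ("y", "a", 1)]
    )


@pytest.fixture
def two_group_design() -> pd.DataFrame:
    """Minimal balanced single-DIV, single-plate two-group design."""
    return pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "treatment": ["vehicle", "vehicle", "compound", "compound"],
            "condition": ["seeded"] * 4,
            "div": [3, 3, 3, 3],
            "plate": ["P1"] * 4,
            "replicate": [1, 2, 1, 2],
        }
    )


def random_signed_graph(
    n_nodes: int, p_edge: float, rng: np.random.Generator
) -> SignedNetwork:
    """Erdos-Renyi style signed digraph for oracle comparisons."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p_edge:
                edges.append((u, v, 1 if rng.random() < 0.5 else -1))
    return SignedNetwork.from_edges(edges, nodes=nodes)
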