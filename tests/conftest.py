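import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from netpharm import Network


@pytest.fixture
def k4() -> Network:
    return Network(graph=nx.complete_graph(["A", "B", "C", "D"]), name="K4")


@pytest.fixture
def path3() -> Network:
    """Path a–b–c."""
    return Network.from_edges([("A", "B"), ("B", "C")], name="path3")


@pytest.fixture
def star5() -> Network:
    """Star with hub H and 5 leaves."""
    return Network.from_edges([("H", f"L{i}") for i in range(1, 6)], name="star5")


def net_from_nx(g: nx.Graph, name: str = "") -> Network:
    return Network(graph=nx.relabel_nodes(g, {n: f"N{n}" for n in g}), name=name)
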