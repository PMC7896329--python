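"""Shared fixture graphs with known closed-form diffusion behavior."""

import networkx as nx
import pytest


@pytest.fixture
def path3():
    """Path a-b-c on nodes 0-1-2: the smallest graph with a betweenness broker."""
    return nx.path_graph(3)


@pytest.fixture
def star5():
    """Star with hub 0 and 4 leaves."""
    return nx.star_graph(4)


@pytest.fixture
def star11():
    """Star with hub 0 and 10 leaves: hub betweenness (n-1)(n-2)/2 = 45."""
    return nx.star_graph(10)


@pytest.fixture
def cycle4():
    return nx.cycle_graph(4)


@pytest.fixture
def complete4():
    return nx.complete_graph(4)


@pytest.fixture
def fixture_graphs(path3, star5, cycle4, complete4):
    return {"path3": path3, "star5": star5, "cycle4": cycle4, "complete4": complete4}


@pytest.fixture
def edge_list_file(tmp_path):
    def write(lines, name="edges.txt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return write
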