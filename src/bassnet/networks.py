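"""Graph generation, loading, and centrality-based seed selection.

Diffusion runs on undirected simple graphs (:class:`networkx.Graph`): no
self-loops, no parallel edges, integer node ids. Graphs come from three
sources: a Barabási–Albert preferential-attachment generator (the default
experimental substrate — with one edge per node it yields a tree whose
betweenness distribution is heavily right-skewed), a Watts–Strogatz
small-world generator, and plain-text edge lists for empirical networks.

Betweenness is unnormalized shortest-path betweenness with each unordered
pair of endpoints counted once; z-scores are invariant to the normalization
constant, so reports of "SDs above the mean" do not depend on this
convention.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np

from .exceptions import (
    DegenerateCentralityError,
    EdgeListParseError,
    InvalidParameterError,
)

__all__ = [
    "CentralityReport",
    "generate_preferential_attachment",
    "generate_small_world",
    "load_edge_list",
    "giant_component",
    "betweenness_report",
    "pick_seed",
    "save_edge_list",
    "save_node_table",
]


@dataclass(frozen=True)
class CentralityReport:
    """Betweenness scores plus the top node and how extreme it is.

    ``top_zscore`` is (top score − mean) / sample SD of the scores: a
    dimensionless measure of how far the most central node sits above the
    rest of the network. On preferential-attachment trees this is typically
    well above 6.
    """

    scores: dict[int, float]
    top_node: int
    top_zscore: float


def generate_preferential_attachment(
    n: int, edges_per_node: int = 1, power: float = 1.0, rng_seed: int | None = None
) -> nx.Graph:
    """Barabási–Albert preferential-attachment graph.

    Each new node attaches to ``edges_per_node`` existing nodes with
    probability proportional to degree**power (power=1 is linear preferential
    attachment). With ``edges_per_node=1`` the result is a tree: connected,
    with n − 1 edges.

    Parameters
    ----------
    n : int
        Number of nodes (≥ 2).
    edges_per_node : int
        Edges added per arriving node (≥ 1).
    power : float
        Attachment-kernel exponent.
    rng_seed : int, optional
        Seed for the generator; identical seeds give identical edge sets.
    """
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 nodes, got {n}")
    if edges_per_node < 1:
        raise InvalidParameterError(f"need edges_per_node >= 1, got {edges_per_node}")
    rng = random.Random(rng_seed)
    ig.set_random_number_generator(rng)
    try:
        h = ig.Graph.Barabasi(n=n, m=edges_per_node, power=power, directed=False)
    finally:
        ig.set_random_number_generator(random)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(h.get_edgelist())
    return g


def generate_small_world(
    n: int, neighbors: int = 4, rewire_prob: float = 0.1, rng_seed: int | None = None
) -> nx.Graph:
    """Watts–Strogatz small-world graph.

    Ring lattice on ``n`` nodes where each node connects to its ``neighbors``
    nearest neighbors (``neighbors`` must be even), then each edge is rewired
    independently with probability ``rewire_prob``; rewirings that would
    create self-loops or duplicate edges are discarded.
    """
    if neighbors < 2 or neighbors % 2 != 0:
        raise InvalidParameterError(f"neighbors must be an even integer >= 2, got {neighbors}")
    if n <= neighbors:
        raise InvalidParameterError(f"need n > neighbors, got n={n}, neighbors={neighbors}")
    if not 0.0 <= rewire_prob <= 1.0:
        raise InvalidParameterError(f"rewire_prob must be in [0, 1], got {rewire_prob}")
    return nx.watts_strogatz_graph(n, neighbors, rewire_prob, seed=rng_seed)


def load_edge_list(
    path: str | Path, delimiter: str | None = None, comment_prefix: str = "#"
) -> nx.Graph:
    """Read an undirected simple graph from a plain-text edge list.

    One edge per line, the first two tokens being the endpoint labels
    (whitespace-split by default, or on ``delimiter``). Lines starting with
    ``comment_prefix`` and blank lines are skipped. Self-loops are dropped
    and duplicate/reciprocal edges collapsed. Labels are remapped to dense
    0-based integer ids in order of first appearance; the original labels
    are retained in ``g.graph["labels"]`` (id → label) and
    ``g.graph["label_to_id"]``.
    """
    path = Path(path)
    label_to_id: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()

    def _id(label: str) -> int:
        if label not in label_to_id:
            label_to_id[label] = len(label_to_id)
        return label_to_id[label]

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split(delimiter) if delimiter else line.split()
            tokens = [t for t in tokens if t]
            if len(tokens) < 2:
                raise EdgeListParseError(lineno, line)
            u, v = _id(tokens[0]), _id(tokens[1])
            if u == v:
                continue
            edges.add((min(u, v), max(u, v)))

    if not label_to_id:
        raise InvalidParameterError(f"no nodes found in edge list {path}")
    g = nx.Graph()
    g.add_nodes_from(range(len(label_to_id)))
    g.add_edges_from(edges)
    g.graph["labels"] = {i: lbl for lbl, i in label_to_id.items()}
    g.graph["label_to_id"] = dict(label_to_id)
    return g


def giant_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken in favor of the component containing
    the smallest node id. Node ids are preserved (not relabeled).
    """
    if g.number_of_nodes() == 0:
        raise InvalidParameterError("empty graph has no giant component")
    comps = list(nx.connected_components(g))
    best = max(comps, key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(best).copy()
    sub.graph.update(g.graph)
    return sub


def _betweenness_scores(g: nx.Graph) -> dict[int, float]:
    """Unnormalized betweenness (unordered pairs counted once) via igraph."""
    nodes = sorted(g.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    h = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges], directed=False
    )
    vals = h.betweenness(directed=False)
    return {u: float(vals[index[u]]) for u in nodes}


def betweenness_report(g: nx.Graph) -> CentralityReport:
    """Betweenness for every node, the top node, and its z-score.

    Requires a connected graph with at least 3 nodes and nonconstant
    betweenness (an SD of zero makes "most central" meaningless). Ties for
    the top score are broken by smallest node id so repeated runs pick the
    same seed.
    """
    if g.number_of_nodes() < 3:
        raise InvalidParameterError("betweenness report needs at least 3 nodes")
    if not nx.is_connected(g):
        raise InvalidParameterError("betweenness report requires a connected graph")
    scores = _betweenness_scores(g)
    vals = np.array([scores[u] for u in sorted(scores)])
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        raise DegenerateCentralityError("betweenness is constant across nodes")
    top = min(scores, key=lambda u: (-scores[u], u))
    z = (scores[top] - float(np.mean(vals))) / sd
    return CentralityReport(scores=scores, top_node=top, top_zscore=z)


def pick_seed(g: nx.Graph, condition: str, rng_seed: int | None = None) -> int:
    """Select the initial adopter.

    ``condition="central"`` returns the top-betweenness node (deterministic
    given the graph); ``condition="random"`` draws uniformly over all nodes,
    reproducibly given ``rng_seed``.
    """
    if condition == "central":
        return betweenness_report(g).top_node
    if condition == "random":
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(rng_seed)
        return nodes[int(rng.integers(len(nodes)))]
    raise InvalidParameterError(f"condition must be 'central' or 'random', got {condition!r}")


def save_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write the graph as a plain-text edge list (one ``u v`` pair per line)."""
    with Path(path).open("w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges):
            fh.write(f"{u} {v}\n")


def save_node_table(g: nx.Graph, path: str | Path) -> None:
    """Write a per-node CSV ``node,label,betweenness``.

    Labels default to the node id unless the graph carries a
    ``labels`` map from :func:`load_edge_list`.
    """
    scores = _betweenness_scores(g)
    labels = g.graph.get("labels", {})
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "label", "betweenness"])
        for u in sorted(g.nodes):
            writer.writerow([u, labels.get(u, u), scores[u]])
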