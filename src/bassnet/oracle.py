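"""Exact Markov-chain analysis of the diffusion process on small graphs.

The adopter set is a Markov chain on the subsets of nodes containing the
seed: given the current set S, each non-adopter i adopts independently with
probability min(1, alpha + beta * f_i(S)), so the transition probability to
a superset T is a product of per-node Bernoulli terms. On graphs small
enough to enumerate (guarded at 20 nodes) this gives exact saturation
probabilities and expected first-passage times, against which the Monte
Carlo simulator is validated.

States are encoded as bitmasks over the sorted node list. Expected
first-passage times to a target adopter count are computed by the standard
absorbing-chain linear system (I − Q) t = 1 over the transient states,
which is exact whenever absorption has probability 1 (alpha > 0, or beta > 0
on a connected graph).
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx
import numpy as np

from .exceptions import (
    GraphTooLargeError,
    InfeasibilityError,
    InvalidParameterError,
    InvalidTransitionError,
)
from .simulator import adoption_probability

__all__ = [
    "transition_probability",
    "exact_saturation_probability",
    "exact_expected_time",
]

MAX_ORACLE_NODES = 20


def _node_order(g: nx.Graph) -> list[int]:
    return sorted(g.nodes)


def _hazard(g: nx.Graph, node, adopters: frozenset, alpha: float, beta: float) -> float:
    nbrs = list(g.neighbors(node))
    frac = sum(1 for v in nbrs if v in adopters) / len(nbrs) if nbrs else 0.0
    return adoption_probability(alpha, beta, frac)


def transition_probability(
    g: nx.Graph,
    from_set: Iterable[int],
    to_set: Iterable[int],
    alpha: float,
    beta: float,
) -> float:
    """Exact one-tick probability of moving from one adopter set to another.

    Product over newly adopting nodes of their hazards, times the product
    over remaining non-adopters of one minus theirs, all hazards computed
    from ``from_set``. Requires from_set ⊆ to_set (adoption is
    irreversible).
    """
    from_set, to_set = frozenset(from_set), frozenset(to_set)
    if not from_set <= to_set:
        raise InvalidTransitionError("from_set must be a subset of to_set")
    nodes = set(g.nodes)
    if not to_set <= nodes:
        raise InvalidParameterError("adopter sets must be subsets of the graph's nodes")
    prob = 1.0
    for u in nodes - from_set:
        p = _hazard(g, u, from_set, alpha, beta)
        prob *= p if u in to_set else 1.0 - p
    return prob


def _check_size(g: nx.Graph) -> None:
    if g.number_of_nodes() > MAX_ORACLE_NODES:
        raise GraphTooLargeError(
            f"oracle enumerates adopter sets exactly; refuses graphs with more than "
            f"{MAX_ORACLE_NODES} nodes (got {g.number_of_nodes()})"
        )


def _successor_distribution(
    nodes: list[int],
    neighbor_masks: list[int],
    degrees: list[int],
    state: int,
    alpha: float,
    beta: float,
) -> dict[int, float]:
    """Distribution over next-tick adopter bitmasks from ``state``."""
    n = len(nodes)
    dist = {state: 1.0}
    for i in range(n):
        bit = 1 << i
        if state & bit:
            continue
        if degrees[i]:
            frac = bin(neighbor_masks[i] & state).count("1") / degrees[i]
        else:
            frac = 0.0
        p = min(1.0, alpha + beta * frac)
        if p == 0.0:
            continue
        new = {}
        for mask, pr in dist.items():
            if p < 1.0:
                new[mask] = new.get(mask, 0.0) + pr * (1.0 - p)
            new[mask | bit] = new.get(mask | bit, 0.0) + pr * p
        dist = new
    return dist


def _graph_masks(g: nx.Graph) -> tuple[list[int], list[int], list[int]]:
    nodes = _node_order(g)
    index = {u: i for i, u in enumerate(nodes)}
    neighbor_masks = [0] * len(nodes)
    for u, v in g.edges:
        neighbor_masks[index[u]] |= 1 << index[v]
        neighbor_masks[index[v]] |= 1 << index[u]
    degrees = [bin(m).count("1") for m in neighbor_masks]
    return nodes, neighbor_masks, degrees


def exact_saturation_probability(
    g: nx.Graph, seed: int, alpha: float, beta: float, tick_limit: int
) -> float:
    """P(every node has adopted within ``tick_limit`` ticks of seeding).

    Propagates the exact state distribution tick by tick; the all-adopted
    state is absorbing, so the returned value is the cumulative mass it has
    collected.
    """
    _check_size(g)
    if seed not in g.nodes:
        raise InvalidParameterError(f"seed node {seed} is not in the graph")
    nodes, neighbor_masks, degrees = _graph_masks(g)
    index = {u: i for i, u in enumerate(nodes)}
    full = (1 << len(nodes)) - 1
    dist = {1 << index[seed]: 1.0}
    for _ in range(tick_limit):
        if set(dist) == {full}:
            break
        new: dict[int, float] = {}
        for state, pr in dist.items():
            if state == full:
                new[full] = new.get(full, 0.0) + pr
                continue
            for nxt, q in _successor_distribution(
                nodes, neighbor_masks, degrees, state, alpha, beta
            ).items():
                new[nxt] = new.get(nxt, 0.0) + pr * q
        dist = new
    return dist.get(full, 0.0)


def exact_expected_time(
    g: nx.Graph, seed: int, alpha: float, beta: float, target_fraction: float = 1.0
) -> float:
    """Exact expected first-passage time to ⌈fraction·n⌉ adopters.

    Solves the absorbing-chain system (I − Q) t = 1 over the transient
    states (adopter sets below the target). Requires the target to be
    reached with probability 1: alpha > 0, or beta > 0 on a connected
    graph (any proper adopter set then has a boundary node with positive
    hazard).
    """
    _check_size(g)
    if seed not in g.nodes:
        raise InvalidParameterError(f"seed node {seed} is not in the graph")
    if not 0.0 < target_fraction <= 1.0:
        raise InvalidParameterError("target_fraction must be in (0, 1]")
    n = g.number_of_nodes()
    target = math.ceil(target_fraction * n)
    if target <= 1:
        return 0.0
    if alpha == 0.0 and (beta == 0.0 or not nx.is_connected(g)):
        raise InfeasibilityError(
            "target adoption level is unreachable with probability 1 "
            "(alpha = 0 requires beta > 0 on a connected graph)"
        )
    nodes, neighbor_masks, degrees = _graph_masks(g)
    index = {u: i for i, u in enumerate(nodes)}
    seed_mask = 1 << index[seed]

    # transient states: supersets of the seed with fewer than `target` adopters
    transient = [
        m
        for m in range(1 << n)
        if (m & seed_mask) and bin(m).count("1") < target
    ]
    t_index = {m: k for k, m in enumerate(transient)}
    q = np.zeros((len(transient), len(transient)))
    for k, state in enumerate(transient):
        for nxt, pr in _successor_distribution(
            nodes, neighbor_masks, degrees, state, alpha, beta
        ).items():
            if nxt in t_index:
                q[k, t_index[nxt]] += pr
    times = np.linalg.solve(np.eye(len(transient)) - q, np.ones(len(transient)))
    return float(times[t_index[seed_mask]])
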