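"""Discrete-time agent-based Bass diffusion on a graph.

Each tick, every non-adopter *i* adopts independently with probability

    p_i = min(1, alpha + beta * f_i)

where ``f_i`` is the fraction of *i*'s neighbors that had adopted by the end
of the previous tick. ``alpha`` is the constant external-influence hazard
(advertising, mass media); ``beta`` weights interpersonal influence (word of
mouth). Adoption is irreversible, so cumulative adopter counts are
nondecreasing. The update is synchronous: all hazards within a tick are
computed from the adopter set at the start of the tick, mirroring the
structure of the aggregate Bass recursion

    N_{t+1} = N_t + (a + b N_t)(N_max − N_t)

which the agent model reduces to, in expectation, on a complete graph with
a = alpha and b = beta / (n − 1).

Conventions: isolated (degree-0) nodes have an adopted-neighbor fraction of
0 and adopt through alpha only; hazards above 1 are capped at 1; the seed
adopts at tick 0 and counts toward cumulative[0] = 1. Each tick draws one
uniform variate per node, aligned with ascending node-id order (draws for
already-adopted nodes are discarded), so a run is fully reproducible from
its RNG seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import InvalidParameterError

__all__ = [
    "SimulationParams",
    "AdoptionTrajectory",
    "AggregateBassParams",
    "DiffusionEngine",
    "adoption_probability",
    "step",
    "run_simulation",
    "time_to_fraction",
    "aggregate_bass_curve",
    "mean_cumulative_curve",
    "save_trajectory",
]


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of a single run.

    alpha and beta are per-tick probability weights (≥ 0; combined hazards
    above 1 are legal and capped at 1).
    """

    alpha: float
    beta: float
    seed_node: int
    max_ticks: int = 1000
    rng_seed: int | None = None

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("alpha and beta must be nonnegative")
        if self.max_ticks < 1:
            raise InvalidParameterError("max_ticks must be >= 1")


@dataclass
class AdoptionTrajectory:
    """Cumulative adopter counts per tick plus derived passage times.

    ``cumulative[t]`` is the adopter count at the end of tick t
    (``cumulative[0] == 1``: the seed). ``time_to_half``/``time_to_full``
    are first-passage ticks to ⌈n/2⌉ and n adopters, or None if censored
    (not attained within max_ticks).
    """

    cumulative: np.ndarray
    n_nodes: int
    saturated: bool
    time_to_half: int | None
    time_to_full: int | None


@dataclass(frozen=True)
class AggregateBassParams:
    """Coefficients of the aggregate (mean-field) Bass recursion."""

    a: float
    b: float
    n_max: float
    n0: float

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise InvalidParameterError("a and b must be nonnegative")
        if not 0 <= self.n0 <= self.n_max:
            raise InvalidParameterError("need 0 <= n0 <= n_max")


def adoption_probability(alpha: float, beta: float, adopted_neighbor_fraction: float) -> float:
    """Per-tick conditional adoption probability for one non-adopter."""
    if alpha < 0 or beta < 0:
        raise InvalidParameterError("alpha and beta must be nonnegative")
    if not 0.0 <= adopted_neighbor_fraction <= 1.0:
        raise InvalidParameterError(
            f"adopted_neighbor_fraction must be in [0, 1], got {adopted_neighbor_fraction}"
        )
    return min(1.0, alpha + beta * adopted_neighbor_fraction)


class DiffusionEngine:
    """Vectorized diffusion runner bound to one graph.

    Builds the sparse adjacency once; single runs and replicated ensembles
    share it. Node ids are mapped to dense indices in sorted order, so the
    engine works on induced subgraphs with gaps in their id range.
    """

    def __init__(self, g: nx.Graph):
        self.nodes: list[int] = sorted(g.nodes)
        self.n = len(self.nodes)
        self.index = {u: i for i, u in enumerate(self.nodes)}
        rows, cols = [], []
        for u, v in g.edges:
            iu, iv = self.index[u], self.index[v]
            rows += [iu, iv]
            cols += [iv, iu]
        data = np.ones(len(rows), dtype=np.float32)
        self.adjacency = sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        # degree-0 nodes: fraction fixed at 0 via a zero inverse degree
        self.inv_degree = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0).astype(np.float64)

    def hazards(self, adopted: np.ndarray, alpha: float, beta: float) -> np.ndarray:
        """Per-node adoption probabilities given adopter indicator rows."""
        counts = adopted.astype(np.float32) @ self.adjacency
        frac = np.asarray(counts, dtype=np.float64) * self.inv_degree
        return np.minimum(1.0, alpha + beta * frac)

    def run(
        self,
        alpha: float,
        beta: float,
        seed_index: int,
        max_ticks: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """One run; returns the cumulative-count array (stops early once full)."""
        adopted = np.zeros(self.n, dtype=bool)
        adopted[seed_index] = True
        cumulative = [1]
        for _ in range(max_ticks):
            p = self.hazards(adopted[None, :], alpha, beta)[0]
            draws = rng.random(self.n)
            adopted |= (~adopted) & (draws < p)
            cumulative.append(int(adopted.sum()))
            if cumulative[-1] == self.n:
                break
        return np.array(cumulative, dtype=np.int64)

    def times_to_fraction(
        self,
        alpha: float,
        beta: float,
        seed_indices: np.ndarray,
        max_ticks: int,
        rng: np.random.Generator,
        fraction: float = 1.0,
    ) -> np.ndarray:
        """First-passage ticks to ⌈fraction·n⌉ adopters for a batch of runs.

        One replication per entry of ``seed_indices``; returns an int array
        with −1 marking censored runs (target not reached by max_ticks).
        Replications are advanced in lockstep and dropped once they hit the
        target, so the cost scales with the number of still-active runs.
        """
        seed_indices = np.asarray(seed_indices, dtype=np.int64)
        n_reps = len(seed_indices)
        target = math.ceil(fraction * self.n)
        times = np.full(n_reps, -1, dtype=np.int64)
        if target <= 1:
            times[:] = 0
            return times
        adopted = np.zeros((n_reps, self.n), dtype=bool)
        adopted[np.arange(n_reps), seed_indices] = True
        active = np.arange(n_reps)
        for t in range(1, max_ticks + 1):
            p = self.hazards(adopted[active], alpha, beta)
            draws = rng.random((len(active), self.n))
            block = adopted[active]
            block |= (~block) & (draws < p)
            adopted[active] = block
            reached = block.sum(axis=1) >= target
            if reached.any():
                times[active[reached]] = t
                active = active[~reached]
                if len(active) == 0:
                    break
        return times

    def mean_curve(
        self,
        alpha: float,
        beta: float,
        seed_index: int,
        n_reps: int,
        ticks: int,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble mean and SD of the cumulative curve over ``n_reps`` runs.

        Returns (mean, sd) arrays of length ticks+1, indexed by tick.
        """
        counts = np.zeros((n_reps, ticks + 1), dtype=np.int64)
        adopted = np.zeros((n_reps, self.n), dtype=bool)
        adopted[:, seed_index] = True
        counts[:, 0] = 1
        for t in range(1, ticks + 1):
            if not (adopted.sum(axis=1) < self.n).any():
                counts[:, t:] = self.n
                break
            p = self.hazards(adopted, alpha, beta)
            draws = rng.random((n_reps, self.n))
            adopted |= (~adopted) & (draws < p)
            counts[:, t] = adopted.sum(axis=1)
        return counts.mean(axis=0), counts.std(axis=0, ddof=1)


def step(
    g: nx.Graph,
    adopters: set[int],
    params: SimulationParams,
    rng: np.random.Generator,
) -> set[int]:
    """One synchronous tick: returns the post-tick adopter set.

    Hazards are computed from ``adopters`` as it stood at the start of the
    tick; each non-adopter adopts independently. One uniform variate is
    drawn per node in ascending node-id order (adopters' draws discarded),
    the same protocol as :func:`run_simulation`.
    """
    if not adopters:
        raise InvalidParameterError("adopters must be nonempty")
    if not set(adopters) <= set(g.nodes):
        raise InvalidParameterError("adopters must be a subset of the graph's nodes")
    engine = DiffusionEngine(g)
    adopted = np.zeros(engine.n, dtype=bool)
    adopted[[engine.index[u] for u in adopters]] = True
    p = engine.hazards(adopted[None, :], params.alpha, params.beta)[0]
    draws = rng.random(engine.n)
    adopted |= (~adopted) & (draws < p)
    return {engine.nodes[i] for i in np.flatnonzero(adopted)}


def run_simulation(g: nx.Graph, params: SimulationParams) -> AdoptionTrajectory:
    """Run one full trajectory from the seed node.

    Iterates synchronous ticks until every node has adopted or
    ``params.max_ticks`` is reached, recording the cumulative adopter count
    at every tick. Identical (graph, params) including ``rng_seed`` give
    identical trajectories.
    """
    if params.seed_node not in g.nodes:
        raise InvalidParameterError(f"seed node {params.seed_node} is not in the graph")
    engine = DiffusionEngine(g)
    rng = np.random.default_rng(params.rng_seed)
    cumulative = engine.run(
        params.alpha, params.beta, engine.index[params.seed_node], params.max_ticks, rng
    )
    n = engine.n
    return AdoptionTrajectory(
        cumulative=cumulative,
        n_nodes=n,
        saturated=bool(cumulative[-1] == n),
        time_to_half=time_to_fraction(cumulative, n, 0.5),
        time_to_full=time_to_fraction(cumulative, n, 1.0),
    )


def time_to_fraction(
    cumulative: np.ndarray | AdoptionTrajectory, n: int, fraction: float
) -> int | None:
    """First tick at which adopters reach ⌈fraction·n⌉, or None if censored."""
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    if isinstance(cumulative, AdoptionTrajectory):
        cumulative = cumulative.cumulative
    target = math.ceil(fraction * n)
    hits = np.flatnonzero(np.asarray(cumulative) >= target)
    return int(hits[0]) if len(hits) else None


def aggregate_bass_curve(params: AggregateBassParams, ticks: int) -> np.ndarray:
    """Deterministic aggregate Bass recursion N_0..N_ticks.

    N_{t+1} = N_t + (a + b N_t)(N_max − N_t), clipped to N_max.
    """
    if ticks < 0:
        raise InvalidParameterError("ticks must be >= 0")
    out = np.empty(ticks + 1, dtype=np.float64)
    out[0] = params.n0
    for t in range(ticks):
        n_t = out[t]
        out[t + 1] = min(params.n_max, n_t + (params.a + params.b * n_t) * (params.n_max - n_t))
    return out


def mean_cumulative_curve(
    g: nx.Graph,
    alpha: float,
    beta: float,
    seed_node: int,
    n_reps: int,
    ticks: int,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo mean (and SD) of the cumulative adopter curve."""
    engine = DiffusionEngine(g)
    rng = np.random.default_rng(rng_seed)
    return engine.mean_curve(alpha, beta, engine.index[seed_node], n_reps, ticks, rng)


def save_trajectory(traj: AdoptionTrajectory, params: SimulationParams, path: str | Path) -> None:
    """Write a trajectory as CSV (`tick,cumulative_adopters`) with a metadata sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tick", "cumulative_adopters"])
        for t, c in enumerate(traj.cumulative):
            writer.writerow([t, int(c)])
    meta = {
        "alpha": params.alpha,
        "beta": params.beta,
        "seed_node": params.seed_node,
        "rng_seed": params.rng_seed,
        "saturated": traj.saturated,
        "time_to_half": traj.time_to_half,
        "time_to_full": traj.time_to_full,
    }
    with path.with_suffix(path.suffix + ".meta").open("w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")
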