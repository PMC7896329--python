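"""The seeding experiment: central vs. random seeds over an (alpha, beta) grid.

For each grid cell the treatment condition seeds diffusion at the fixed
top-betweenness node; the control condition redraws a uniformly random seed
node for every replication. The cell summary is the ratio of mean times to
50% adoption (random / central): a ratio above 1 means the central seed
spreads faster. Doses are expressed as fractions of the calibrated LD50
values so that external and interpersonal influence are on comparable
scales; the default grid is {0} plus log-spaced points from 0.26% to 100%
of LD50, which puts the interesting collapse of the central-seed advantage
— from a ratio above 2 at alpha = 0 to near parity by a few percent of
LD50 — on a log axis.

A run is right-censored when it does not reach half-adoption within the
tick budget; means are taken over uncensored runs only, and a cell is
flagged censored whenever either condition's censored share exceeds a
threshold (default 5%), since means over mostly-censored runs are biased
downward.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .networks import betweenness_report
from .simulator import DiffusionEngine

__all__ = [
    "SweepConfig",
    "SweepCell",
    "default_grid",
    "run_cell",
    "run_sweep",
    "sparkline_summary",
    "sweep_to_dataframe",
    "save_sweep_csv",
]

GRID_FLOOR_FRACTION = 0.0026  # smallest positive dose, as a fraction of LD50


@dataclass(frozen=True)
class SweepConfig:
    """Grid and replication settings for a sweep.

    ``alpha_fractions``/``beta_fractions`` are fractions of the respective
    LD50 doses (0 allowed; conventionally the alpha grid starts at 0).
    """

    alpha_fractions: tuple[float, ...]
    beta_fractions: tuple[float, ...]
    n_reps: int = 100
    max_ticks: int = 1000
    censor_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        if any(f < 0 for f in self.alpha_fractions + self.beta_fractions):
            raise InvalidParameterError("grid fractions must be nonnegative")


@dataclass
class SweepCell:
    """Per-(alpha, beta) summary of the two seeding conditions.

    Means are over uncensored runs and are None when every run in the
    condition was censored; ``ratio`` is mean_time_random /
    mean_time_central when both are defined.
    """

    alpha_fraction: float
    beta_fraction: float
    alpha: float
    beta: float
    mean_time_random: float | None
    mean_time_central: float | None
    ratio: float | None
    n_censored_random: int
    n_censored_central: int
    censored: bool


def default_grid(ld50_value: float, n_points: int = 13) -> np.ndarray:
    """{0} followed by ``n_points`` log-spaced doses from 0.26% to 100% of LD50."""
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    positive = np.geomspace(GRID_FLOOR_FRACTION * ld50_value, ld50_value, n_points)
    return np.concatenate([[0.0], positive])


def run_cell(
    g: nx.Graph,
    alpha: float,
    beta: float,
    n_reps: int = 100,
    max_ticks: int = 1000,
    rng_seed: int | None = None,
    censor_threshold: float = 0.05,
    alpha_fraction: float = math.nan,
    beta_fraction: float = math.nan,
    central_node: int | None = None,
    engine: DiffusionEngine | None = None,
) -> SweepCell:
    """Run both seeding conditions at one (alpha, beta) point.

    ``central_node`` and ``engine`` can be supplied to avoid recomputing
    betweenness and adjacency across cells of a sweep.
    """
    if engine is None:
        engine = DiffusionEngine(g)
    if central_node is None:
        central_node = betweenness_report(g).top_node
    if isinstance(rng_seed, np.random.SeedSequence):
        seq = rng_seed
    else:
        seq = np.random.SeedSequence(rng_seed if rng_seed is not None else None)
    rng_central, rng_random = (np.random.default_rng(s) for s in seq.spawn(2))

    central_seeds = np.full(n_reps, engine.index[central_node], dtype=np.int64)
    t_central = engine.times_to_fraction(
        alpha, beta, central_seeds, max_ticks, rng_central, fraction=0.5
    )
    random_seeds = rng_random.integers(0, engine.n, size=n_reps)
    t_random = engine.times_to_fraction(
        alpha, beta, random_seeds, max_ticks, rng_random, fraction=0.5
    )

    def summarize(times: np.ndarray) -> tuple[float | None, int]:
        ok = times[times >= 0]
        n_cens = int((times < 0).sum())
        return (float(ok.mean()) if len(ok) else None), n_cens

    mean_random, cens_random = summarize(t_random)
    mean_central, cens_central = summarize(t_central)
    ratio = None
    if mean_random is not None and mean_central is not None and mean_central > 0:
        ratio = mean_random / mean_central
    censored = (
        cens_random / n_reps > censor_threshold or cens_central / n_reps > censor_threshold
    )
    return SweepCell(
        alpha_fraction=alpha_fraction,
        beta_fraction=beta_fraction,
        alpha=alpha,
        beta=beta,
        mean_time_random=mean_random,
        mean_time_central=mean_central,
        ratio=ratio,
        n_censored_random=cens_random,
        n_censored_central=cens_central,
        censored=censored,
    )


def run_sweep(
    g: nx.Graph, ld50_alpha: float, ld50_beta: float, config: SweepConfig
) -> list[SweepCell]:
    """Evaluate every cell of the alpha × beta fraction grid.

    Per-cell RNG substreams are derived from (config.rng_seed, i, j) cell
    indices, so adding grid points never perturbs other cells' draws, and a
    repeated sweep with the same seed reproduces the table exactly.
    """
    if not config.alpha_fractions or not config.beta_fractions:
        raise InvalidParameterError("grids must be nonempty")
    engine = DiffusionEngine(g)
    central = betweenness_report(g).top_node
    cells = []
    for i, af in enumerate(config.alpha_fractions):
        for j, bf in enumerate(config.beta_fractions):
            cell_seed = np.random.SeedSequence([config.rng_seed, i, j])
            cells.append(
                run_cell(
                    g,
                    alpha=af * ld50_alpha,
                    beta=bf * ld50_beta,
                    n_reps=config.n_reps,
                    max_ticks=config.max_ticks,
                    rng_seed=cell_seed,
                    censor_threshold=config.censor_threshold,
                    alpha_fraction=af,
                    beta_fraction=bf,
                    central_node=central,
                    engine=engine,
                )
            )
    return cells


def sparkline_summary(
    cells: list[SweepCell], beta_fraction: float
) -> list[tuple[float, float | None]]:
    """Ratio profile across alpha for one fixed beta row, ordered by alpha.

    Censored cells appear with a None ratio rather than a number.
    """
    row = [c for c in cells if c.beta_fraction == beta_fraction]
    if not row:
        raise InvalidParameterError(f"no sweep cells with beta_fraction={beta_fraction}")
    row.sort(key=lambda c: c.alpha_fraction)
    return [(c.alpha_fraction, None if c.censored else c.ratio) for c in row]


def sweep_to_dataframe(cells: list[SweepCell]) -> pd.DataFrame:
    """Long-format table of sweep cells (one row per grid point)."""
    return pd.DataFrame(
        {
            "alpha_fraction": [c.alpha_fraction for c in cells],
            "beta_fraction": [c.beta_fraction for c in cells],
            "alpha": [c.alpha for c in cells],
            "beta": [c.beta for c in cells],
            "mean_time_random": [c.mean_time_random for c in cells],
            "mean_time_central": [c.mean_time_central for c in cells],
            "ratio": [c.ratio for c in cells],
            "n_censored_random": [c.n_censored_random for c in cells],
            "n_censored_central": [c.n_censored_central for c in cells],
            "censored": [c.censored for c in cells],
        }
    )


def save_sweep_csv(cells: list[SweepCell], path: str | Path) -> None:
    """Write the sweep table as CSV; undefined means render as empty fields."""
    sweep_to_dataframe(cells).to_csv(path, index=False)
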