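"""LD50 dose calibration.

The external (alpha) and interpersonal (beta) hazards live on different
natural scales, so experiments express both as fractions of a saturating
dose: the parameter value at which the network fully adopts within a tick
budget (default 100 ticks) in 50% of trials — "LD50", by analogy with
toxicology. Alpha is calibrated with beta pinned at 0 and vice versa.

The saturation probability is nondecreasing in either dose (raising a
hazard can only speed adoption), which justifies bisection. Alpha is itself
a per-tick probability, so its search bracket is [0, 1] (doses above 1 are
indistinguishable from 1 once hazards are capped). Beta is a *weight* on
the adopted-neighbor fraction: a high-degree node with one adopted neighbor
has a tiny fraction, so saturating a hub-dominated graph within the tick
budget routinely requires beta > 1. The beta search therefore starts from
[0, 1] and doubles the upper bracket until it saturates in at least half of
trials (guarded at 1024). Calibration
trials use a uniformly random seed node per trial — the LD50 is a
seed-agnostic property of the (graph, parameter) pair, not of any one seed.
Bisection uses a fixed trial count per candidate; binomial noise near the
0.5 crossing then limits the precision of the estimate to roughly one
binomial standard error divided by the local slope of the dose-response
curve, so trial counts should rise when the LD50 feeds quantitative
downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import InfeasibilityError, InvalidParameterError, NoLD50InRangeError
from .simulator import DiffusionEngine

__all__ = ["LD50Result", "saturation_fraction", "estimate_ld50", "save_ld50_csv"]

DEFAULT_TICK_LIMIT = 100
MAX_BETA_DOSE = 1024.0


@dataclass
class LD50Result:
    """A calibrated saturating dose plus search diagnostics.

    ``bracket_history`` records every (candidate dose, observed saturation
    fraction) pair the bisection evaluated, in order.
    """

    parameter: str
    value: float
    saturation_fraction_at_value: float
    trials_per_candidate: int
    bracket_history: list[tuple[float, float]] = field(default_factory=list)
    tick_limit: int = DEFAULT_TICK_LIMIT


def saturation_fraction(
    g: nx.Graph,
    alpha: float,
    beta: float,
    tick_limit: int = DEFAULT_TICK_LIMIT,
    n_trials: int = 100,
    rng_seed: int | None = None,
    engine: DiffusionEngine | None = None,
) -> float:
    """Fraction of trials in which every node adopts within ``tick_limit``.

    Each trial is an independent run from a fresh uniformly random seed
    node. With alpha = 0 diffusion can only follow edges, so a disconnected
    graph can never saturate and is rejected as infeasible.
    """
    if n_trials < 1 or tick_limit < 1:
        raise InvalidParameterError("n_trials and tick_limit must be >= 1")
    if alpha == 0.0 and not nx.is_connected(g):
        raise InfeasibilityError(
            "beta-only diffusion cannot saturate a disconnected graph; "
            "extract the giant component first"
        )
    if engine is None:
        engine = DiffusionEngine(g)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, engine.n, size=n_trials)
    times = engine.times_to_fraction(alpha, beta, seeds, tick_limit, rng, fraction=1.0)
    return float(np.mean(times >= 0))


def estimate_ld50(
    g: nx.Graph,
    parameter: str,
    tick_limit: int = DEFAULT_TICK_LIMIT,
    n_trials: int = 100,
    tolerance: float = 1.0 / 1024,
    rng_seed: int | None = None,
) -> LD50Result:
    """Bisection estimate of the LD50 dose for ``parameter`` ("alpha" or "beta").

    The other parameter is held at 0. The search maintains a bracket
    [lo, hi] with observed saturation fraction < 0.5 at lo and ≥ 0.5 at hi,
    and halves it until its width drops below ``tolerance``; the returned
    value is the final midpoint, re-evaluated once with fresh trials for
    the reported saturation fraction. For alpha the bracket is [0, 1]; for
    beta the upper bracket doubles from 1 as needed (see module docstring).
    """
    if parameter not in ("alpha", "beta"):
        raise InvalidParameterError(f"parameter must be 'alpha' or 'beta', got {parameter!r}")
    if not 0 < tolerance < 1:
        raise InvalidParameterError("tolerance must be in (0, 1)")
    engine = DiffusionEngine(g)
    seq = np.random.SeedSequence(rng_seed if rng_seed is not None else None)
    children = iter(seq.spawn(2048))

    def frac_at(dose: float) -> float:
        alpha, beta = (dose, 0.0) if parameter == "alpha" else (0.0, dose)
        return saturation_fraction(
            g, alpha, beta, tick_limit, n_trials,
            rng_seed=next(children), engine=engine,
        )

    max_dose = 1.0 if parameter == "alpha" else MAX_BETA_DOSE
    history: list[tuple[float, float]] = []
    lo, hi = 0.0, 1.0
    f_hi = frac_at(hi)
    history.append((hi, f_hi))
    while f_hi < 0.5 and hi < max_dose:
        lo, hi = hi, hi * 2.0
        f_hi = frac_at(hi)
        history.append((hi, f_hi))
    if f_hi < 0.5:
        raise NoLD50InRangeError(
            f"saturation fraction at {parameter}={hi:g} is {f_hi:.3f} < 0.5; "
            f"no LD50 in (0, {max_dose:g}]"
        )
    while hi - lo >= tolerance:
        mid = 0.5 * (lo + hi)
        f_mid = frac_at(mid)
        history.append((mid, f_mid))
        if f_mid >= 0.5:
            hi = mid
        else:
            lo = mid
    value = 0.5 * (lo + hi)
    f_value = frac_at(value)
    history.append((value, f_value))
    return LD50Result(
        parameter=parameter,
        value=value,
        saturation_fraction_at_value=f_value,
        trials_per_candidate=n_trials,
        bracket_history=history,
        tick_limit=tick_limit,
    )


def save_ld50_csv(
    results: list[LD50Result], path: str | Path, network: str = "",
    history_path: str | Path | None = None,
) -> None:
    """Write LD50 results as CSV, optionally with the bracket history long-format."""
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["network", "parameter", "value", "saturation_fraction", "trials", "tick_limit"]
        )
        for r in results:
            writer.writerow(
                [network, r.parameter, r.value, r.saturation_fraction_at_value,
                 r.trials_per_candidate, r.tick_limit]
            )
    if history_path is not None:
        with Path(history_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["network", "parameter", "evaluation", "candidate", "fraction"])
            for r in results:
                for k, (cand, frac) in enumerate(r.bracket_history):
                    writer.writerow([network, r.parameter, k, cand, frac])
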