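"""Generic simulated-annealing engine: Metropolis acceptance with a
geometric (exponential-decay) cooling schedule.

One engine serves both uses in this package — feature-weight
optimization (which maximizes an objective by minimizing its negation)
and classifier parameter training (which minimizes a loss directly).
The convention is minimization throughout: a proposal with
``delta_E <= 0`` is always accepted, a worse one with probability
``exp(-delta_E / T)``.  Ties are accepted, which aids plateau
exploration.  After a rejection the chain stays at the current solution
(standard Metropolis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass
class AnnealSchedule:
    """Cooling plan.

    Defaults are the package-wide annealing settings: initial
    temperature 1.0, cooling rate 0.95 per iteration, 500 iterations.
    The run stops early once ``T < T_min`` (default 1e-6, at which point
    worse moves are effectively never accepted).
    """

    T0: float = 1.0
    gamma: float = 0.95
    max_iter: int = 500
    T_min: float = 1e-6

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.T_min < 0:
            raise ValueError("T_min must be >= 0")


@dataclass
class AnnealTrace:
    """Per-iteration record of one annealing run."""

    temperature: list = field(default_factory=list)
    energy: list = field(default_factory=list)            # proposal energy
    accepted: list = field(default_factory=list)
    best_energy: list = field(default_factory=list)
    best_solution: object = None
    final_best_energy: float = math.nan

    def __len__(self) -> int:
        return len(self.temperature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(len(self)),
            "T": self.temperature,
            "energy": self.energy,
            "accepted": self.accepted,
            "best_energy": self.best_energy,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def acceptance_probability(delta_E: float, T: float) -> float:
    """Metropolis acceptance probability under minimization.

    Improvements and ties (``delta_E <= 0``) are accepted with
    certainty; otherwise ``exp(-delta_E / T)``.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if delta_E <= 0:
        return 1.0
    return math.exp(-delta_E / T)


def cool(T: float, gamma: float) -> float:
    """One geometric cooling step, ``T * gamma``."""
    return T * gamma


def anneal(energy_fn: Callable, perturb_fn: Callable, x0,
           schedule: AnnealSchedule | None = None,
           rng: np.random.Generator | None = None):
    """Run simulated annealing and return ``(best_solution, trace)``.

    Parameters
    ----------
    energy_fn : callable
        Maps a solution to a finite scalar energy (lower is better).
    perturb_fn : callable
        ``perturb_fn(solution, rng)`` proposes a neighbouring solution.
    x0 : object
        Initial solution.
    schedule : AnnealSchedule
        Cooling plan; defaults to T0=1.0, gamma=0.95, 500 iterations.
    rng : numpy.random.Generator
        Source of all randomness; identical generators give
        bit-identical runs.
    """
    schedule = schedule or AnnealSchedule()
    rng = rng if rng is not None else np.random.default_rng()

    current = x0
    current_E = float(energy_fn(x0))
    if not math.isfinite(current_E):
        raise ValueError("energy of the initial solution is not finite")

    best = current
    best_E = current_E
    trace = AnnealTrace()
    T = schedule.T0

    for it in range(schedule.max_iter):
        if T < schedule.T_min:
            break
        proposal = perturb_fn(current, rng)
        prop_E = float(energy_fn(proposal))
        if not math.isfinite(prop_E):
            raise ValueError(f"non-finite energy at iteration {it}")
        delta = prop_E - current_E
        if delta <= 0:
            accept = True
        else:
            accept = rng.random() < acceptance_probability(delta, T)
        if accept:
            current, current_E = proposal, prop_E
            if current_E < best_E:
                best, best_E = current, current_E
        trace.temperature.append(T)
        trace.energy.append(prop_E)
        trace.accepted.append(accept)
        trace.best_energy.append(best_E)
        T = cool(T, schedule.gamma)

    trace.best_solution = best
    trace.final_best_energy = best_E
    return best, trace
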