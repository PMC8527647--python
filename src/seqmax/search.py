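"""Gradient-free baselines: greedy substitution search and simulated annealing.

Both operate directly on one-hot sequences and only require oracle
*predictions* (no gradients).  The greedy baseline ("evolution") proposes 1
or, with 50% probability, 2 random substitutions per step and accepts only
strict improvements.  Simulated annealing proposes 1 substitution per step
and accepts worse candidates with the Metropolis probability
exp(-(P(x) - P(x')) / T) under a geometric cooling schedule, tracking the
best-so-far sequence independently of the current state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Oracle


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling: T_t = initial_temperature * decay**t."""

    initial_temperature: float = 1.0
    decay: float = 0.999
    steps: int = 5000

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0:
            raise ValueError("initial temperature must be > 0")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")

    def temperature(self, t: int) -> float:
        return self.initial_temperature * self.decay**t


def _substitute(x: np.ndarray, pos: int, rng: np.random.Generator) -> None:
    """In-place: replace the symbol at ``pos`` with a uniformly chosen other."""
    m = x.shape[1]
    current = int(np.argmax(x[pos]))
    new = int(rng.integers(m - 1))
    if new >= current:
        new += 1
    x[pos] = 0.0
    x[pos, new] = 1.0


def mutate(
    x: np.ndarray, rng: np.random.Generator, *, n_substitutions: int | None = None
) -> np.ndarray:
    """Random substitution proposal.

    By default applies 1 or, with 50% probability, 2 substitutions at
    distinct uniformly chosen positions, each to a uniformly chosen
    *different* symbol.  ``n_substitutions`` forces a fixed count (simulated
    annealing uses 1).
    """
    n = x.shape[0]
    if n_substitutions is None:
        n_substitutions = 2 if rng.random() < 0.5 else 1
    n_substitutions = min(n_substitutions, n)
    out = np.array(x, dtype=float)
    positions = rng.choice(n, size=n_substitutions, replace=False)
    for pos in positions:
        _substitute(out, int(pos), rng)
    return out


@dataclass
class SearchResult:
    best: np.ndarray
    best_fitness: float
    trajectory: np.ndarray  # best-so-far fitness per step, length steps + 1


def evolution_search(
    oracle: Oracle, x0: np.ndarray, steps: int, rng: np.random.Generator
) -> SearchResult:
    """Greedy pairwise-substitution hill climbing.

    Candidates are accepted only on strict fitness improvement, so the
    trajectory is non-decreasing.  ``steps=0`` returns ``x0`` unchanged.
    """
    x = np.array(x0, dtype=float)
    fitness = float(oracle.predict(x))
    traj = [fitness]
    for _ in range(steps):
        candidate = mutate(x, rng)
        cand_fitness = float(oracle.predict(candidate))
        if cand_fitness > fitness:
            x, fitness = candidate, cand_fitness
        traj.append(fitness)
    return SearchResult(best=x, best_fitness=fitness, trajectory=np.array(traj))


def metropolis_accept(
    p_old: float, p_new: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(-(p_old - p_new) / T))."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if p_new >= p_old:
        return True
    return rng.random() < np.exp(-(p_old - p_new) / temperature)


def simulated_annealing(
    oracle: Oracle,
    x0: np.ndarray,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
) -> SearchResult:
    """Metropolis search with 1 substitution per step under geometric cooling.

    The returned sequence is the best-so-far over the whole walk, not the
    final state, so the reported trajectory is non-decreasing even though
    downhill moves are accepted.
    """
    x = np.array(x0, dtype=float)
    fitness = float(oracle.predict(x))
    best, best_fitness = x.copy(), fitness
    traj = [best_fitness]
    for t in range(schedule.steps):
        candidate = mutate(x, rng, n_substitutions=1)
        cand_fitness = float(oracle.predict(candidate))
        if metropolis_accept(fitness, cand_fitness, schedule.temperature(t), rng):
            x, fitness = candidate, cand_fitness
            if fitness > best_fitness:
                best, best_fitness = x.copy(), fitness
        traj.append(best_fitness)
    return SearchResult(best=best, best_fitness=best_fitness, trajectory=np.array(traj))
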