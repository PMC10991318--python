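"""Hybrid mutation-based white-shark-style swarm optimizer (HMSI).

Population minimizer over a box, combining three ingredients:

* constriction-damped velocity updates pulled toward each member's personal
  best and toward a randomly chosen member's personal best (the "social"
  attractor), with constriction coefficient
  ``eta = 2 / |2 - tau - sqrt(tau^2 - 4 tau)|`` (tau > 4 enforced);
* learning factors m1 = m2 decaying linearly from ``m_max`` to ``m_min``
  over the run, and a constant step scale
  ``f = f_min + (f_max - f_min) / (f_max + f_min)``;
* fitness-adaptive crossover/mutation: each member's probability of uniform
  crossover with the global best and of Gaussian perturbation follows a
  logistic in its fitness quality (good members are perturbed less), with
  greedy acceptance so the search is strictly elitist.

The best-so-far fitness history is monotone non-increasing by construction
and is returned as the convergence-curve artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HMSIConfig",
    "HMSIState",
    "initialize",
    "schedules",
    "adaptive_probability",
    "mutate_crossover",
    "step",
    "optimize",
    "random_search",
    "save_history",
]


@dataclass(frozen=True)
class HMSIConfig:
    dimensions: int
    lower: np.ndarray | float = -2.0
    upper: np.ndarray | float = 2.0
    population_size: int = 30
    max_iterations: int = 100
    tau: float = 4.125
    m_max: float = 2.5
    m_min: float = 0.5
    f_min: float = 0.07
    f_max: float = 0.75
    L_min: float = 0.1
    L_max: float = 0.9
    mutation_sigma: float = 0.1  # fraction of the per-dimension bound range
    seed: int = 0

    def __post_init__(self) -> None:
        lower = np.broadcast_to(np.asarray(self.lower, float), (self.dimensions,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, float), (self.dimensions,)).copy()
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if self.tau <= 4.0:
            raise ValueError("tau must exceed 4 so the constriction root is real")
        if not 0.0 <= self.L_min < self.L_max <= 1.0:
            raise ValueError("need 0 <= L_min < L_max <= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass
class HMSIState:
    positions: np.ndarray       # (a, dim)
    velocities: np.ndarray      # (a, dim)
    fitness: np.ndarray         # (a,)
    pbest_pos: np.ndarray       # (a, dim) personal bests
    pbest_fit: np.ndarray       # (a,)
    best_pos: np.ndarray        # (dim,) global best
    best_fit: float
    iteration: int
    history: list[float]
    rng: np.random.Generator
    n_evaluations: int = 0


def _evaluate(fitness_fn, positions: np.ndarray, state: HMSIState | None) -> np.ndarray:
    vals = np.array([fitness_fn(p) for p in positions], dtype=float)
    if not np.isfinite(vals).all():
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise ValueError(f"fitness_fn returned a non-finite value for member {bad}")
    if state is not None:
        state.n_evaluations += len(vals)
    return vals


def initialize(fitness_fn, config: HMSIConfig) -> HMSIState:
    """Uniform random population within the box; velocities zero."""
    rng = np.random.default_rng(config.seed)
    span = config.upper - config.lower
    positions = config.lower + rng.random((config.population_size, config.dimensions)) * span
    state = HMSIState(
        positions=positions,
        velocities=np.zeros_like(positions),
        fitness=np.empty(config.population_size),
        pbest_pos=positions.copy(),
        pbest_fit=np.empty(config.population_size),
        best_pos=positions[0].copy(),
        best_fit=np.inf,
        iteration=0,
        history=[],
        rng=rng,
    )
    state.fitness = _evaluate(fitness_fn, positions, state)
    state.pbest_fit = state.fitness.copy()
    ibest = int(np.argmin(state.fitness))
    state.best_pos = positions[ibest].copy()
    state.best_fit = float(state.fitness[ibest])
    state.history.append(state.best_fit)
    return state


def schedules(h: int, config: HMSIConfig) -> tuple[float, float, float, float]:
    """(m1, m2, f, eta) at iteration ``h`` of ``max_iterations``."""
    R = config.max_iterations
    if not 0 <= h <= R:
        raise ValueError(f"iteration {h} outside [0, {R}]")
    m = config.m_max - (config.m_max - config.m_min) * h / R
    f = config.f_min + (config.f_max - config.f_min) / (config.f_max + config.f_min)
    tau = config.tau
    eta = 2.0 / abs(2.0 - tau - np.sqrt(tau * tau - 4.0 * tau))
    return m, m, f, eta


def adaptive_probability(
    K_prime: float, K_avg: float, K_max: float, config: HMSIConfig
) -> float:
    """Crossover/mutation probability from a member's fitness quality.

    Quality K is the negated loss, so the best member has K = K_max.  Members
    at or above average quality get a logistic-shaped probability between
    L_min and L_max (the better, the smaller); below-average members get
    L_max outright.
    """
    if K_max <= K_avg:
        return config.L_max
    if K_prime >= K_avg:
        p = config.L_min + (config.L_max - config.L_min) / (
            1.0 + np.exp((K_prime - K_avg) / (K_max - K_avg))
        )
        return float(np.clip(p, config.L_min, config.L_max))
    return config.L_max


def mutate_crossover(
    state: HMSIState, probabilities: np.ndarray, fitness_fn, config: HMSIConfig
) -> None:
    """Per-member uniform crossover with the global best and Gaussian mutation.

    Candidates replace the member only on fitness improvement (greedy
    acceptance), so the global best can never be lost.
    """
    rng = state.rng
    span = config.upper - config.lower
    for i in range(config.population_size):
        p = probabilities[i]
        if rng.random() < p:  # crossover with the global best
            mask = rng.random(config.dimensions) < 0.5
            cand = np.where(mask, state.best_pos, state.positions[i])
            val = _evaluate(fitness_fn, cand[None, :], state)[0]
            if val < state.fitness[i]:
                state.positions[i] = cand
                state.fitness[i] = val
        if rng.random() < p:  # Gaussian mutation
            noise = rng.normal(0.0, config.mutation_sigma, config.dimensions) * span
            cand = np.clip(state.positions[i] + noise, config.lower, config.upper)
            val = _evaluate(fitness_fn, cand[None, :], state)[0]
            if val < state.fitness[i]:
                state.positions[i] = cand
                state.fitness[i] = val


def step(state: HMSIState, fitness_fn, config: HMSIConfig) -> HMSIState:
    """One iteration: velocity/position update, adaptive operators, elitism."""
    rng = state.rng
    a = config.population_size
    m1, m2, f, eta = schedules(state.iteration, config)
    beta = np.minimum((a * rng.random(a)).astype(int) + 1, a) - 1  # member index
    x1 = rng.random((a, config.dimensions))
    x2 = rng.random((a, config.dimensions))
    social = state.pbest_pos[beta]
    state.velocities = eta * (
        state.velocities
        + m1 * (state.pbest_pos - state.positions) * x1
        + m2 * (social - state.positions) * x2
    )
    state.positions = np.clip(
        state.positions + f * state.velocities, config.lower, config.upper
    )
    state.fitness = _evaluate(fitness_fn, state.positions, state)

    quality = -state.fitness
    K_avg, K_max = float(quality.mean()), float(quality.max())
    probs = np.array(
        [adaptive_probability(float(q), K_avg, K_max, config) for q in quality]
    )
    mutate_crossover(state, probs, fitness_fn, config)

    improved = state.fitness < state.pbest_fit
    state.pbest_pos[improved] = state.positions[improved]
    state.pbest_fit[improved] = state.fitness[improved]
    ibest = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[ibest] < state.best_fit:
        state.best_fit = float(state.pbest_fit[ibest])
        state.best_pos = state.pbest_pos[ibest].copy()
    state.iteration += 1
    state.history.append(state.best_fit)
    return state


def optimize(
    fitness_fn, config: HMSIConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the full loop; returns (best_vector, best_fitness, history).

    ``history`` has length ``max_iterations + 1`` (initial population best
    plus one entry per iteration) and is monotone non-increasing.
    """
    state = initialize(fitness_fn, config)
    for _ in range(config.max_iterations):
        step(state, fitness_fn, config)
    return state.best_pos.copy(), state.best_fit, np.asarray(state.history)


def random_search(
    fitness_fn, config: HMSIConfig, n_evaluations: int
) -> tuple[np.ndarray, float]:
    """Uniform random sampling in the box with the same evaluation budget;
    the paired baseline for benchmark comparisons."""
    rng = np.random.default_rng(config.seed)
    span = config.upper - config.lower
    best_pos, best_fit = None, np.inf
    chunk = 256
    remaining = n_evaluations
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        pts = config.lower + rng.random((m, config.dimensions)) * span
        vals = np.array([fitness_fn(p) for p in pts])
        i = int(np.argmin(vals))
        if vals[i] < best_fit:
            best_fit = float(vals[i])
            best_pos = pts[i].copy()
    return best_pos, best_fit


def save_history(history: np.ndarray, path: str | Path) -> None:
    """Two-column CSV (iteration, best_fitness) for convergence plots."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("iteration,best_fitness\n")
        for i, v in enumerate(np.asarray(history)):
            fh.write(f"{i},{float(v)!r}\n")
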