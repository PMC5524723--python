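"""Particle swarm optimization with a linearly decaying inertia weight.

A swarm of N particles moves through a bounded box; each particle carries a
position x, a velocity v, and its personal best p; the swarm shares a global
best g.  Per iteration k (1-based) and dimension m:

    v ← ω(k)·v + c1·r1·(p − x)/Δt + c2·r2·(g − x)/Δt,   r1, r2 ~ U[0,1]
    x ← x + v·Δt

with velocities clamped to [−v_max, v_max], positions clipped to the box
(the clipped component's velocity is zeroed), and the inertia decaying
linearly, ω(k) = ω_max − (ω_max − ω_min)·k/T_max.  Defaults are the common
variance-maximization setting: N=10, T_max=100, c1=c2=2, ω 0.9→0.4,
v_max=5, search box [0.1, 9.9]².

The optimizer maximizes.  Positions are initialized uniformly over the box
from a seeded NumPy generator and velocities start at zero, so a (seed,
config, fitness) triple fully determines the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["PSOConfig", "PSOResult", "update_velocity", "update_position", "optimize"]


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of a PSO run. See module docstring for semantics."""

    swarm_size: int = 10
    max_iter: int = 100
    c1: float = 2.0
    c2: float = 2.0
    inertia_max: float = 0.9
    inertia_min: float = 0.4
    v_max: float = 5.0
    bounds: tuple[tuple[float, float], ...] = ((0.1, 9.9), (0.1, 9.9))
    seed: int = 0
    time_step: float = 1.0

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.max_iter < 1:
            raise InvalidParameterError("swarm_size and max_iter must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise InvalidParameterError("acceleration constants must be nonnegative")
        if self.inertia_min > self.inertia_max:
            raise InvalidParameterError("inertia_min must not exceed inertia_max")
        if not self.v_max > 0:
            raise InvalidParameterError("v_max must be positive")
        if not self.time_step > 0:
            raise InvalidParameterError("time_step must be positive")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(bounds) == 0 or any(hi < lo for lo, hi in bounds):
            raise InvalidParameterError(f"bounds must be nonempty intervals, got {bounds}")
        object.__setattr__(self, "bounds", bounds)

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])


@dataclass(frozen=True)
class PSOResult:
    """Outcome of a seeded PSO run.

    ``fitness_trace`` holds the best-so-far fitness after each iteration and
    is nondecreasing; ``best_fitness`` equals its final entry.
    """

    best_position: np.ndarray
    best_fitness: float
    fitness_trace: tuple[float, ...]
    iterations_run: int
    seed: int


def _check_dim(config: PSOConfig, *vectors: np.ndarray) -> None:
    for vec in vectors:
        if vec.shape != (config.dim,):
            raise InvalidParameterError(
                f"expected vectors of shape ({config.dim},), got {vec.shape}"
            )


def update_velocity(
    v: np.ndarray,
    x: np.ndarray,
    p_best: np.ndarray,
    g_best: np.ndarray,
    inertia: float,
    config: PSOConfig,
    random_draws: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """One velocity update, with independent draws per dimension and clamping."""
    v = np.asarray(v, dtype=float)
    x = np.asarray(x, dtype=float)
    p_best = np.asarray(p_best, dtype=float)
    g_best = np.asarray(g_best, dtype=float)
    _check_dim(config, v, x, p_best, g_best)
    r1, r2 = (np.asarray(r, dtype=float) for r in random_draws)
    _check_dim(config, r1, r2)
    dt = config.time_step
    new_v = (
        inertia * v
        + config.c1 * r1 * (p_best - x) / dt
        + config.c2 * r2 * (g_best - x) / dt
    )
    return np.clip(new_v, -config.v_max, config.v_max)


def update_position(
    x: np.ndarray, v: np.ndarray, config: PSOConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a position by v·Δt, clip to bounds, zero clipped velocities."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dim(config, x, v)
    new_x = x + v * config.time_step
    clipped = np.clip(new_x, config.lower, config.upper)
    new_v = np.where(clipped == new_x, v, 0.0)
    return clipped, new_v


def optimize(fitness, config: PSOConfig) -> PSOResult:
    """Run PSO maximizing ``fitness`` over the configured box.

    Exactly ``max_iter`` iterations are run (no early stopping); the trace
    lets callers inspect convergence.  Errors raised by ``fitness`` are
    propagated with the offending position attached as a note.
    """
    rng = np.random.default_rng(config.seed)
    n, dim = config.swarm_size, config.dim
    lower, upper = config.lower, config.upper

    def evaluate(pos: np.ndarray) -> float:
        try:
            return float(fitness(pos))
        except Exception as exc:  # re-raise with context for debugging
            exc.add_note(f"fitness evaluation failed at position {pos.tolist()}")
            raise

    positions = lower + rng.random((n, dim)) * (upper - lower)
    velocities = np.zeros((n, dim))
    p_best = positions.copy()
    p_best_fit = np.array([evaluate(positions[i]) for i in range(n)])
    g_idx = int(np.argmax(p_best_fit))
    g_best = p_best[g_idx].copy()
    g_best_fit = float(p_best_fit[g_idx])

    trace: list[float] = []
    for k in range(1, config.max_iter + 1):
        inertia = config.inertia_max - (
            config.inertia_max - config.inertia_min
        ) * k / config.max_iter
        for i in range(n):
            draws = (rng.random(dim), rng.random(dim))
            velocities[i] = update_velocity(
                velocities[i], positions[i], p_best[i], g_best, inertia, config, draws
            )
            positions[i], velocities[i] = update_position(
                positions[i], velocities[i], config
            )
            fit = evaluate(positions[i])
            if fit > p_best_fit[i]:
                p_best_fit[i] = fit
                p_best[i] = positions[i].copy()
                if fit > g_best_fit:
                    g_best_fit = fit
                    g_best = positions[i].copy()
        trace.append(g_best_fit)

    return PSOResult(
        best_position=g_best,
        best_fitness=g_best_fit,
        fitness_trace=tuple(trace),
        iterations_run=config.max_iter,
        seed=config.seed,
    )
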