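"""Particle swarm optimization (global-best topology).

Velocity update for particle m, dimension n at step t+1:

    V(t+1) = w(t) V(t) + c1 r1 (pbest - H(t)) + c2 r2 (gbest - H(t))
    H(t+1) = H(t) + V(t+1)

with r1, r2 drawn i.i.d. uniform on [0, 1] per particle and dimension.
The inertia weight ``w`` defaults to 1 (the bare update with no damping
on the previous velocity); because that variant never dissipates kinetic
energy, velocities are clamped per dimension to the width of the search
box, and a configurable constant or linearly decaying inertia is exposed
for callers that need tight convergence.  Positions are clipped to the
box after each move and the velocity component of any clipped dimension
is zeroed, which prevents particles sticking to a boundary at full
speed.

Minimization convention throughout; wrap an objective in a negation to
maximize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SwarmConfig", "SwarmState", "PsoResult", "init_swarm", "pso_minimize"]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters and the search box."""

    n_particles: int
    bounds: tuple[tuple[float, float], ...]
    cognitive: float = 1.5  # weight on the pull toward a particle's own best
    social: float = 1.5  # weight on the pull toward the swarm best
    inertia: float = 1.0
    inertia_final: float | None = None  # linear decay target; None = constant
    max_iters: int = 100
    init_velocity_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("cognitive and social factors must be >= 0")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if not bounds:
            raise ValueError("bounds must be non-empty")
        for lo, hi in bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): need lo < hi")
        object.__setattr__(self, "bounds", bounds)

    @property
    def dims(self) -> int:
        return len(self.bounds)

    def _lo_hi(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=float)
        return b[:, 0], b[:, 1]


@dataclass
class SwarmState:
    """Mutable swarm state at one iteration."""

    positions: np.ndarray  # z x n
    velocities: np.ndarray  # z x n
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # z
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    history: list = field(default_factory=list)  # gbest fitness per iteration


@dataclass(frozen=True)
class PsoResult:
    x: np.ndarray
    fun: float
    history: np.ndarray  # gbest fitness after each iteration (incl. init)
    state: SwarmState


def init_swarm(config: SwarmConfig, rng: np.random.Generator | None = None) -> SwarmState:
    """Uniform positions in the box; velocities uniform in a scaled box width.

    The personal bests start at the initial positions with fitness +inf
    (they are evaluated on the first iteration of :func:`pso_minimize`).
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config._lo_hi()
    span = hi - lo
    z, n = config.n_particles, config.dims
    positions = rng.uniform(lo, hi, size=(z, n))
    vmax = config.init_velocity_fraction * span
    velocities = rng.uniform(-vmax, vmax, size=(z, n))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=np.full(z, np.inf),
        gbest_position=positions[0].copy(),
        gbest_fitness=np.inf,
    )


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(
                f"objective returned non-finite value {v!r} at position {x.tolist()}"
            )
        vals[i] = v
    return vals


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    config: SwarmConfig,
    callback: Callable[[SwarmState], None] | None = None,
) -> PsoResult:
    """Minimize ``objective`` over the config's box.

    Returns the best position and fitness found, plus the global-best
    trace (monotone non-increasing by construction).  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    state = init_swarm(config, rng)
    lo, hi = config._lo_hi()
    span = hi - lo

    w0 = config.inertia
    w1 = config.inertia_final if config.inertia_final is not None else w0

    for t in range(config.max_iters):
        fitness = _evaluate(objective, state.positions)
        improved = fitness < state.pbest_fitness
        state.pbest_fitness = np.where(improved, fitness, state.pbest_fitness)
        state.pbest_positions = np.where(
            improved[:, None], state.positions, state.pbest_positions
        )
        best = int(np.argmin(state.pbest_fitness))
        if state.pbest_fitness[best] < state.gbest_fitness:
            state.gbest_fitness = float(state.pbest_fitness[best])
            state.gbest_position = state.pbest_positions[best].copy()
        state.history.append(state.gbest_fitness)
        state.iteration = t + 1
        if callback is not None:
            callback(state)
        if t == config.max_iters - 1:
            break

        frac = t / max(config.max_iters - 1, 1)
        w = w0 + (w1 - w0) * frac
        r1 = rng.uniform(size=state.positions.shape)
        r2 = rng.uniform(size=state.positions.shape)
        state.velocities = (
            w * state.velocities
            + config.cognitive * r1 * (state.pbest_positions - state.positions)
            + config.social * r2 * (state.gbest_position[None, :] - state.positions)
        )
        np.clip(state.velocities, -span, span, out=state.velocities)
        proposed = state.positions + state.velocities
        clipped = np.clip(proposed, lo, hi)
        state.velocities[proposed != clipped] = 0.0
        state.positions = clipped

    return PsoResult(
        x=state.gbest_position.copy(),
        fun=state.gbest_fitness,
        history=np.asarray(state.history),
        state=state,
    )
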