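"""Particle swarm optimization of the network's weights and thresholds.

Velocity/position updates follow the canonical inertia-weight form

    v <- omega * v + c1 * rand() * (pbest - x) + c2 * rand() * (gbest - x)
    x <- x + v

with rand() drawn per dimension, velocities clamped to a fraction of the
search-box width and positions clipped to the box. Fitness is minimized;
the global best is therefore non-increasing by construction. The hybrid
trainer runs PSO over the flattened network parameters (fitness =
training-set MSE) and then fine-tunes the best network with schedule-driven
gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bpnn import BPNNModel, LRSchedule, TrainingTrace, init_bpnn, mse_loss, train_gd

__all__ = [
    "SwarmConfig",
    "Swarm",
    "init_swarm",
    "pso_step",
    "optimize",
    "pso_train_bpnn",
    "flatten_model",
    "unflatten_model",
]

Fitness = Callable[[np.ndarray], float]


@dataclass
class SwarmConfig:
    n_particles: int = 30
    omega: float = 0.2
    c1: float = 1.4
    c2: float = 2.0
    max_iterations: int = 100
    bounds: float = 2.0            # symmetric box [-bounds, bounds] per dimension
    velocity_clamp: float = 0.5    # fraction of the box width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 < self.omega <= 1:
            raise ValueError("omega must lie in (0, 1]")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration factors must be >= 0")
        if not np.isfinite(self.bounds) or self.bounds <= 0:
            raise ValueError("bounds must be finite and positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass
class Swarm:
    positions: np.ndarray        # (N, dim)
    velocities: np.ndarray       # (N, dim)
    pbest: np.ndarray            # (N, dim)
    pbest_fitness: np.ndarray    # (N,)
    gbest: np.ndarray            # (dim,)
    gbest_fitness: float
    iteration: int = 0


def _evaluate(fitness: Fitness, positions: np.ndarray) -> np.ndarray:
    vals = np.array([fitness(p) for p in positions], dtype=float)
    bad = np.flatnonzero(np.isnan(vals))
    if bad.size:
        raise ValueError(f"fitness returned NaN for particle {bad[0]}")
    return vals


def init_swarm(
    dim: int,
    fitness: Fitness,
    config: SwarmConfig,
    rng: np.random.Generator,
    initial_positions: np.ndarray | None = None,
) -> Swarm:
    """Uniform random positions in the box (optionally seeded with given
    rows, e.g. a pre-trained network) and zero initial velocities."""
    b = config.bounds
    positions = rng.uniform(-b, b, (config.n_particles, dim))
    if initial_positions is not None:
        given = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        positions[: given.shape[0]] = np.clip(given, -b, b)
    velocities = np.zeros_like(positions)
    f = _evaluate(fitness, positions)
    best = int(np.argmin(f))
    return Swarm(
        positions=positions,
        velocities=velocities,
        pbest=positions.copy(),
        pbest_fitness=f,
        gbest=positions[best].copy(),
        gbest_fitness=float(f[best]),
    )


def pso_step(
    swarm: Swarm, fitness: Fitness, config: SwarmConfig, rng: np.random.Generator
) -> Swarm:
    """One synchronous velocity/position update with pbest/gbest refresh."""
    n, dim = swarm.positions.shape
    r1 = rng.uniform(size=(n, dim))
    r2 = rng.uniform(size=(n, dim))
    v = (
        config.omega * swarm.velocities
        + config.c1 * r1 * (swarm.pbest - swarm.positions)
        + config.c2 * r2 * (swarm.gbest - swarm.positions)
    )
    vmax = config.velocity_clamp * 2.0 * config.bounds
    v = np.clip(v, -vmax, vmax)
    x = np.clip(swarm.positions + v, -config.bounds, config.bounds)
    f = _evaluate(fitness, x)
    improved = f < swarm.pbest_fitness
    pbest = np.where(improved[:, None], x, swarm.pbest)
    pbest_f = np.where(improved, f, swarm.pbest_fitness)
    best = int(np.argmin(pbest_f))
    gbest, gbest_f = swarm.gbest, swarm.gbest_fitness
    if pbest_f[best] < gbest_f:
        gbest, gbest_f = pbest[best].copy(), float(pbest_f[best])
    return Swarm(x, v, pbest, pbest_f, gbest, gbest_f, swarm.iteration + 1)


def optimize(
    fitness: Fitness,
    dim: int,
    config: SwarmConfig,
    initial_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run PSO for max_iterations; returns (gbest position, gbest-fitness
    trace including the initial population's best). The trace is
    non-increasing by the definition of the global best."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(dim, fitness, config, rng, initial_positions)
    trace = [swarm.gbest_fitness]
    for _ in range(config.max_iterations):
        swarm = pso_step(swarm, fitness, config, rng)
        trace.append(swarm.gbest_fitness)
    return swarm.gbest.copy(), np.array(trace)


def flatten_model(model: BPNNModel) -> np.ndarray:
    """Particle encoding: concatenation of all weights and thresholds."""
    return np.concatenate(
        [
            model.hidden_weights.ravel(),
            model.hidden_thresholds,
            model.output_weights.ravel(),
            model.output_thresholds,
        ]
    )


def unflatten_model(
    vector: np.ndarray, m: int, h: int, n: int, output_activation: str
) -> BPNNModel:
    v = np.asarray(vector, dtype=float)
    expected = m * h + h + h * n + n
    if v.size != expected:
        raise ValueError(f"vector length {v.size} != parameter count {expected}")
    i = 0
    w1 = v[i : i + m * h].reshape(m, h); i += m * h
    b1 = v[i : i + h].copy(); i += h
    w2 = v[i : i + h * n].reshape(h, n); i += h * n
    b2 = v[i : i + n].copy()
    return BPNNModel(w1.copy(), b1, w2.copy(), b2, output_activation)


def pso_train_bpnn(
    features: np.ndarray,
    targets: np.ndarray,
    topology: tuple[int, int, int],
    swarm_config: SwarmConfig,
    schedule: LRSchedule,
    gd_epochs: int,
    seed: int = 0,
    output_activation: str = "sigmoid",
    initial_model: BPNNModel | None = None,
) -> tuple[BPNNModel, np.ndarray, TrainingTrace | None]:
    """PSO global search over network parameters, then gradient-descent
    refinement of the best particle.

    Fitness is the training-set MSE of the decoded network (never the test
    set). Returns (model, PSO gbest-fitness trace, GD trace or None when
    gd_epochs == 0).
    """
    m, h, n = topology
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != m:
        raise ValueError(f"feature width {x.shape[1]} != input layer size {m}")

    def fitness(vec: np.ndarray) -> float:
        return mse_loss(unflatten_model(vec, m, h, n, output_activation), x, targets)

    init = None
    if initial_model is None:
        initial_model = init_bpnn(m, h, n, output_activation, seed=seed)
    init = flatten_model(initial_model)[None, :]
    cfg = SwarmConfig(**{**swarm_config.__dict__, "seed": seed})
    gbest, trace = optimize(fitness, init.shape[1], cfg, initial_positions=init)
    model = unflatten_model(gbest, m, h, n, output_activation)
    if gd_epochs == 0:
        return model, trace, None
    model, gd_trace = train_gd(model, x, targets, schedule, epochs=gd_epochs)
    return model, trace, gd_trace
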