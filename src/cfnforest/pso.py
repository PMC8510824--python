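"""Particle swarm optimization of FNT parameter vectors.

Each particle is a candidate parameter vector for a fixed tree topology.
Velocities follow v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x) with
componentwise clamping to [-v_max, v_max], positions follow x <- x + v.
r1, r2 are fresh U(0,1) draws per dimension per particle per update (the
convention that explores all coordinate directions; scalar draws, which
confine each move to the span of three vectors, are available via
``per_dimension=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fnt import FlexibleNeuralTree, fitness

__all__ = ["PSOConfig", "Particle", "update_velocity", "update_position",
           "minimize", "optimize_params"]

logger = logging.getLogger(__name__)


@dataclass
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 50
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    v_max: float = 4.0
    per_dimension: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    p_best_position: np.ndarray
    p_best_fitness: float

    def __post_init__(self) -> None:
        if not (self.position.shape == self.velocity.shape == self.p_best_position.shape):
            raise ValueError("particle vectors must have equal shapes")


def update_velocity(
    p: Particle, g_best: np.ndarray, cfg: PSOConfig, rng: np.random.Generator
) -> np.ndarray:
    """New (clamped) velocity for one particle; does not mutate the particle."""
    if g_best.shape != p.position.shape:
        raise ValueError("g_best dimension differs from particle dimension")
    shape = p.position.shape if cfg.per_dimension else ()
    r1 = rng.uniform(0.0, 1.0, size=shape)
    r2 = rng.uniform(0.0, 1.0, size=shape)
    v = (
        cfg.inertia * p.velocity
        + cfg.c1 * r1 * (p.p_best_position - p.position)
        + cfg.c2 * r2 * (g_best - p.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: Particle) -> np.ndarray:
    """x + v, no clamping of the position itself."""
    return p.position + p.velocity


def minimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the swarm on an arbitrary objective, seeded around ``x0``.

    One particle starts exactly at ``x0``; the rest at x0 + U(-1,1)
    perturbations. Returns (g_best position, g_best fitness, per-iteration
    g_best trace including the initial evaluation).
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    particles: list[Particle] = []
    for i in range(cfg.swarm_size):
        pos = x0.copy() if i == 0 else x0 + rng.uniform(-1.0, 1.0, size=dim)
        # zero initial velocity: the first moves are purely attraction-driven,
        # which refines the incumbent instead of scattering the swarm
        vel = np.zeros(dim)
        fit = float(objective(pos))
        particles.append(Particle(pos, vel, pos.copy(), fit))
    g_idx = int(np.argmin([p.p_best_fitness for p in particles]))
    g_best = particles[g_idx].p_best_position.copy()
    g_fit = particles[g_idx].p_best_fitness
    trace = [g_fit]
    for it in range(cfg.iterations):
        for p in particles:
            p.velocity = update_velocity(p, g_best, cfg, rng)
            p.position = update_position(p)
            fit = float(objective(p.position))
            if fit < p.p_best_fitness:
                p.p_best_fitness = fit
                p.p_best_position = p.position.copy()
                if fit < g_fit:
                    g_fit = fit
                    g_best = p.position.copy()
        trace.append(g_fit)
        logger.debug("pso iteration %d g_best fitness %.6g", it + 1, g_fit)
    return g_best, g_fit, trace


def optimize_params(
    tree: FlexibleNeuralTree,
    X: np.ndarray,
    y: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> FlexibleNeuralTree:
    """Refine a tree's weights/biases in place of its current values.

    The swarm is initialized around the incumbent parameter vector so PSO
    refines rather than restarts. Returns the tree with the best-found
    parameters installed; its fitness never exceeds the input tree's.
    """
    if tree.n_params == 0:
        logger.info("tree has no parameters (single leaf); PSO skipped")
        return tree.copy()
    if cfg.iterations == 0:
        return tree.copy()
    x0 = tree.flatten_params()

    def objective(v: np.ndarray) -> float:
        return fitness(tree.set_params(v), X, y)

    best, _, _ = minimize(objective, x0, cfg, rng)
    return tree.set_params(best)
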