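"""Discrete binary particle swarm optimization over 15-bit genomes.

Particles keep a real-valued velocity per bit; positions are resampled each
iteration as Bernoulli draws with probability sigmoid(velocity).  Social
information flows through a ring topology (each particle sees only its two
adjacent neighbors), which deliberately slows convergence and preserves
diversity on multimodal landscapes.  The inertia weight decays
multiplicatively (9% every five iterations) from 0.9 down to a floor of 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import N_BITS, random_genome, repair
from .evaluation import diversity
from .ga_optimizer import OptimizerTrace

__all__ = [
    "PSOParams",
    "inertia",
    "ring_neighbors",
    "update_velocity",
    "update_position",
    "run_pso",
]


@dataclass(frozen=True)
class PSOParams:
    swarm_size: int = 15
    c1: float = 0.6  # cognitive weight
    c2: float = 0.3  # social weight
    omega0: float = 0.9
    omega_min: float = 0.4
    omega_decay: float = 0.91  # multiplier applied every 5 iterations
    max_iterations: int = 20
    patience: int = 15
    v_max: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if self.omega0 < self.omega_min:
            raise ValueError("omega0 must be >= omega_min")
        if self.swarm_size < 3:
            raise ValueError("a ring topology needs at least 3 particles")


def inertia(i: int, params: PSOParams = PSOParams()) -> float:
    """Inertia weight at iteration i (1-indexed), floored at omega_min."""
    if i < 1:
        raise ValueError("iterations are 1-indexed")
    return max(params.omega_min, params.omega0 * params.omega_decay ** ((i - 1) // 5))


def ring_neighbors(index: int, swarm_size: int) -> tuple[int, int]:
    """The two adjacent particles of ``index`` on the ring."""
    if swarm_size < 3:
        raise ValueError("ring topology requires swarm_size >= 3")
    return ((index - 1) % swarm_size, (index + 1) % swarm_size)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_velocity(
    v: np.ndarray,
    x: np.ndarray,
    p: np.ndarray,
    l: np.ndarray,
    omega: float,
    params: PSOParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """v' = omega*v + c1*r1*(p - x) + c2*r2*(l - x), clamped to [-v_max, v_max]."""
    r1 = rng.random(N_BITS)
    r2 = rng.random(N_BITS)
    v_new = omega * v + params.c1 * r1 * (p - x) + params.c2 * r2 * (l - x)
    return np.clip(v_new, -params.v_max, params.v_max)


def update_position(velocity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample each bit as 1 with probability sigmoid(velocity)."""
    return (rng.random(len(velocity)) < _sigmoid(velocity)).astype(int)


def run_pso(
    fitness_fn,
    params: PSOParams = PSOParams(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, OptimizerTrace]:
    """Maximize ``fitness_fn`` over valid genomes with ring-topology binary PSO."""
    rng = rng or np.random.default_rng(params.seed)
    z = params.swarm_size

    def evaluate(genome):
        f = float(fitness_fn(genome))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness for genome {genome.tolist()}")
        return f

    x = [random_genome(rng) for _ in range(z)]
    v = [rng.uniform(-1.0, 1.0, size=N_BITS) for _ in range(z)]
    fit = np.array([evaluate(g) for g in x])
    evaluations = z
    pbest = [g.copy() for g in x]
    pbest_fit = fit.copy()

    def local_best(k: int) -> np.ndarray:
        left, right = ring_neighbors(k, z)
        candidates = (k, left, right)
        best = max(candidates, key=lambda c: pbest_fit[c])
        return pbest[best]

    gbest_idx = int(np.argmax(pbest_fit))
    gbest = pbest[gbest_idx].copy()
    gbest_fit = float(pbest_fit[gbest_idx])

    trace = OptimizerTrace()
    trace.record(0, gbest_fit, diversity(x), evaluations, gbest)
    patience = 0

    for i in range(1, params.max_iterations + 1):
        if patience >= params.patience:
            break
        omega = inertia(i, params)
        for k in range(z):
            v[k] = update_velocity(v[k], x[k], pbest[k], local_best(k), omega, params, rng)
        for k in range(z):
            x[k] = repair(update_position(v[k], rng), rng)
            fit[k] = evaluate(x[k])
            if fit[k] > pbest_fit[k]:
                pbest_fit[k] = fit[k]
                pbest[k] = x[k].copy()
        evaluations += z
        best_now = int(np.argmax(pbest_fit))
        if pbest_fit[best_now] > gbest_fit:
            gbest_fit = float(pbest_fit[best_now])
            gbest = pbest[best_now].copy()
            patience = 0
        else:
            patience += 1
        trace.record(i, gbest_fit, diversity(x), evaluations, gbest)

    return gbest, trace
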