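"""Genetic algorithm over 15-bit architecture genomes.

Tournament-of-two selection without replacement, two-point crossover
(producing one offspring), scheduled bit-flip mutation, two-elite survival,
and patience-based stopping.  The initial population's evaluation counts as
generation 1, so a full run of G = 20 generations with z = 15 costs exactly
300 fitness evaluations.

Each offspring round varies z - 2 genomes (crossover or tournament cloning,
then mutation, then repair) and carries the two elites over unmutated — the
expected mutation count per round is therefore m(g) * (z - 2) * N_bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import N_BITS, random_genome, repair
from .evaluation import diversity

__all__ = [
    "GAParams",
    "OptimizerTrace",
    "mutation_prob",
    "expected_mutations",
    "tournament_select",
    "two_point_crossover",
    "run_ga",
]


@dataclass(frozen=True)
class GAParams:
    z: int = 15  # population size
    max_generations: int = 20  # G
    patience: int = 15  # Pa_max
    crossover_prob: float = 0.9
    m0: float = 0.2  # initial mutation probability
    m_decay: float = 0.7  # multiplier applied every 5 generations
    m_min: float = 0.01
    n_elites: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.z < 3:
            raise ValueError("population size must be >= 3 for tournament selection")
        if self.n_elites >= self.z:
            raise ValueError("n_elites must be smaller than the population size")


@dataclass
class OptimizerTrace:
    """Per-round search history shared by both optimizers."""

    rounds: list[dict] = field(default_factory=list)

    def record(self, round_index, best_fitness, div, evaluations, best_genome):
        self.rounds.append(
            {
                "round": round_index,
                "best_fitness": float(best_fitness),
                "diversity": float(div),
                "evaluations": int(evaluations),
                "best_genome": np.asarray(best_genome, dtype=int).copy(),
            }
        )

    @property
    def best_fitness_per_round(self) -> np.ndarray:
        return np.array([r["best_fitness"] for r in self.rounds])

    @property
    def evaluations(self) -> int:
        return self.rounds[-1]["evaluations"] if self.rounds else 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "round": r["round"],
                    "best_fitness": r["best_fitness"],
                    "diversity": r["diversity"],
                    "evaluations": r["evaluations"],
                    "best_genome": "".join(str(b) for b in r["best_genome"]),
                }
                for r in self.rounds
            ]
        )


def mutation_prob(g: int, params: GAParams = GAParams()) -> float:
    """Mutation probability at generation g: m0 shrunk by m_decay every 5
    generations, floored at m_min."""
    if g < 1:
        raise ValueError("generations are 1-indexed")
    return max(params.m_min, params.m0 * params.m_decay ** ((g - 1) // 5))


def expected_mutations(g: int, params: GAParams = GAParams()) -> float:
    """Expected number of flipped bits per offspring round (elites exempt)."""
    return mutation_prob(g, params) * (params.z - params.n_elites) * N_BITS


def tournament_select(
    population: list[np.ndarray], fitnesses: np.ndarray, rng: np.random.Generator
) -> int:
    """Index of the winner of a tournament of two distinct random members.

    Every member enters a given tournament with marginal probability 2/z;
    ties are broken uniformly at random.
    """
    z = len(population)
    if z < 3:
        raise ValueError("tournament selection requires z >= 3")
    a, b = rng.choice(z, size=2, replace=False)
    if fitnesses[a] > fitnesses[b]:
        return int(a)
    if fitnesses[b] > fitnesses[a]:
        return int(b)
    return int(a if rng.random() < 0.5 else b)


def _select_two_parents(population, fitnesses, rng) -> tuple[int, int]:
    """Two tournament winners, re-running tournaments until they differ."""
    first = tournament_select(population, fitnesses, rng)
    second = first
    while second == first:
        second = tournament_select(population, fitnesses, rng)
    return first, second


def two_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring a[0:i] + b[i:j] + a[j:] with uniform cuts 0 < i < j < 15."""
    if parent_a is parent_b:
        raise ValueError("crossover requires two distinct parent individuals")
    i, j = np.sort(rng.choice(np.arange(1, N_BITS), size=2, replace=False))
    child = np.asarray(parent_a, dtype=int).copy()
    child[i:j] = np.asarray(parent_b, dtype=int)[i:j]
    return child


def _mutate(genome: np.ndarray, m: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(N_BITS) < m
    out = genome.copy()
    out[flips] = 1 - out[flips]
    return out


def run_ga(
    fitness_fn,
    params: GAParams = GAParams(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, OptimizerTrace]:
    """Maximize ``fitness_fn`` (genome -> real) over valid 15-bit genomes."""
    rng = rng or np.random.default_rng(params.seed)
    z, n_el = params.z, params.n_elites

    def evaluate(genome):
        f = float(fitness_fn(genome))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness for genome {genome.tolist()}")
        return f

    population = [random_genome(rng) for _ in range(z)]
    fitnesses = np.array([evaluate(g) for g in population])
    evaluations = z
    order = np.argsort(-fitnesses, kind="stable")
    population = [population[k] for k in order]
    fitnesses = fitnesses[order]

    trace = OptimizerTrace()
    trace.record(1, fitnesses[0], diversity(population), evaluations, population[0])
    best_fitness = fitnesses[0]
    patience = 0

    for g in range(2, params.max_generations + 1):
        if patience >= params.patience:
            break
        m = mutation_prob(g, params)
        offspring = []
        for _ in range(z - n_el):
            if rng.random() < params.crossover_prob:
                ia, ib = _select_two_parents(population, fitnesses, rng)
                child = two_point_crossover(population[ia], population[ib], rng)
            else:
                child = population[tournament_select(population, fitnesses, rng)].copy()
            offspring.append(repair(_mutate(child, m, rng), rng))
        # the two elites ride along unmutated (their re-evaluation keeps the
        # per-round budget at exactly z)
        offspring += [population[k].copy() for k in range(n_el)]
        off_fitnesses = np.array([evaluate(q) for q in offspring])
        evaluations += z

        # pool P without its elites with Q, keep the best z - 2, reinsert elites
        pool = population[n_el:] + offspring
        pool_fit = np.concatenate([fitnesses[n_el:], off_fitnesses])
        keep = np.argsort(-pool_fit, kind="stable")[: z - n_el]
        new_pop = [population[k].copy() for k in range(n_el)] + [pool[k] for k in keep]
        new_fit = np.concatenate([fitnesses[:n_el], pool_fit[keep]])
        order = np.argsort(-new_fit, kind="stable")
        population = [new_pop[k] for k in order]
        fitnesses = new_fit[order]

        if fitnesses[0] > best_fitness:
            best_fitness = fitnesses[0]
            patience = 0
        else:
            patience += 1
        trace.record(g, fitnesses[0], diversity(population), evaluations, population[0])

    return population[0].copy(), trace
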