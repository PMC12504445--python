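"""Spider-wasp population metaheuristic for bounded continuous search.

One generation cycles through four phases (minimisation throughout):

1. *Exploration / tracking* — the worst 70% of agents by fitness rank take
   large uniform steps inside the bounds (searchers); the best 30% move
   toward the current best with a random convex step (followers).
2. *Local analysis / nesting* — the top 10% (elites) each get a single
   randomly chosen dimension perturbed by a heavy-tailed Cauchy step
   (scale = 1% of the dimension range), clipped to bounds.
3. *Diversity maintenance* — the worst 20% are culled and rebuilt by
   per-dimension inheritance from two fitness-proportional parents; a few
   offspring receive differential mutation x + F (a - b), F = 0.5.
4. *Termination* — the loop stops when the best-ever fitness has not
   improved (by more than 1e-8) for ``patience`` generations, or the
   generation budget is exhausted.

Initialisation uses Latin hypercube sampling: per dimension, exactly one
agent per equal-width interval of the n-way partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class SWOConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SWOConfig:
    bounds: tuple[tuple[float, float], ...]
    population: int = 30
    search_fraction: float = 0.70
    follow_fraction: float = 0.30
    elite_fraction: float = 0.10
    cull_fraction: float = 0.20
    inherit_prob: float = 0.5
    n_mutants: int | None = None  # default max(1, 10% of population)
    mutation_factor: float = 0.5
    search_step: float = 0.25  # step scale as a fraction of each range
    cauchy_scale: float = 0.01  # elite perturbation scale, fraction of range
    patience: int = 10
    max_generations: int = 100
    improvement_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise SWOConfigError("population must be >= 1")
        if abs(self.search_fraction + self.follow_fraction - 1.0) > 1e-9:
            raise SWOConfigError("search_fraction + follow_fraction must equal 1")
        if not 0 < self.inherit_prob < 1:
            raise SWOConfigError("inherit_prob must be in (0, 1)")
        if self.cull_fraction >= 1:
            raise SWOConfigError("cull_fraction must be < 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise SWOConfigError("each bound must satisfy low < high")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def highs(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def effective_mutants(self) -> int:
        if self.n_mutants is not None:
            return self.n_mutants
        return max(1, int(round(0.10 * self.population)))


@dataclass
class Agent:
    position: np.ndarray
    fitness: float = np.inf


@dataclass
class SWOResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    generations: int = 0
    evaluations: int = 0


def _clip(pos: np.ndarray, config: SWOConfig) -> np.ndarray:
    return np.clip(pos, config.lows, config.highs)


def lhs_init(config: SWOConfig, rng: np.random.Generator | None = None) -> list[Agent]:
    """Latin hypercube initialisation: one agent per interval per dimension."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, d = config.population, config.dim
    positions = np.empty((n, d))
    for j in range(d):
        lo, hi = config.bounds[j]
        edges = np.linspace(lo, hi, n + 1)
        samples = edges[:-1] + rng.uniform(size=n) * (edges[1:] - edges[:-1])
        positions[:, j] = rng.permutation(samples)
    return [Agent(position=positions[i].copy()) for i in range(n)]


def _rank_order(population: list[Agent]) -> np.ndarray:
    """Indices sorted best (lowest fitness) first; ties by agent index."""
    fits = np.array([a.fitness for a in population])
    return np.argsort(fits, kind="stable")


def explore_step(
    population: list[Agent],
    best: Agent,
    config: SWOConfig,
    rng: np.random.Generator,
) -> tuple[list[Agent], np.ndarray]:
    """Search/follow phase.  Returns (population, boolean search-role mask).

    Roles by fitness rank: the worst ``search_fraction`` of agents search
    with large uniform steps; the best ``follow_fraction`` move toward the
    current best by a convex step r (best - position), r ~ U(0, 1).
    """
    n = len(population)
    n_follow = int(round(config.follow_fraction * n))
    order = _rank_order(population)
    follow_set = set(order[:n_follow].tolist())
    search_mask = np.array([i not in follow_set for i in range(n)])
    span = config.highs - config.lows
    for i, agent in enumerate(population):
        if search_mask[i]:
            step = rng.uniform(-1.0, 1.0, size=config.dim) * span * config.search_step
            agent.position = _clip(agent.position + step, config)
        else:
            r = rng.uniform()
            agent.position = _clip(
                agent.position + r * (best.position - agent.position), config
            )
        agent.fitness = np.inf  # stale until re-evaluated
    return population, search_mask


def local_perturb(
    population: list[Agent],
    config: SWOConfig,
    rng: np.random.Generator,
) -> list[Agent]:
    """Perturb one random dimension of each elite agent with a Cauchy step."""
    order = _rank_order(population)
    n_elite = max(1, int(round(config.elite_fraction * len(population))))
    span = config.highs - config.lows
    for i in order[:n_elite]:
        agent = population[i]
        j = int(rng.integers(config.dim))
        step = rng.standard_cauchy() * config.cauchy_scale * span[j]
        pos = agent.position.copy()
        pos[j] = np.clip(pos[j] + step, config.lows[j], config.highs[j])
        agent.position = pos
        agent.fitness = np.inf
    return population


def _fitness_proportional(fits: np.ndarray, rng: np.random.Generator, k: int) -> np.ndarray:
    """Sample k parent indices with probability proportional to
    (worst - fitness + eps) — minimisation-friendly proportional selection."""
    w = fits.max() - fits + 1e-12
    w = w / w.sum()
    return rng.choice(len(fits), size=k, p=w)


def reproduce_and_cull(
    population: list[Agent],
    config: SWOConfig,
    rng: np.random.Generator,
) -> list[Agent]:
    """Cull the worst ``cull_fraction``; rebuild by per-dimension inheritance
    from two fitness-proportional parents, with differential mutation on a
    few offspring.  Population size is conserved."""
    n = len(population)
    n_cull = int(round(config.cull_fraction * n))
    if n_cull == 0:
        return population
    order = _rank_order(population)
    survivors = [population[i] for i in order[: n - n_cull]]
    fits = np.array([a.fitness for a in survivors])
    positions = np.stack([a.position for a in survivors])
    offspring: list[Agent] = []
    for _ in range(n_cull):
        pa, pb = _fitness_proportional(fits, rng, 2)
        take_a = rng.uniform(size=config.dim) < config.inherit_prob
        child = np.where(take_a, positions[pa], positions[pb])
        offspring.append(Agent(position=_clip(child, config)))
    n_mut = min(config.effective_mutants, len(offspring))
    for m in range(n_mut):
        a, b = rng.choice(len(survivors), size=2, replace=False)
        mutated = offspring[m].position + config.mutation_factor * (
            positions[a] - positions[b]
        )
        offspring[m].position = _clip(mutated, config)
    return survivors + offspring


def optimize(objective, config: SWOConfig) -> SWOResult:
    """Full loop: explore -> local perturb -> reproduce/cull until patience
    or the generation budget runs out.  Returns the best-ever agent; the
    fitness trace is monotone non-increasing."""
    rng = np.random.default_rng(config.seed)
    evaluations = 0

    def evaluate(agent: Agent) -> None:
        nonlocal evaluations
        value = objective(agent.position)
        evaluations += 1
        if not np.isfinite(value):
            warnings.warn("objective returned non-finite value; assigning worst fitness")
            value = np.inf
        agent.fitness = float(value)

    population = lhs_init(config, rng)
    for agent in population:
        evaluate(agent)
    best = min(population, key=lambda a: a.fitness)
    best_ever = Agent(best.position.copy(), best.fitness)
    trace = [best_ever.fitness]
    stall = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        population, _ = explore_step(population, best_ever, config, rng)
        for agent in population:
            evaluate(agent)
        population = local_perturb(population, config, rng)
        for agent in population:
            if not np.isfinite(agent.fitness):
                evaluate(agent)
        population = reproduce_and_cull(population, config, rng)
        for agent in population:
            if not np.isfinite(agent.fitness):
                evaluate(agent)
        gen_best = min(population, key=lambda a: a.fitness)
        if gen_best.fitness < best_ever.fitness - config.improvement_tol:
            best_ever = Agent(gen_best.position.copy(), gen_best.fitness)
            stall = 0
        else:
            stall += 1
        # elitism: re-insert the best-ever agent in place of the current worst
        worst_i = int(_rank_order(population)[-1])
        population[worst_i] = Agent(best_ever.position.copy(), best_ever.fitness)
        trace.append(best_ever.fitness)
        if stall >= config.patience:
            break
    return SWOResult(
        best_position=best_ever.position.copy(),
        best_fitness=best_ever.fitness,
        trace=trace,
        generations=gen,
        evaluations=evaluations,
    )
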