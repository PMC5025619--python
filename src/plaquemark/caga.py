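"""Chain agent genetic algorithm (CAGA) over binary selection chromosomes.

The population is a closed ring of "agents": position 1's left neighbour is
position L and position L's right neighbour is position 1, so genetic
information can propagate around the chain.  One generation applies

1. a dynamic neighbourhood competition sweep — each agent, visited in
   ascending ring order, is compared against its fitter neighbour (left
   neighbours already updated in this sweep, right neighbours not yet);
   losers are rebuilt by gene competition against the winner, where loci
   that agree are kept and loci that differ are replaced by a random bit;
2. adaptive crossover of each agent with its fitter neighbour, with a pair
   probability that decays as the pair approaches the generation's best
   fitness and is damped by the pair's Hamming distance;
3. mutation at the rate 1/chromosome_length (a configured initial rate is
   used for generation 0 only); and
4. elitist reinsertion — parents and offspring are pooled and the best
   ``elite_count`` individuals form the next ring.

The run stops when the best population-average fitness seen so far has not
improved for more than ``stall_limit`` generations, or after
``max_iterations`` generations.  All randomness flows through a single
seeded generator, so identical seeds give identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Agent",
    "AgentChain",
    "CAGAConfig",
    "CrossoverContext",
    "neighbors",
    "gene_competition",
    "competition_sweep",
    "adaptive_crossover_prob",
    "crossover",
    "mutate",
    "run_caga",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass(eq=False)
class Agent:
    """Binary selection chromosome with cached fitness ("energy")."""

    genes: np.ndarray
    energy: float | None = None

    def copy(self) -> "Agent":
        return Agent(genes=self.genes.copy(), energy=self.energy)

    @property
    def n_selected(self) -> int:
        return int(self.genes.sum())


class AgentChain:
    """Agents arranged on a closed ring; indexing is 0-based internally."""

    def __init__(self, agents: Sequence[Agent]):
        if len(agents) == 0:
            raise ValueError("empty chain")
        self.agents: list[Agent] = list(agents)

    def __len__(self) -> int:
        return len(self.agents)

    def __getitem__(self, j: int) -> Agent:
        return self.agents[j]

    def neighbor_positions(self, j: int) -> tuple[int, int]:
        size = len(self.agents)
        if not 0 <= j < size:
            raise IndexError(f"position {j} outside chain of size {size}")
        return ((j - 1) % size, (j + 1) % size)


@dataclass(frozen=True)
class CAGAConfig:
    """Search settings.  Defaults follow the reference operating point:
    population 50, initial crossover probability 0.8, initial mutation
    probability 0.05, at most 30 generations, full elitist reinsertion of
    the 50 best individuals.  ``stall_limit`` is the tolerated number of
    generations without improvement of the best population-average fitness.
    """

    population_size: int = 50
    initial_crossover_prob: float = 0.8
    initial_mutation_prob: float = 0.05
    max_iterations: int = 30
    stall_limit: int = 5
    elite_count: int = 50
    uniform_crossover: bool = False
    repair_empty: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("initial_crossover_prob", "initial_mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.population_size, self.max_iterations, self.elite_count) < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class CrossoverContext:
    """Generation statistics feeding the adaptive crossover probability."""

    f_max: float
    f_ave: float
    f_prime: float
    gh: int


def neighbors(chain: AgentChain, j: int) -> tuple[Agent, Agent]:
    """Left and right ring neighbours of position ``j`` (0-based)."""
    left, right = chain.neighbor_positions(j)
    return chain[left], chain[right]


def gene_competition(
    loser: Agent, winner: Agent, rng: np.random.Generator
) -> Agent:
    """Rebuild a losing agent against the winner.

    Loci where the two agree are preserved; loci where they differ become an
    independent uniform random bit.  The winner is untouched.
    """
    if loser.genes.shape != winner.genes.shape:
        raise ValueError("chromosome length mismatch")
    differ = loser.genes != winner.genes
    genes = winner.genes.copy()
    genes[differ] = rng.integers(0, 2, size=int(differ.sum()), dtype=genes.dtype)
    return Agent(genes=genes, energy=None)


def competition_sweep(
    chain: AgentChain, fitness_fn: FitnessFn, rng: np.random.Generator
) -> AgentChain:
    """One dynamic neighbourhood competition pass in ascending order.

    Agent ``i`` is compared with the fitter of its two ring neighbours,
    taking the already-updated ("post") state for positions processed
    earlier in this sweep and the pre-sweep state for positions not yet
    reached.  An agent whose energy is at least its rival's survives;
    otherwise it is replaced by gene competition against the rival and the
    replacement's energy is evaluated immediately.
    """
    size = len(chain)
    if any(a.energy is None for a in chain.agents):
        raise ValueError("all energies must be evaluated before a sweep")
    pre = [a.copy() for a in chain.agents]
    post = [a.copy() for a in chain.agents]
    for i in range(size):
        if i == 0:
            left, right = pre[size - 1], pre[1 % size]
        elif i == size - 1:
            left, right = post[i - 1], post[0]
        else:
            left, right = post[i - 1], pre[i + 1]
        rival = left if left.energy >= right.energy else right
        if post[i].energy >= rival.energy:
            continue
        replacement = gene_competition(post[i], rival, rng)
        replacement.energy = float(fitness_fn(replacement.genes))
        post[i] = replacement
    return AgentChain(post)


def adaptive_crossover_prob(ctx: CrossoverContext) -> float:
    """Adaptive pair crossover probability.

    Pairs below the population mean always cross (p = 1).  Above the mean,
    p = ((f_max - f') / (f_max - f_ave)) ** (1 / GH), so pairs already near
    the generation's best fitness cross rarely, with the decay softened for
    genetically distant pairs.  Degenerate cases: a flat generation
    (f_max == f_ave) returns 1 to keep mixing; identical parents (GH == 0)
    return 0 since crossover would be a no-op.
    """
    if ctx.f_prime < ctx.f_ave:
        return 1.0
    if ctx.f_max == ctx.f_ave:
        return 1.0
    if ctx.gh == 0:
        return 0.0
    base = (ctx.f_max - ctx.f_prime) / (ctx.f_max - ctx.f_ave)
    base = min(max(base, 0.0), 1.0)
    return float(base ** (1.0 / ctx.gh))


def crossover(
    agent: Agent,
    partner: Agent,
    p_c: float,
    rng: np.random.Generator,
    uniform: bool = False,
) -> tuple[Agent, Agent]:
    """With probability ``p_c``, exchange genes between the two parents.

    Default is a one-point exchange at a uniformly random cut; ``uniform``
    switches to per-locus uniform exchange.  Otherwise the parents are
    returned unchanged (as copies).
    """
    if agent.genes.shape != partner.genes.shape:
        raise ValueError("chromosome length mismatch")
    a, b = agent.copy(), partner.copy()
    if rng.random() >= p_c:
        return a, b
    length = len(a.genes)
    if length < 2:
        return a, b
    if uniform:
        swap = rng.integers(0, 2, size=length, dtype=bool)
    else:
        cut = int(rng.integers(1, length))
        swap = np.zeros(length, dtype=bool)
        swap[cut:] = True
    a_genes = np.where(swap, partner.genes, agent.genes)
    b_genes = np.where(swap, agent.genes, partner.genes)
    return Agent(genes=a_genes, energy=None), Agent(genes=b_genes, energy=None)


def mutate(agent: Agent, p_m: float, rng: np.random.Generator) -> Agent:
    """Flip each gene independently with probability ``p_m``."""
    if not 0.0 <= p_m <= 1.0:
        raise ValueError("p_m must lie in [0, 1]")
    flips = rng.random(len(agent.genes)) < p_m
    genes = agent.genes ^ flips.astype(agent.genes.dtype)
    return Agent(genes=genes, energy=None)


def _repair(genes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # classifier-based fitness is undefined on an all-zero chromosome
    if not genes.any():
        genes = genes.copy()
        genes[rng.integers(0, len(genes))] = 1
    return genes


def run_caga(
    fitness_fn: FitnessFn,
    chromosome_length: int,
    config: CAGAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Agent, list[dict]]:
    """Search binary chromosomes of the given length for maximal fitness.

    Returns the highest-energy agent ever seen and a per-generation
    trajectory (generation, f_max, f_ave, f_best, k_stop, selected-feature
    count of the incumbent).  ``rng`` overrides ``config.seed`` when given,
    allowing a caller to thread one generator through repeated runs.
    """
    config = config or CAGAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def evaluate(agent: Agent) -> None:
        if config.repair_empty:
            agent.genes = _repair(agent.genes, rng)
        agent.energy = float(fitness_fn(agent.genes))

    def sweep_fitness(genes: np.ndarray) -> float:
        # replacements built inside the competition sweep may come out
        # all-zero; repair in place so the sweep keeps the fixed gene
        if config.repair_empty and not genes.any():
            genes[rng.integers(0, len(genes))] = 1
        return float(fitness_fn(genes))

    population = []
    for _ in range(config.population_size):
        genes = rng.integers(0, 2, size=chromosome_length, dtype=np.uint8)
        agent = Agent(genes=genes)
        evaluate(agent)
        population.append(agent)
    chain = AgentChain(population)

    best_agent = max(chain.agents, key=lambda a: a.energy).copy()
    f_best = -np.inf
    k_stop = 0
    trajectory: list[dict] = []

    for generation in range(config.max_iterations):
        chain = competition_sweep(chain, sweep_fitness, rng)
        energies = np.array([a.energy for a in chain.agents])
        f_max, f_ave = float(energies.max()), float(energies.mean())

        p_m = (
            config.initial_mutation_prob
            if generation == 0
            else 1.0 / chromosome_length
        )
        offspring: list[Agent] = []
        for i in range(len(chain)):
            agent = chain[i]
            left, right = neighbors(chain, i)
            partner = left if left.energy >= right.energy else right
            gh = int(np.count_nonzero(agent.genes != partner.genes))
            if generation == 0:
                p_c = config.initial_crossover_prob
            else:
                p_c = adaptive_crossover_prob(
                    CrossoverContext(
                        f_max=f_max,
                        f_ave=f_ave,
                        f_prime=max(agent.energy, partner.energy),
                        gh=gh,
                    )
                )
            child_a, child_b = crossover(
                agent, partner, p_c, rng, uniform=config.uniform_crossover
            )
            offspring.extend([child_a, child_b])
        for child in offspring:
            mutated = mutate(child, p_m, rng)
            child.genes = mutated.genes
            evaluate(child)

        pool = chain.agents + offspring
        pool.sort(key=lambda a: a.energy, reverse=True)
        n_elite = min(config.elite_count, config.population_size)
        survivors = [a.copy() for a in pool[:n_elite]]
        if len(survivors) < config.population_size:
            # non-elitist slots are filled by the best remaining offspring
            rest = sorted(
                (a for a in offspring if a not in pool[:n_elite]),
                key=lambda a: a.energy,
                reverse=True,
            )
            survivors.extend(a.copy() for a in rest)
        chain = AgentChain(survivors[: config.population_size])

        if pool[0].energy > best_agent.energy:
            best_agent = pool[0].copy()

        gen_ave = float(np.mean([a.energy for a in chain.agents]))
        if gen_ave > f_best:
            f_best = gen_ave
            k_stop = 0
        else:
            k_stop += 1
        trajectory.append(
            {
                "generation": generation,
                "f_max": float(max(a.energy for a in chain.agents)),
                "f_ave": gen_ave,
                "f_best": f_best,
                "k_stop": k_stop,
                "best_n_selected": best_agent.n_selected,
            }
        )
        if k_stop > config.stall_limit:
            break
    return best_agent, trajectory
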