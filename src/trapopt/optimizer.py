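"""Genetic-algorithm search over trap placements.

Chromosomes encode only the *movable* traps: a vector of node indices in
discrete mode, or an (n, 2) array of free coordinates in continuous mode.
Immovable traps live outside the genome and are re-attached at every fitness
evaluation, which guarantees crossover and mutation can never move them.

The GA minimizes expected trapping time (mean or worst-origin) with
tournament selection, two-point crossover on the gene list (a coordinate pair
is one gene and is never split), uniform-resample mutation (discrete) or
clipped Gaussian perturbation (continuous), and a size-1 elite archive so the
best-so-far fitness trace is non-increasing. Configurations from which some
origin can never be trapped evaluate to ``+inf`` and simply lose tournaments.

``brute_force_discrete`` enumerates all placements of the movable traps on
the nodes and is the exactness oracle for small instances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .landscape import InvalidInputError, Landscape
from .traps import Trap, TrapKernel, augment_with_traps
from .fitness import expected_absorption_time, fitness_max, fitness_mean

__all__ = [
    "GAConfig",
    "OptimizationResult",
    "evaluate",
    "mutate_discrete",
    "mutate_continuous",
    "crossover",
    "select_tournament",
    "optimize",
    "brute_force_discrete",
]

BRUTE_FORCE_CAP = 200_000

#: INFO-level progress is logged every this many generations.
LOG_EVERY = 50

log = logging.getLogger("trapopt")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (all exposed; defaults are conventional
    evolutionary-toolbox values, not tuned to any particular landscape)."""

    population_size: int = 128
    generations: int = 200
    crossover_prob: float = 0.7
    mutation_prob: float = 0.3
    #: per-gene mutation rate; None selects a mode-appropriate default
    #: (0.5 discrete, 0.1 continuous — simultaneous fine placement of many
    #: coordinate pairs needs far less disruptive mutation)
    per_gene_rate: Optional[float] = None
    tournament_size: int = 3
    # continuous-mode Gaussian step: starts at gaussian_sigma_fraction x the
    # bounding-box diagonal and decays geometrically to sigma_final_fraction
    # of that start by the last generation (coarse exploration early, fine
    # placement late); sigma_final_fraction=1 keeps a fixed step
    gaussian_sigma_fraction: float = 0.05
    sigma_final_fraction: float = 0.02
    seed: int = 0
    objective: str = "mean"  # mean | max
    mode: str = "discrete"  # discrete | continuous
    repetitions: int = 1
    bbox_pad_fraction: float = 0.05

    def __post_init__(self) -> None:
        probs = [self.crossover_prob, self.mutation_prob]
        if self.per_gene_rate is not None:
            probs.append(self.per_gene_rate)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError("probabilities must lie in [0, 1]")
        for c in (self.population_size, self.generations, self.tournament_size,
                  self.repetitions):
            if c < 1:
                raise InvalidInputError("counts must be >= 1")
        if self.objective not in ("mean", "max"):
            raise InvalidInputError("objective must be mean|max")
        if self.mode not in ("discrete", "continuous"):
            raise InvalidInputError("mode must be discrete|continuous")

    @property
    def effective_per_gene_rate(self) -> float:
        if self.per_gene_rate is not None:
            return self.per_gene_rate
        return 0.5 if self.mode == "discrete" else 0.1


@dataclass
class OptimizationResult:
    """Best placement found, with per-repetition convergence traces."""

    best_genes: np.ndarray
    best_fitness: float
    objective: str
    mode: str
    seed: int
    traces: list[list[dict]]  # per repetition: [{gen, best, mean}, ...]
    config: GAConfig
    all_unreachable_warning: bool = False

    @property
    def trace(self) -> list[dict]:
        """Trace of the repetition that produced the best placement."""
        return self.traces[self._best_rep]

    _best_rep: int = field(default=0, repr=False)

    def best_placement(self) -> list:
        if self.mode == "discrete":
            return [int(g) for g in self.best_genes]
        return [(float(x), float(y)) for x, y in self.best_genes]

    def to_json_dict(self) -> dict:
        cfg = asdict(self.config)
        return {
            "best_placement": self.best_placement(),
            "best_fitness_days": self.best_fitness,
            "objective": self.objective,
            "mode": self.mode,
            "seed": self.seed,
            "trace": self.trace,
            "config": cfg,
            "all_unreachable_warning": self.all_unreachable_warning,
        }


def _genes_to_traps(
    genes: np.ndarray,
    fixed_traps: Sequence[Trap],
    movable_kernels: Sequence[TrapKernel],
    mode: str,
) -> list[Trap]:
    traps = list(fixed_traps)
    base = len(traps)
    for k, kernel in enumerate(movable_kernels):
        if mode == "discrete":
            placement: object = int(genes[k])
        else:
            placement = (float(genes[k, 0]), float(genes[k, 1]))
        traps.append(Trap(id=base + k, placement=placement, kernel=kernel))
    return traps


def evaluate(
    genes: np.ndarray,
    landscape: Landscape,
    fixed_traps: Sequence[Trap],
    movable_kernels: Sequence[TrapKernel],
    objective: str = "mean",
    mode: str = "discrete",
) -> float:
    """Fitness (days, minimized) of one chromosome: build traps, augment the
    chain, solve, reduce. Unreachable configurations return ``+inf``."""
    traps = _genes_to_traps(genes, fixed_traps, movable_kernels, mode)
    chain = augment_with_traps(landscape, traps)
    profile = expected_absorption_time(chain)
    return fitness_mean(profile) if objective == "mean" else fitness_max(profile)


def mutate_discrete(
    genes: np.ndarray, rng: np.random.Generator, per_gene_rate: float, n_sites: int
) -> np.ndarray:
    """Each gene independently resampled uniformly over the nodes."""
    out = genes.copy()
    mask = rng.random(len(out)) < per_gene_rate
    out[mask] = rng.integers(0, n_sites, int(mask.sum()))
    return out


def mutate_continuous(
    genes: np.ndarray,
    rng: np.random.Generator,
    per_gene_rate: float,
    sigma: float,
    bounds: tuple[float, float, float, float],
) -> np.ndarray:
    """Gaussian perturbation of selected coordinate pairs, clipped to the
    bounding box (xmin, ymin, xmax, ymax)."""
    out = genes.copy()
    mask = rng.random(len(out)) < per_gene_rate
    out[mask] += rng.normal(0.0, sigma, (int(mask.sum()), 2))
    xmin, ymin, xmax, ymax = bounds
    out[:, 0] = np.clip(out[:, 0], xmin, xmax)
    out[:, 1] = np.clip(out[:, 1], ymin, ymax)
    return out


def crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point crossover on the gene list; children jointly conserve the
    parents' multiset of genes."""
    n = len(parent_a)
    a, b = sorted(rng.integers(0, n + 1, 2))
    child_a, child_b = parent_a.copy(), parent_b.copy()
    child_a[a:b], child_b[a:b] = parent_b[a:b].copy(), parent_a[a:b].copy()
    return child_a, child_b


def select_tournament(
    population: Sequence[np.ndarray],
    fitnesses: Sequence[float],
    k: int,
    tournament_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """k winners, each the minimum-fitness member of a uniform tournament;
    ties broken by lowest population index."""
    fit = np.asarray(fitnesses, dtype=float)
    winners = []
    for _ in range(k):
        cand = np.sort(rng.integers(0, len(population), tournament_size))
        winner = cand[int(np.argmin(fit[cand]))]  # first min -> lowest index
        winners.append(population[winner].copy())
    return winners


def _run_single(
    landscape: Landscape,
    fixed_traps: Sequence[Trap],
    movable_kernels: Sequence[TrapKernel],
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[dict], bool]:
    n_genes = len(movable_kernels)
    n_sites = landscape.n_sites
    bounds = landscape.bounding_box(config.bbox_pad_fraction)
    diag = math.hypot(bounds[2] - bounds[0], bounds[3] - bounds[1])
    sigma0 = config.gaussian_sigma_fraction * diag
    # geometric decay reaching sigma0 * sigma_final_fraction at the last gen
    decay = (
        config.sigma_final_fraction ** (1.0 / config.generations)
        if config.generations > 0
        else 1.0
    )

    def _eval(g: np.ndarray) -> float:
        return evaluate(
            g, landscape, fixed_traps, movable_kernels, config.objective, config.mode
        )

    per_gene_rate = config.effective_per_gene_rate
    if config.mode == "discrete":
        pop = [
            rng.integers(0, n_sites, n_genes)
            for _ in range(config.population_size)
        ]
    else:
        # seed continuous chromosomes at jittered node coordinates: only the
        # neighbourhoods of population sites carry fitness signal, so a
        # uniform scatter would start almost entirely in dead space
        xy = landscape.coords
        xmin, ymin, xmax, ymax = bounds
        pop = []
        for _ in range(config.population_size):
            idx = rng.integers(0, n_sites, n_genes)
            genes = xy[idx] + rng.normal(0.0, sigma0 / 4.0, (n_genes, 2))
            genes[:, 0] = np.clip(genes[:, 0], xmin, xmax)
            genes[:, 1] = np.clip(genes[:, 1], ymin, ymax)
            pop.append(genes)
    fit = [_eval(g) for g in pop]
    best_idx = int(np.argmin(fit))
    elite, elite_fit = pop[best_idx].copy(), fit[best_idx]
    warn = not np.any(np.isfinite(fit))

    trace = [{"gen": 0, "best": elite_fit, "mean": float(np.mean(fit))}]
    for gen in range(1, config.generations + 1):
        offspring = select_tournament(
            pop, fit, config.population_size, config.tournament_size, rng
        )
        for i in range(0, len(offspring) - 1, 2):
            if rng.random() < config.crossover_prob:
                offspring[i], offspring[i + 1] = crossover(
                    offspring[i], offspring[i + 1], rng
                )
        for i in range(len(offspring)):
            if rng.random() < config.mutation_prob:
                if config.mode == "discrete":
                    offspring[i] = mutate_discrete(
                        offspring[i], rng, per_gene_rate, n_sites
                    )
                else:
                    sigma = sigma0 * decay**gen
                    offspring[i] = mutate_continuous(
                        offspring[i], rng, per_gene_rate, sigma, bounds
                    )
        fit = [_eval(g) for g in offspring]
        # elitism: re-inject the best-ever individual over the current worst
        worst = int(np.argmax(fit))
        if fit[worst] > elite_fit:
            offspring[worst] = elite.copy()
            fit[worst] = elite_fit
        pop = offspring
        best_idx = int(np.argmin(fit))
        if fit[best_idx] < elite_fit:
            elite, elite_fit = pop[best_idx].copy(), fit[best_idx]
        trace.append({"gen": gen, "best": elite_fit, "mean": float(np.mean(fit))})
        if gen % LOG_EVERY == 0:
            log.info("generation %d: best %.4f days", gen, elite_fit)
    return elite, elite_fit, trace, warn


def optimize(
    landscape: Landscape,
    fixed_traps: Sequence[Trap],
    movable_kernels: Sequence[TrapKernel],
    config: GAConfig,
) -> OptimizationResult:
    """Run the GA for ``config.repetitions`` independent seeded restarts and
    return the best placement across repetitions with every trace retained."""
    if len(movable_kernels) == 0:
        raise InvalidInputError("need at least one movable trap")
    seeds = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    traces: list[list[dict]] = []
    best_genes, best_fit, best_rep, warn = None, np.inf, 0, False
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        genes, f, trace, w = _run_single(
            landscape, fixed_traps, movable_kernels, config, rng
        )
        traces.append(trace)
        warn = warn or w
        if best_genes is None or f < best_fit:
            best_genes, best_fit, best_rep = genes, f, rep
    result = OptimizationResult(
        best_genes=best_genes,
        best_fitness=float(best_fit),
        objective=config.objective,
        mode=config.mode,
        seed=config.seed,
        traces=traces,
        config=config,
        all_unreachable_warning=warn,
    )
    result._best_rep = best_rep
    return result


def brute_force_discrete(
    landscape: Landscape,
    fixed_traps: Sequence[Trap],
    movable_kernels: Sequence[TrapKernel],
    objective: str = "mean",
    cap: int = BRUTE_FORCE_CAP,
) -> tuple[list[int], float]:
    """Exact global optimum over node placements by exhaustive enumeration.

    With identical movable kernels the search runs over multisets of nodes;
    with heterogeneous kernels the full ordered product is enumerated.
    Refuses (with a size estimate) beyond ``cap`` combinations.
    """
    n = landscape.n_sites
    k = len(movable_kernels)
    if k == 0:
        raise InvalidInputError("need at least one movable trap")
    identical = len(set(movable_kernels)) == 1
    n_combos = math.comb(n + k - 1, k) if identical else n**k
    if n_combos > cap:
        raise InvalidInputError(
            f"brute force would evaluate {n_combos} placements (cap {cap})"
        )
    space = (
        itertools.combinations_with_replacement(range(n), k)
        if identical
        else itertools.product(range(n), repeat=k)
    )
    best_placement: Optional[tuple[int, ...]] = None
    best_fit = np.inf
    for placement in space:
        f = evaluate(
            np.array(placement), landscape, fixed_traps, movable_kernels,
            objective, "discrete",
        )
        if f < best_fit or best_placement is None:
            best_placement, best_fit = placement, f
    return list(best_placement), float(best_fit)
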