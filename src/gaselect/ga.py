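"""Genetic-algorithm wrapper for feature-subset search.

Each individual ("GA-chromosome") is a bit vector over the stage-1 candidate
features: bit i = 1 includes feature i.  One generation consists of

1. fitness evaluation (cross-validated accuracy, see :mod:`gaselect.fitness`),
2. fitness-proportional (roulette-wheel) parent selection,
   p_i = ACC-bar_i / sum_k ACC-bar_k,
3. single- or double-point crossover at rate 0.8,
4. independent per-bit mutation at rate 0.05,
5. replacement of the population by the offspring plus the two elite
   (highest-fitness) chromosomes copied unchanged.

Elitism plus frozen CV folds make the per-generation best fitness exactly
non-decreasing.  A single master seed derives independent named substreams
(init / selection / crossover / mutation / folds / classifier) so a run is
bit-reproducible and each operator is independently replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import FeatureTable, subset_features
from .errors import ConfigurationError
from .fitness import FitnessEvaluator, FitnessSpec

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "Population",
    "GAResult",
    "GARandomStreams",
    "init_population",
    "selection_probabilities",
    "select_parents",
    "single_point_crossover",
    "double_point_crossover",
    "crossover_pair",
    "mutate",
    "next_generation",
    "run_ga",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class GAConfig:
    """Evolution hyperparameters.

    Defaults are the study conditions of the method: population x = 100,
    crossover rate 0.8, mutation probability 0.05, 5000 generations, two
    elites.
    """

    population_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    n_generations: int = 5000
    n_elites: int = 2
    crossover_mode: str = "random_choice"  # single | double | random_choice
    mutation_mode: str = "per_bit"  # per_bit | single_point
    master_seed: int = 0
    early_stop_patience: int | None = None  # off by default

    def __post_init__(self) -> None:
        if self.population_size < self.n_elites + 2:
            raise ConfigurationError(
                "population_size must be at least n_elites + 2"
            )
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {rate}")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.n_elites < 0:
            raise ConfigurationError("n_elites must be >= 0")
        if self.crossover_mode not in ("single", "double", "random_choice"):
            raise ConfigurationError(
                f"unknown crossover_mode {self.crossover_mode!r}"
            )
        if self.mutation_mode not in ("per_bit", "single_point"):
            raise ConfigurationError(
                f"unknown mutation_mode {self.mutation_mode!r}"
            )


@dataclass(frozen=True)
class GARandomStreams:
    """Named, independent substreams derived from one master seed."""

    init: np.random.Generator
    selection: np.random.Generator
    crossover: np.random.Generator
    mutation: np.random.Generator
    fold_seed: int
    classifier_seed: int

    @classmethod
    def from_master_seed(cls, master_seed: int) -> "GARandomStreams":
        root = np.random.SeedSequence(int(master_seed))
        init_ss, sel_ss, cx_ss, mut_ss, fold_ss, clf_ss = root.spawn(6)
        return cls(
            init=np.random.default_rng(init_ss),
            selection=np.random.default_rng(sel_ss),
            crossover=np.random.default_rng(cx_ss),
            mutation=np.random.default_rng(mut_ss),
            fold_seed=int(fold_ss.generate_state(1)[0] % _SEED_MOD),
            classifier_seed=int(clf_ss.generate_state(1)[0] % _SEED_MOD),
        )


@dataclass
class Population:
    """Fixed-size collection of equal-length chromosomes."""

    members: np.ndarray  # (x, d) uint8
    generation_index: int = 0

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.uint8)
        if self.members.ndim != 2:
            raise ConfigurationError("population must be a 2-D bit array")
        if not np.isin(self.members, (0, 1)).all():
            raise ConfigurationError("chromosomes must be 0/1 vectors")

    @property
    def size(self) -> int:
        return self.members.shape[0]

    @property
    def chromosome_length(self) -> int:
        return self.members.shape[1]


@dataclass(frozen=True)
class GAResult:
    """Outcome of one GA run."""

    best_chromosome: np.ndarray
    best_fitness: float
    best_generation: int
    trajectory_best: tuple[float, ...]  # per-generation best fitness
    trajectory_mean: tuple[float, ...]  # per-generation mean fitness
    selected_feature_names: tuple[str, ...]
    n_evaluations: int = 0

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.best_chromosome))


def init_population(d: int, x: int, rng: np.random.Generator) -> Population:
    """Random initial population: each bit an independent fair coin."""
    if d < 1:
        raise ConfigurationError("chromosome length d must be >= 1")
    if x < 1:
        raise ConfigurationError("population size x must be >= 1")
    return Population(rng.integers(0, 2, size=(x, d), dtype=np.uint8), 0)


def selection_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Roulette-wheel probabilities p_i = ACC-bar_i / sum_k ACC-bar_k.

    A degenerate all-zero fitness vector falls back to the uniform
    distribution (logged); otherwise the output is ordered like the input,
    nonnegative and sums to 1.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ConfigurationError("empty fitness vector")
    if np.any(f < 0) or np.any(f > 1):
        raise ConfigurationError("fitnesses must lie in [0, 1]")
    total = f.sum()
    if total == 0:
        logger.warning("all fitnesses are zero; using uniform selection")
        return np.full(f.size, 1.0 / f.size)
    return f / total


def select_parents(
    population: Population, probs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent draws with replacement from the categorical ``probs``
    (the same member may parent twice)."""
    i, j = rng.choice(population.size, size=2, replace=True, p=probs)
    return population.members[i].copy(), population.members[j].copy()


def single_point_crossover(
    p1: np.ndarray, p2: np.ndarray, cut: int
) -> tuple[np.ndarray, np.ndarray]:
    """Splice at interior position ``cut`` (1 <= cut <= d-1): children are
    p1[:cut]+p2[cut:] and p2[:cut]+p1[cut:]."""
    d = len(p1)
    if not 1 <= cut <= d - 1:
        raise ConfigurationError(f"cut point {cut} outside interior of length {d}")
    c1 = np.concatenate([p1[:cut], p2[cut:]])
    c2 = np.concatenate([p2[:cut], p1[cut:]])
    return c1, c2


def double_point_crossover(
    p1: np.ndarray, p2: np.ndarray, cut_a: int, cut_b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the segment between two distinct interior cut points."""
    if cut_a == cut_b:
        raise ConfigurationError("double crossover needs distinct cut points")
    lo, hi = sorted((cut_a, cut_b))
    c1, c2 = p1.copy(), p2.copy()
    c1[lo:hi], c2[lo:hi] = p2[lo:hi], p1[lo:hi]
    return c1, c2


def crossover_pair(
    p1: np.ndarray,
    p2: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``crossover_rate``, recombine the parents; otherwise
    return copies.

    Cut points are uniform over interior positions 1..d-1 (distinct for the
    double crossover); ``random_choice`` mode flips a fair coin between
    single and double per mating pair.  Whatever happens, the positionwise
    bit multiset {c1[i], c2[i]} equals {p1[i], p2[i]} for every i.
    """
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    d = len(p1)
    if len(p2) != d:
        raise ConfigurationError("parents must have equal length")
    if rng.random() >= config.crossover_rate:
        return p1.copy(), p2.copy()
    if d < 2:
        raise ConfigurationError("crossover needs chromosomes of length >= 2")
    mode = config.crossover_mode
    if mode == "random_choice":
        mode = "single" if rng.random() < 0.5 else "double"
    if mode == "single" or d == 2:  # length 2 has a single interior point
        cut = int(rng.integers(1, d))
        return single_point_crossover(p1, p2, cut)
    cut_a, cut_b = rng.choice(np.arange(1, d), size=2, replace=False)
    return double_point_crossover(p1, p2, int(cut_a), int(cut_b))


def mutate(
    c: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
    mode: str = "per_bit",
) -> np.ndarray:
    """Bit-flip mutation.

    ``per_bit`` flips each bit independently with probability
    ``mutation_rate`` (the default semantics); ``single_point`` flips exactly
    one uniformly chosen bit with probability ``mutation_rate``.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ConfigurationError("mutation_rate must lie in [0, 1]")
    c = np.asarray(c, dtype=np.uint8)
    out = c.copy()
    if mode == "per_bit":
        flips = rng.random(len(c)) < mutation_rate
        out[flips] ^= 1
    elif mode == "single_point":
        if rng.random() < mutation_rate:
            pos = int(rng.integers(len(c)))
            out[pos] ^= 1
    else:
        raise ConfigurationError(f"unknown mutation mode {mode!r}")
    return out


def _elite_order(fitnesses: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Indices sorted by fitness desc, then fewer set bits (parsimony), then
    original index — the elite tie-break."""
    popcounts = members.sum(axis=1)
    order = sorted(
        range(len(fitnesses)),
        key=lambda i: (-fitnesses[i], popcounts[i], i),
    )
    return np.array(order, dtype=np.intp)


def next_generation(
    population: Population,
    fitnesses: Sequence[float],
    config: GAConfig,
    streams: GARandomStreams,
) -> Population:
    """One replacement step: copy the elites, then fill the remaining
    x - n_elites slots with offspring produced by roulette selection,
    crossover and mutation (the last pair is truncated to one child when the
    offspring count is odd)."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.shape != (population.size,):
        raise ConfigurationError("one fitness per population member required")
    probs = selection_probabilities(fitnesses)
    elite_idx = _elite_order(fitnesses, population.members)[: config.n_elites]
    children: list[np.ndarray] = [
        population.members[i].copy() for i in elite_idx
    ]
    n_offspring = population.size - len(children)
    offspring: list[np.ndarray] = []
    while len(offspring) < n_offspring:
        pa, pb = select_parents(population, probs, streams.selection)
        ca, cb = crossover_pair(pa, pb, config, streams.crossover)
        for child in (ca, cb):
            if len(offspring) < n_offspring:
                offspring.append(
                    mutate(
                        child,
                        config.mutation_rate,
                        streams.mutation,
                        config.mutation_mode,
                    )
                )
    return Population(
        np.vstack(children + offspring) if children or offspring else
        population.members.copy(),
        population.generation_index + 1,
    )


def run_ga(
    candidates: Sequence[str],
    table: FeatureTable,
    config: GAConfig,
    fitness_spec: FitnessSpec,
    progress: Callable[[int, float, float, int], None] | None = None,
) -> GAResult:
    """Full evolution over the stage-1 candidate features.

    The fitness fold seed and classifier seed are derived from
    ``config.master_seed`` unless the spec sets them explicitly (non-zero),
    so a single master seed reproduces the entire run.  ``progress`` (if
    given) is called per generation with (generation, best, mean,
    best_popcount).
    """
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ConfigurationError(
            f"GA needs at least 2 candidate features, got {len(candidates)}"
        )
    sub = subset_features(table, candidates)
    streams = GARandomStreams.from_master_seed(config.master_seed)
    spec = fitness_spec
    if spec.fold_seed == 0 and spec.classifier_seed == 0:
        spec = spec.with_seeds(streams.fold_seed, streams.classifier_seed)
    evaluator = FitnessEvaluator(sub, spec)

    population = init_population(len(candidates), config.population_size, streams.init)
    traj_best: list[float] = []
    traj_mean: list[float] = []
    best_fit = -1.0
    best_bits: np.ndarray | None = None
    best_gen = 0
    stale = 0

    for gen in range(config.n_generations + 1):
        fitnesses = np.array([evaluator(m).mean_accuracy for m in population.members])
        gen_best_idx = _elite_order(fitnesses, population.members)[0]
        gen_best = float(fitnesses[gen_best_idx])
        traj_best.append(gen_best)
        traj_mean.append(float(fitnesses.mean()))
        if gen_best > best_fit:
            best_fit = gen_best
            best_bits = population.members[gen_best_idx].copy()
            best_gen = gen
            stale = 0
        else:
            stale += 1
        if progress is not None:
            progress(gen, gen_best, traj_mean[-1], int(population.members[gen_best_idx].sum()))
        if (
            config.early_stop_patience is not None
            and stale >= config.early_stop_patience
        ):
            logger.info("early stop at generation %d (patience reached)", gen)
            break
        if gen < config.n_generations:
            population = next_generation(population, fitnesses, config, streams)

    assert best_bits is not None
    selected = tuple(
        name for name, bit in zip(candidates, best_bits) if bit
    )
    return GAResult(
        best_chromosome=best_bits,
        best_fitness=best_fit,
        best_generation=best_gen,
        trajectory_best=tuple(traj_best),
        trajectory_mean=tuple(traj_mean),
        selected_feature_names=selected,
        n_evaluations=evaluator.n_evaluations,
    )
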