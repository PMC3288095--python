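"""Genetic-algorithm wrapper feature selection over binary patch masks.

A chromosome is a binary vector of length N (1 = the patch participates in
learning).  Fitness is F = 1 - rho, where rho is the classification
performance of a linear classifier - trained on the training split with the
selected patches' C2 rows - measured at the equilibrium point of the ROC on
the evaluation split.  The GA minimizes F with linear rank selection,
uniform crossover, per-bit mutation and elitist replacement, stopping at a
generation cap or after a stagnation patience without improvement.

All randomness flows from a single seeded generator per run.  Stream order:
population initialization first, then per generation and per offspring pair -
two rank-selection draws, one crossover coin, the crossover mask (if the coin
hit), and the two mutation masks (re-drawn while a child is all-zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class GAConfig:
    pop_size: int = 20
    crossover_prob: float = 0.9
    mutation_rate: float | None = None  # None -> 1 / n_bits
    elite_count: int = 1
    max_generations: int = 100
    stagnation_patience: int = 15
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0 <= self.elite_count < self.pop_size:
            raise ValueError("need 0 <= elite_count < pop_size")
        if not 0 < self.init_density < 1:
            raise ValueError("init_density must lie in (0, 1)")
        if self.max_generations < 1 or self.stagnation_patience < 1:
            raise ValueError("generation counts must be >= 1")


@dataclass
class GAResult:
    """Outcome of one GA run.

    ``fitness_history[g]`` is the best F seen up to generation g (entry 0 is
    the initial population); it is non-increasing under elitism.
    """

    best_chromosome: np.ndarray
    best_fitness: float
    fitness_history: list
    final_population: np.ndarray
    initial_population: np.ndarray
    n_generations: int
    n_evaluations: int


def init_population(n_bits: int, cfg: GAConfig, rng=None) -> np.ndarray:
    """pop_size x n_bits binary matrix, bits i.i.d. Bernoulli(init_density);
    all-zero rows are re-drawn."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pop = (rng.random((cfg.pop_size, n_bits)) < cfg.init_density).astype(np.uint8)
    for r in range(cfg.pop_size):
        while not pop[r].any():
            pop[r] = (rng.random(n_bits) < cfg.init_density).astype(np.uint8)
    return pop


def rank_select(pop: np.ndarray, fitnesses, k: int, rng) -> list:
    """Sample k parents with probability proportional to linear rank.

    Lowest F is best and receives the highest weight (pop_size); tied
    fitnesses share the average of their rank weights, so equal fitnesses
    yield uniform selection.  Returns chromosome copies.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not np.isfinite(fitnesses).all():
        raise ValueError("fitnesses must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    size = len(pop)
    order = np.lexsort((np.arange(size), fitnesses))  # best first, stable
    raw = np.arange(size, 0, -1, dtype=float)
    weights = np.empty(size, dtype=float)
    sorted_f = fitnesses[order]
    i = 0
    while i < size:
        j = i
        while j + 1 < size and sorted_f[j + 1] == sorted_f[i]:
            j += 1
        weights[order[i:j + 1]] = raw[i:j + 1].mean()
        i = j + 1
    probs = weights / weights.sum()
    chosen = rng.choice(size, size=k, p=probs)
    return [np.array(pop[i], dtype=np.uint8, copy=True) for i in chosen]


def uniform_crossover(a: np.ndarray, b: np.ndarray, rng, p_swap: float = 0.5):
    """Per-bit exchange: each locus swaps between the two offspring with
    probability p_swap, so the per-position multiset of bits is conserved."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("parent chromosomes must have equal length")
    swap = rng.random(a.shape[0]) < p_swap
    child_a = np.where(swap, b, a).astype(np.uint8)
    child_b = np.where(swap, a, b).astype(np.uint8)
    return child_a, child_b


def mutate(c: np.ndarray, rate: float, rng) -> np.ndarray:
    """Flip each bit independently with probability ``rate``; an all-zero
    result is re-mutated from the original (validity guard)."""
    c = np.asarray(c, dtype=np.uint8)
    if not 0 <= rate <= 1:
        raise ValueError("mutation rate must lie in [0, 1]")
    if rate == 0:
        return c.copy()
    while True:
        flips = rng.random(c.shape[0]) < rate
        out = c.copy()
        out[flips] ^= 1
        if out.any():
            return out
        if rate >= 1.0:
            # the flip mask is deterministic, so re-drawing cannot help:
            # keep the chromosome valid by setting one random bit
            out[int(rng.integers(c.shape[0]))] = 1
            return out


def run_ga(n_bits: int, fitness_fn, cfg: GAConfig) -> GAResult:
    """Evolve patch-selection chromosomes until the generation cap or a
    stagnation patience is hit; fully reproducible from ``cfg.seed``.

    ``fitness_fn`` maps a chromosome (uint8 vector with >= 1 set bit) to a
    fitness F in [0, 1]; lower is better.  Identical chromosomes are
    evaluated once (cached).
    """
    rng = np.random.default_rng(cfg.seed)
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_bits
    pop = init_population(n_bits, cfg, rng)
    initial = pop.copy()

    cache: dict = {}
    n_evals = 0

    def evaluate(ch: np.ndarray) -> float:
        nonlocal n_evals
        key = ch.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(ch))
            n_evals += 1
        return cache[key]

    fits = np.array([evaluate(c) for c in pop])
    best_i = int(np.lexsort((np.arange(len(fits)), fits))[0])
    best_c, best_f = pop[best_i].copy(), float(fits[best_i])
    history = [best_f]

    stagnation = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.lexsort((np.arange(len(fits)), fits))
        elites = [pop[i].copy() for i in order[:cfg.elite_count]]
        n_children = cfg.pop_size - cfg.elite_count
        children = []
        while len(children) < n_children:
            pa, pb = rank_select(pop, fits, 2, rng)
            if rng.random() < cfg.crossover_prob:
                ca, cb = uniform_crossover(pa, pb, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            children.append(mutate(ca, mut_rate, rng))
            children.append(mutate(cb, mut_rate, rng))
        pop = np.array(elites + children[:n_children], dtype=np.uint8)
        fits = np.array([evaluate(c) for c in pop])
        gen_best_i = int(np.lexsort((np.arange(len(fits)), fits))[0])
        if fits[gen_best_i] < best_f:
            best_c, best_f = pop[gen_best_i].copy(), float(fits[gen_best_i])
            stagnation = 0
        else:
            stagnation += 1
        history.append(best_f)
        if stagnation >= cfg.stagnation_patience:
            break

    return GAResult(best_chromosome=best_c, best_fitness=best_f,
                    fitness_history=history, final_population=pop,
                    initial_population=initial, n_generations=gen,
                    n_evaluations=n_evals)


def evaluate_fitness(
    chromosome: np.ndarray,
    c2_train: np.ndarray,
    y_train: np.ndarray,
    c2_eval: np.ndarray,
    y_eval: np.ndarray,
    svm_c: float = 1.0,
    metric: str = "equilibrium",
) -> float:
    """Wrapper fitness F = 1 - rho for one chromosome.

    Trains a linear classifier on the row-masked training C2 matrix and
    measures rho on the row-masked evaluation matrix: equilibrium-point
    performance by default, plain accuracy with ``metric="accuracy"``.
    """
    from .evaluate import equilibrium_error, train_linear_classifier

    chromosome = np.asarray(chromosome).astype(bool)
    if not chromosome.any():
        raise ValueError("a chromosome with no set bits cannot be evaluated")
    if c2_train.shape[0] != chromosome.shape[0] or \
            c2_eval.shape[0] != chromosome.shape[0]:
        raise ValueError("chromosome length must match the C2 patch axis")
    scorer = train_linear_classifier(c2_train[chromosome].T, y_train, c=svm_c)
    scores = scorer(c2_eval[chromosome].T)
    if metric == "equilibrium":
        return float(equilibrium_error(scores, y_eval))
    if metric == "accuracy":
        pred = np.where(scores >= 0, 1, -1)
        return float(np.mean(pred != np.asarray(y_eval)))
    raise ValueError(f"unknown fitness metric: {metric!r}")


def make_wrapper_fitness(c2_train, y_train, c2_eval, y_eval,
                         svm_c: float = 1.0, metric: str = "equilibrium"):
    """Bind the data splits into a ``fitness_fn`` for :func:`run_ga`."""
    y_train = np.asarray(y_train)
    y_eval = np.asarray(y_eval)
    for name, y in (("training", y_train), ("evaluation", y_eval)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} labels contain a single class")

    def fitness(bits: np.ndarray) -> float:
        return evaluate_fitness(bits, c2_train, y_train, c2_eval, y_eval,
                                svm_c=svm_c, metric=metric)

    return fitness
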