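"""Evolutionary search over ensembles of weighted, signed gene-pair rules.

An individual is an ordered list of k weighted pairs; each pair (i, j) carries
a relation sign — whether observing x_i < x_j votes for class C1 or C2 — and a
positive weight r (a power of two: weights start at 1 and mutate by ×2 / ÷2).
A sample is classified by summing the weights of pairs voting for each class;
the larger sum wins (equality of expression values counts against "<",
matching the scoring indicator).

Fitness balances training accuracy against model complexity:

    fitness = Q_reclass − α · (2k + u)

where Q_reclass is training-set accuracy, k the pair count and u the number of
unique genes; u being counted on top of 2k penalizes unique genes doubly,
which favours pairs that share genes (so triplet-like relations emerge for
free). α defaults to 0.005.

The population (default 100) is seeded with "mixed dipole" individuals: a pair
of training samples from opposite classes is drawn and random gene pairs are
rejected until one orders differently across the two samples, guaranteeing the
initial rules separate at least one opposite-class sample pair. Ranking linear
selection with elitism, two crossover variants (pair exchange between parents,
probability 0.9, or injection of a pair from the best individual found so far,
probability 0.1) and six mutation variants drive the search; it stops when the
best fitness has not improved for ``stall_generations`` (default 1000) or at
``max_generations`` (default 10000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io_model import ExpressionMatrix, LabelVector


class DipoleError(RuntimeError):
    """No effective gene pair could be found for a sampled dipole."""


@dataclass
class WeightedPair:
    """One signed, weighted comparison rule between genes i and j."""

    i: int
    j: int
    less_votes_c1: bool   # True: x_i < x_j votes C1 (else that event votes C2)
    weight: float = 1.0

    def copy(self) -> "WeightedPair":
        return WeightedPair(self.i, self.j, self.less_votes_c1, self.weight)

    def canonical(self) -> tuple:
        return (min(self.i, self.j), max(self.i, self.j),
                self.less_votes_c1 == (self.i < self.j), self.weight)


@dataclass
class Individual:
    """An ordered collection of weighted pairs with a cached fitness."""

    pairs: list
    cached_fitness: Optional[float] = None

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise ValueError("an individual must hold at least one pair")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def u(self) -> int:
        genes = set()
        for p in self.pairs:
            genes.update((p.i, p.j))
        return len(genes)

    def copy(self) -> "Individual":
        return Individual([p.copy() for p in self.pairs], self.cached_fitness)

    def invalidate(self) -> None:
        self.cached_fitness = None

    def sort_key(self) -> tuple:
        """Deterministic tie-break identity: sorted canonical pair tuples."""
        return tuple(sorted(p.canonical() for p in self.pairs))


@dataclass(frozen=True)
class EvoConfig:
    """Hyperparameters of the evolutionary search (defaults as published)."""

    population_size: int = 100
    alpha: float = 0.005
    p_crossover: float = 0.5
    p_mutation: float = 0.5
    p_exchange_variant: float = 0.9
    stall_generations: int = 1000
    max_generations: int = 10000
    init_k_max: int = 5
    dipole_retry_limit: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("p_crossover", "p_mutation", "p_exchange_variant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        for name in ("population_size", "stall_generations", "max_generations",
                     "init_k_max", "dipole_retry_limit"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def effective_pair_from_dipole(expr: ExpressionMatrix, labels: LabelVector,
                               rng: np.random.Generator,
                               retry_limit: int = 1000) -> WeightedPair:
    """Draw an effective pair from a random opposite-class sample dipole.

    One sample q is drawn from C1 and one w from C2; random distinct gene
    pairs (i, j) are rejected until their ordering relation differs between
    q and w, i.e. (x_iq > x_jq and x_iw ≤ x_jw) or (x_iq ≤ x_jq and
    x_iw > x_jw). The sign is set so the relation satisfied in the C1 sample
    votes C1; the weight is 1.
    """
    y = labels.y
    idx1 = np.flatnonzero(y == 0)
    idx2 = np.flatnonzero(y == 1)
    q = int(idx1[rng.integers(len(idx1))])
    w = int(idx2[rng.integers(len(idx2))])
    values = expr.values
    p = expr.n_genes
    for _ in range(retry_limit):
        i = int(rng.integers(p))
        j = int(rng.integers(p - 1))
        if j >= i:
            j += 1
        gt_q = values[i, q] > values[j, q]
        gt_w = values[i, w] > values[j, w]
        if gt_q and not gt_w:
            # relation "x_i > x_j" holds in the C1 sample
            return WeightedPair(i, j, less_votes_c1=False)
        if not gt_q and gt_w:
            return WeightedPair(i, j, less_votes_c1=True)
    raise DipoleError(
        f"no effective pair found for dipole (samples "
        f"{expr.sample_ids[q]!r}, {expr.sample_ids[w]!r}) "
        f"after {retry_limit} draws"
    )


def init_population(expr: ExpressionMatrix, labels: LabelVector,
                    config: EvoConfig,
                    rng: Optional[np.random.Generator] = None) -> list:
    """Population of dipole-seeded individuals, k uniform on {1..init_k_max}."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = []
    for _ in range(config.population_size):
        k = int(rng.integers(1, config.init_k_max + 1))
        pairs = [effective_pair_from_dipole(expr, labels, rng,
                                            config.dipole_retry_limit)
                 for _ in range(k)]
        population.append(Individual(pairs))
    return population


def _margins(ind: Individual, values: np.ndarray) -> np.ndarray:
    """Weighted C1-minus-C2 vote margin per sample (exact for 2^n weights)."""
    score = np.zeros(values.shape[1])
    for p in ind.pairs:
        less = values[p.i] < values[p.j]
        sgn = np.where(less, 1.0, -1.0)
        if not p.less_votes_c1:
            sgn = -sgn
        score += p.weight * sgn
    return score


def classify(ind: Individual, expr: ExpressionMatrix,
             sample_indices=None,
             labels_for_tiebreak: Optional[LabelVector] = None) -> np.ndarray:
    """Predicted class indices (0 = C1, 1 = C2) per sample.

    A zero weighted margin falls back to the majority training class (from
    ``labels_for_tiebreak``); with no labels, or equal class sizes, to C1.
    """
    values = expr.values
    if sample_indices is not None:
        idx = np.atleast_1d(np.asarray(sample_indices, dtype=int))
        values = values[:, idx]
    tie = 0
    if labels_for_tiebreak is not None:
        tie = labels_for_tiebreak.majority_class_index
    margin = _margins(ind, values)
    return np.where(margin > 0, 0, np.where(margin < 0, 1, tie))


def fitness(ind: Individual, expr: ExpressionMatrix, labels: LabelVector,
            alpha: float) -> float:
    """Q_reclass − α·(2k + u); the value is cached on the individual."""
    if ind.cached_fitness is not None:
        return ind.cached_fitness
    pred = classify(ind, expr, labels_for_tiebreak=labels)
    q = float(np.mean(pred == labels.y))
    value = q - alpha * (2 * ind.k + ind.u)
    ind.cached_fitness = value
    return value


def crossover(a: Individual, b: Individual, best_so_far: Individual,
              rng: np.random.Generator,
              p_exchange_variant: float = 0.9) -> None:
    """Recombine in place: pair exchange (prob 0.9) or injection from best.

    Exchange swaps one uniformly chosen pair of ``a`` with one of ``b``
    (both modified); injection copies a uniformly chosen pair of the best
    individual found so far over a uniformly chosen pair of ``a`` only.
    """
    if rng.random() < p_exchange_variant:
        ia = int(rng.integers(a.k))
        ib = int(rng.integers(b.k))
        a.pairs[ia], b.pairs[ib] = b.pairs[ib], a.pairs[ia]
        b.invalidate()
    else:
        src = int(rng.integers(best_so_far.k))
        dst = int(rng.integers(a.k))
        a.pairs[dst] = best_so_far.pairs[src].copy()
    a.invalidate()


# mutation variant indices
MUT_ADD, MUT_REMOVE, MUT_REPLACE, MUT_EXCHANGE_GENE, MUT_WEIGHT, MUT_SIGN = range(6)


def mutate(ind: Individual, expr: ExpressionMatrix, labels: LabelVector,
           rng: np.random.Generator, retry_limit: int = 1000,
           variant: Optional[int] = None) -> None:
    """Apply one of six mutation variants in place, drawn uniformly.

    add / replace build a fresh dipole pair; remove drops a random pair
    (redrawing another variant when k = 1, so individuals never empty);
    gene exchange substitutes one gene of a random pair by a uniform random
    gene distinct from its partner; weight mutation multiplies or divides a
    random pair's weight by 2; sign switch flips a random pair's relation.
    ``variant`` forces a specific variant (testing hook).
    """
    while True:
        v = int(rng.integers(6)) if variant is None else variant
        if v == MUT_REMOVE and ind.k == 1 and variant is None:
            continue
        break
    if v == MUT_ADD:
        ind.pairs.append(effective_pair_from_dipole(expr, labels, rng,
                                                    retry_limit))
    elif v == MUT_REMOVE:
        if ind.k > 1:
            ind.pairs.pop(int(rng.integers(ind.k)))
    elif v == MUT_REPLACE:
        ind.pairs[int(rng.integers(ind.k))] = effective_pair_from_dipole(
            expr, labels, rng, retry_limit)
    elif v == MUT_EXCHANGE_GENE:
        p = ind.pairs[int(rng.integers(ind.k))]
        slot = int(rng.integers(2))
        partner = p.j if slot == 0 else p.i
        g = int(rng.integers(expr.n_genes - 1))
        if g >= partner:
            g += 1
        if slot == 0:
            p.i = g
        else:
            p.j = g
    elif v == MUT_WEIGHT:
        p = ind.pairs[int(rng.integers(ind.k))]
        p.weight = p.weight * 2.0 if rng.random() < 0.5 else p.weight / 2.0
    elif v == MUT_SIGN:
        p = ind.pairs[int(rng.integers(ind.k))]
        p.less_votes_c1 = not p.less_votes_c1
    else:
        raise ValueError(f"unknown mutation variant {v}")
    ind.invalidate()


def rank_selection_probabilities(n: int) -> np.ndarray:
    """Linear-rank selection weights, worst-first: rank t gets t / (n(n+1)/2)."""
    t = np.arange(1, n + 1, dtype=float)
    return t / (n * (n + 1) / 2.0)


def select_next_generation(population: list, fitnesses: list,
                           rng: np.random.Generator) -> list:
    """Ranking linear selection with one elitist copy.

    The returned population has the same size; index 0 is a copy of the best
    individual (exempt from operators in its generation) and the remaining
    n−1 slots are drawn with replacement with probability proportional to
    rank. Fitness ties rank smaller individuals (fewer pairs, then canonical
    pair order) higher for determinism.
    """
    n = len(population)
    order = sorted(range(n), key=lambda t: (-fitnesses[t], population[t].k,
                                            population[t].sort_key()))
    # order[0] is best; selection ranks are worst-first
    worst_first = order[::-1]
    probs = rank_selection_probabilities(n)
    draws = rng.choice(n, size=n - 1, replace=True, p=probs)
    next_pop = [population[order[0]].copy()]
    next_pop.extend(population[worst_first[d]].copy() for d in draws)
    return next_pop


def evolve(expr: ExpressionMatrix, labels: LabelVector,
           config: EvoConfig) -> tuple:
    """Run the evolutionary loop; returns (best individual, history).

    history maps "best_fitness" (best-ever, non-decreasing), "mean_fitness",
    "best_k" and "best_u" to per-generation lists. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(expr, labels, config.alpha)
    population = init_population(expr, labels, config, rng)
    best_ever: Optional[Individual] = None
    best_fit = -np.inf
    stall = 0
    history = {"best_fitness": [], "mean_fitness": [], "best_k": [],
               "best_u": []}
    for gen in range(config.max_generations):
        fits = [evaluator.fitness(ind) for ind in population]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_ever = population[gen_best].copy()
            stall = 0
        else:
            stall += 1
        history["best_fitness"].append(best_fit)
        history["mean_fitness"].append(float(np.mean(fits)))
        history["best_k"].append(best_ever.k)
        history["best_u"].append(best_ever.u)
        if stall >= config.stall_generations or gen == config.max_generations - 1:
            break
        population = select_next_generation(population, fits, rng)
        workers = population[1:]  # index 0 is the protected elite copy
        flagged = [ind for ind in workers if rng.random() < config.p_crossover]
        perm = rng.permutation(len(flagged))
        for a_at in range(0, len(flagged) - 1, 2):
            a = flagged[perm[a_at]]
            b = flagged[perm[a_at + 1]]
            crossover(a, b, best_ever, rng, config.p_exchange_variant)
        for ind in workers:
            if rng.random() < config.p_mutation:
                mutate(ind, expr, labels, rng, config.dipole_retry_limit)
    return best_ever, history


class _Evaluator:
    """Fitness evaluation with a per-(i, j) cache of ordering vectors."""

    def __init__(self, expr: ExpressionMatrix, labels: LabelVector,
                 alpha: float):
        self.values = expr.values
        self.y = labels.y
        self.m = labels.n_samples
        self.tie = labels.majority_class_index
        self.alpha = alpha
        self._less: dict = {}

    def _less_vec(self, i: int, j: int) -> np.ndarray:
        key = (i, j)
        vec = self._less.get(key)
        if vec is None:
            vec = self.values[i] < self.values[j]
            self._less[key] = vec
        return vec

    def fitness(self, ind: Individual) -> float:
        if ind.cached_fitness is not None:
            return ind.cached_fitness
        margin = np.zeros(self.m)
        for p in ind.pairs:
            less = self._less_vec(p.i, p.j)
            sgn = np.where(less, 1.0, -1.0)
            if not p.less_votes_c1:
                sgn = -sgn
            margin += p.weight * sgn
        pred = np.where(margin > 0, 0, np.where(margin < 0, 1, self.tie))
        q = float(np.mean(pred == self.y))
        value = q - self.alpha * (2 * ind.k + ind.u)
        ind.cached_fitness = value
        return value


@dataclass(frozen=True)
class EvoTspModel:
    """A fitted weighted-pair ensemble, addressed by gene ids for portability."""

    pairs: tuple          # (gene_i, gene_j, less_votes_c1, weight)
    class_order: tuple
    majority_class: str
    alpha: float
    seed: int
    fitness: float
    history: dict

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def unique_genes(self) -> int:
        genes = set()
        for gi, gj, _, _ in self.pairs:
            genes.update((gi, gj))
        return len(genes)

    def predict(self, expr: ExpressionMatrix) -> list:
        c1, c2 = self.class_order
        margin = np.zeros(expr.n_samples)
        for gi, gj, lv, w in self.pairs:
            less = expr.values[expr.gene_index(gi)] < expr.values[expr.gene_index(gj)]
            sgn = np.where(less, 1.0, -1.0)
            if not lv:
                sgn = -sgn
            margin += w * sgn
        tie = self.majority_class
        return [c1 if m > 0 else (c2 if m < 0 else tie) for m in margin]

    def to_dict(self) -> dict:
        return {
            "method": "evotsp",
            "class_order": list(self.class_order),
            "pairs": [{"gene_i": gi, "gene_j": gj,
                       "sign": "lt" if lv else "ge", "weight": w}
                      for gi, gj, lv, w in self.pairs],
            "alpha": self.alpha,
            "seed": self.seed,
            "training_summary": {
                "fitness": self.fitness,
                "k": self.k,
                "unique_genes": self.unique_genes,
                "generations": len(self.history["best_fitness"]),
                "majority_class": self.majority_class,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvoTspModel":
        pairs = tuple((p["gene_i"], p["gene_j"], p["sign"] == "lt",
                       float(p.get("weight", 1.0))) for p in d["pairs"])
        summary = d.get("training_summary", {})
        return cls(pairs=pairs, class_order=tuple(d["class_order"]),
                   majority_class=summary.get("majority_class",
                                              d["class_order"][0]),
                   alpha=float(d.get("alpha", 0.005)),
                   seed=int(d.get("seed", 0)),
                   fitness=float(summary.get("fitness", float("nan"))),
                   history={"best_fitness": []})


def fit_evotsp(expr: ExpressionMatrix, labels: LabelVector,
               config: EvoConfig) -> EvoTspModel:
    """Evolve an ensemble on the full training data and package it as a model."""
    best, history = evolve(expr, labels, config)
    pairs = tuple((expr.gene_ids[p.i], expr.gene_ids[p.j], p.less_votes_c1,
                   p.weight) for p in best.pairs)
    c1, c2 = labels.class_order
    majority = c1 if labels.majority_class_index == 0 else c2
    return EvoTspModel(pairs=pairs, class_order=labels.class_order,
                       majority_class=majority, alpha=config.alpha,
                       seed=config.seed,
                       fitness=fitness(best, expr, labels, config.alpha),
                       history=history)
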