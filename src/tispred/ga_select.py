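"""Genetic-algorithm wrapper feature selection.

A chromosome is a bit-vector over the selectable (non-fixed) catalogue
descriptors; the fixed subset is always included when a chromosome is
decoded.  Fitness is the accuracy of the downstream network under
stratified 3-fold cross-validation on the training data, trained with a
reduced budget so that wrapper evaluation stays cheap; each evaluation's
seed derives from (GA seed, chromosome bits) so fitness is a pure
function of the chromosome.

Variation operators follow the classic recipe: single-point crossover and
independent per-bit mutation (15% per bit by default), with tournament
selection and elitism.  Termination is a fixed generation count, for
reproducibility.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .ann import ANNConfig, NeuralNetClassifier
from .errors import ConfigurationError
from .features import FeatureDescriptor

#: reduced training budget for wrapper evaluations; the higher full-batch
#: learning rate compensates for the short epoch budget
FITNESS_ANN = ANNConfig(learning_rate=0.5, max_epochs=60, patience=10)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 30
    mutation_rate: float = 0.15
    tournament_size: int = 3
    elitism: int = 1
    fitness_folds: int = 3
    seed: int = 0
    fitness_ann: ANNConfig = field(default_factory=lambda: FITNESS_ANN)

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("mutation_rate must be in [0,1]")
        if self.fitness_folds < 2:
            raise ConfigurationError("fitness_folds must be >= 2")
        if self.elitism >= self.population_size:
            raise ConfigurationError("elitism must be < population_size")


def mutate(chrom: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``; the input is
    left unmodified."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("mutation rate must be in [0,1]")
    chrom = np.asarray(chrom, dtype=np.uint8)
    flips = rng.random(chrom.shape[0]) < rate
    return chrom ^ flips.astype(np.uint8)


def crossover(
    a: np.ndarray,
    b: np.ndarray,
    point: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover: children swap suffixes after ``point``
    (1-based bit count kept from the first parent)."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ConfigurationError("parents must have equal length")
    L = a.shape[0]
    if L < 2:
        raise ConfigurationError("crossover needs chromosomes of length >= 2")
    if point is None:
        if rng is None:
            raise ConfigurationError("either point or rng must be given")
        point = int(rng.integers(1, L))
    if not 1 <= point <= L - 1:
        raise ConfigurationError(f"crossover point {point} outside 1..{L - 1}")
    c1 = np.concatenate([a[:point], b[point:]])
    c2 = np.concatenate([b[:point], a[point:]])
    return c1, c2


def selectable_indices(catalogue: Sequence[FeatureDescriptor]) -> list[int]:
    return [i for i, d in enumerate(catalogue) if not d.fixed]


def fixed_indices(catalogue: Sequence[FeatureDescriptor]) -> list[int]:
    return [i for i, d in enumerate(catalogue) if d.fixed]


def decode(chrom: np.ndarray, catalogue: Sequence[FeatureDescriptor]) -> list[int]:
    """Catalogue column indices encoded by a chromosome: the always-on fixed
    subset plus the switched-on selectable descriptors."""
    sel = selectable_indices(catalogue)
    if len(chrom) != len(sel):
        raise ConfigurationError(
            f"chromosome length {len(chrom)} != {len(sel)} selectable descriptors"
        )
    idx = fixed_indices(catalogue) + [sel[i] for i in range(len(sel)) if chrom[i]]
    return sorted(idx)


def _eval_seed(seed: int, chrom: np.ndarray) -> int:
    return (zlib.crc32(np.asarray(chrom, dtype=np.uint8).tobytes()) ^ (seed & 0xFFFFFFFF)) % (2**31 - 1)


def fitness(
    chrom: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    catalogue: Sequence[FeatureDescriptor],
    cfg: GAConfig = GAConfig(),
) -> float:
    """Cross-validated accuracy of the network on the decoded feature set.

    ``X`` is the full-catalogue feature matrix of the training windows; the
    chromosome selects columns.  Decoding to zero features (possible only
    with an empty fixed subset) scores 0 by convention.
    """
    idx = decode(chrom, catalogue)
    fx = fixed_indices(catalogue)
    assert set(fx) <= set(idx), "fixed subset must always be included"
    if not idx:
        return 0.0
    seed = _eval_seed(cfg.seed, chrom)
    skf = StratifiedKFold(n_splits=cfg.fitness_folds, shuffle=True, random_state=seed)
    Xs = X[:, idx]
    accs = []
    for k, (tr, te) in enumerate(skf.split(Xs, y)):
        net_cfg = ANNConfig(**{**cfg.fitness_ann.__dict__, "seed": (seed + k) % (2**31 - 1)})
        net = NeuralNetClassifier(**net_cfg.__dict__)
        net.fit(Xs[tr], y[tr])
        accs.append(float(np.mean(net.predict(Xs[te]) == y[te])))
    return float(np.mean(accs))


@dataclass
class GAResult:
    selected: list[FeatureDescriptor]
    support: np.ndarray  # boolean over the full catalogue
    best_bits: np.ndarray
    best_fitness: float
    history: pd.DataFrame  # generation, best_fitness, mean_fitness


def run_ga(
    X: np.ndarray,
    y: np.ndarray,
    catalogue: Sequence[FeatureDescriptor],
    cfg: GAConfig = GAConfig(),
) -> GAResult:
    """Evolve feature subsets; returns the fixed subset plus the selectable
    features of the best-ever chromosome, with a per-generation history."""
    rng = np.random.default_rng(cfg.seed)
    sel = selectable_indices(catalogue)
    L = len(sel)
    cache: dict[bytes, float] = {}

    def ev(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = fitness(bits, X, y, catalogue, cfg)
        return cache[key]

    if L == 0:
        bits = np.zeros(0, dtype=np.uint8)
        f = ev(bits)
        history = pd.DataFrame(
            [{"generation": 0, "best_fitness": f, "mean_fitness": f}]
        )
        return _result(bits, f, catalogue, history)

    pop = rng.integers(0, 2, size=(cfg.population_size, L), dtype=np.uint8)
    best_bits, best_fit = None, -1.0
    rows = []
    for gen in range(cfg.generations):
        fits = np.array([ev(ind) for ind in pop])
        gi = int(np.argmax(fits))
        if fits[gi] > best_fit:
            best_fit, best_bits = float(fits[gi]), pop[gi].copy()
        rows.append({"generation": gen, "best_fitness": float(fits.max()),
                     "mean_fitness": float(fits.mean())})
        if gen == cfg.generations - 1:
            break
        elite_order = np.argsort(-fits, kind="stable")[: cfg.elitism]
        new_pop = [pop[i].copy() for i in elite_order]
        while len(new_pop) < cfg.population_size:
            p1 = _tournament(pop, fits, cfg.tournament_size, rng)
            p2 = _tournament(pop, fits, cfg.tournament_size, rng)
            if L >= 2:
                c1, c2 = crossover(p1, p2, rng=rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            new_pop.append(mutate(c1, cfg.mutation_rate, rng))
            if len(new_pop) < cfg.population_size:
                new_pop.append(mutate(c2, cfg.mutation_rate, rng))
        pop = np.array(new_pop, dtype=np.uint8)
    history = pd.DataFrame(rows)
    return _result(best_bits, best_fit, catalogue, history)


def _tournament(pop, fits, k, rng) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmax(fits[idx])]]


def _result(bits, fit, catalogue, history) -> GAResult:
    idx = decode(bits, catalogue)
    support = np.zeros(len(catalogue), dtype=bool)
    support[idx] = True
    return GAResult(
        selected=[catalogue[i] for i in idx],
        support=support,
        best_bits=np.asarray(bits, dtype=np.uint8),
        best_fitness=fit,
        history=history,
    )


class GeneticFeatureSelector(BaseEstimator):
    """sklearn-style selector over a feature catalogue.

    ``fit(X, y)`` takes the full-catalogue feature matrix and labels;
    ``transform(X)`` keeps the selected columns (fixed subset always
    included).

    Attributes: ``support_`` boolean mask over catalogue columns,
    ``selected_`` the chosen descriptors, ``history_`` per-generation best
    and mean fitness, ``best_fitness_``.
    """

    def __init__(self, catalogue: Sequence[FeatureDescriptor],
                 population_size: int = 50, generations: int = 30,
                 mutation_rate: float = 0.15, tournament_size: int = 3,
                 elitism: int = 1, fitness_folds: int = 3, seed: int = 0,
                 fitness_ann: ANNConfig = FITNESS_ANN):
        self.catalogue = catalogue
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.elitism = elitism
        self.fitness_folds = fitness_folds
        self.seed = seed
        self.fitness_ann = fitness_ann

    def fit(self, X, y):
        cfg = GAConfig(self.population_size, self.generations, self.mutation_rate,
                       self.tournament_size, self.elitism, self.fitness_folds,
                       self.seed, self.fitness_ann)
        res = run_ga(np.asarray(X, dtype=float), np.asarray(y), self.catalogue, cfg)
        self.support_ = res.support
        self.selected_ = res.selected
        self.best_bits_ = res.best_bits
        self.best_fitness_ = res.best_fitness
        self.history_ = res.history
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.support_]
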