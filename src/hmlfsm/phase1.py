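"""Phase 1: information-gain filtering plus genetic-algorithm wrapper search.

Each gene is scored by the information gain of its (supervised-MDL
discretized) values against the tumour/normal labels; genes whose gain
does not exceed the threshold (default: exactly zero) are eliminated.  A
genetic algorithm then searches binary masks over the surviving genes,
scoring candidates by cross-validated classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset, SplitPlan
from .info import discretize_gene, information_gain
from .wrapper import SubsetFitness


@dataclass
class IGScores:
    """Per-gene information gain (bits) and the bin boundaries used."""

    gains: np.ndarray
    boundaries: list
    gene_ids: np.ndarray

    @property
    def n_bins(self) -> np.ndarray:
        return np.asarray([len(b) + 1 for b in self.boundaries], dtype=int)


def ig_scores(ds: ExpressionDataset, method: str = "mdl", bins: int = 4) -> IGScores:
    """Information gain of every gene after per-gene discretization."""
    gains = np.empty(ds.n_genes)
    boundaries = []
    for j in range(ds.n_genes):
        codes, cuts = discretize_gene(ds.matrix[:, j], ds.labels, method=method, bins=bins)
        gains[j] = information_gain(codes, ds.labels) if cuts.size else 0.0
        boundaries.append(cuts)
    return IGScores(gains=gains, boundaries=boundaries, gene_ids=ds.gene_ids.copy())


def ig_filter(
    ds: ExpressionDataset,
    threshold: float = 0.0,
    method: str = "mdl",
    bins: int = 4,
) -> tuple[ExpressionDataset, IGScores]:
    """Drop genes whose information gain is <= ``threshold``.

    Scores are returned for *all* input genes; the surviving genes keep
    their original relative order.  Raises if nothing survives, pointing
    at the threshold, since downstream stages need at least one gene.
    """
    scores = ig_scores(ds, method=method, bins=bins)
    keep = np.flatnonzero(scores.gains > threshold)
    if keep.size == 0:
        raise ValueError(
            f"information-gain filter at threshold {threshold} removed every gene; "
            "lower the threshold or check the labels"
        )
    return ds.subset_genes(keep, provenance=f"{ds.provenance}|ig_filter"), scores


@dataclass
class GAConfig:
    """Genetic-algorithm settings (conventional small-GA defaults)."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1/L per bit
    elitism: int = 1
    tournament_size: int = 3
    fitness_size_weight: float = 0.0
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")
        for name in ("crossover_rate", "fitness_size_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    fitness_history: list = field(default_factory=list)
    evaluations: int = 0


def _mask_key(fitness: float, mask: np.ndarray):
    """Ordering key: higher fitness, then *more* selected genes, then
    lexicographically smaller mask — a total order making the search fully
    deterministic.

    Phase 1 is recall-oriented: once cross-validated accuracy saturates,
    ties resolve toward retaining more information-rich genes, leaving
    redundancy reduction and parsimony to phase 2.
    """
    return (-fitness, -int(mask.sum()), tuple(mask.astype(int)))


def ga_fitness(
    mask,
    ds: ExpressionDataset,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    size_weight: float = 0.0,
    seed: int = 0,
) -> float:
    """Fitness of one mask: CV accuracy with an optional subset-size bonus."""
    return SubsetFitness(ds, classifier, protocol, size_weight=size_weight, seed=seed)(mask)


def ga_select(
    ds: ExpressionDataset,
    config: GAConfig | None = None,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    fitness_fn=None,
) -> GAResult:
    """Search binary gene masks with a generational GA.

    Tournament selection, one-point crossover, per-bit mutation and
    elitism; stops after ``generations`` rounds or once the best-ever
    fitness has stagnated for ``patience`` generations.  ``fitness_fn``
    (mask -> float) overrides the cross-validated default, which is how
    surrogate objectives are injected in tests.
    """
    if ds.n_genes < 1:
        raise ValueError("dataset has no genes to search over")
    config = config or GAConfig()
    L = ds.n_genes
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    if fitness_fn is None:
        scorer = SubsetFitness(
            ds,
            classifier,
            protocol,
            size_weight=config.fitness_size_weight,
            seed=config.seed,
        )
        fitness_fn = scorer
    else:
        scorer = None

    # sparse initialization keeps early subsets small when L is large
    p0 = min(0.5, 100.0 / L)
    pop = rng.random((config.population_size, L)) < p0
    fits = np.asarray([fitness_fn(ind) for ind in pop])

    best_idx = min(range(len(pop)), key=lambda i: _mask_key(fits[i], pop[i]))
    best_mask = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    history = [best_fit]
    stagnant = 0

    for _ in range(config.generations):
        order = sorted(range(len(pop)), key=lambda i: _mask_key(fits[i], pop[i]))
        elites = [pop[i].copy() for i in order[: config.elitism]]

        children: list[np.ndarray] = list(elites)
        while len(children) < config.population_size:
            # tournament selection for two parents
            parents = []
            for _p in range(2):
                contenders = rng.integers(0, len(pop), size=config.tournament_size)
                win = min(contenders, key=lambda i: _mask_key(fits[i], pop[i]))
                parents.append(pop[win])
            a, b = parents[0].copy(), parents[1].copy()
            if L > 1 and rng.random() < config.crossover_rate:
                point = int(rng.integers(1, L))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b):
                flip = rng.random(L) < mut
                child ^= flip
                if len(children) < config.population_size:
                    children.append(child)
        pop = np.asarray(children)
        fits = np.asarray([fitness_fn(ind) for ind in pop])

        gen_best = min(range(len(pop)), key=lambda i: _mask_key(fits[i], pop[i]))
        if _mask_key(fits[gen_best], pop[gen_best]) < _mask_key(best_fit, best_mask):
            best_mask = pop[gen_best].copy()
            best_fit = float(fits[gen_best])
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        if stagnant >= config.patience:
            break

    evaluations = scorer.evaluations if scorer is not None else len(history) * config.population_size
    return GAResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        fitness_history=history,
        evaluations=evaluations,
    )


def phase1(
    ds: ExpressionDataset,
    ig_threshold: float = 0.0,
    config: GAConfig | None = None,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    method: str = "mdl",
):
    """IG filter then GA wrapper; returns ``(selected dataset, scores, GAResult)``.

    The returned dataset contains exactly the genes of the GA's best mask,
    in their original order.
    """
    filtered, scores = ig_filter(ds, threshold=ig_threshold, method=method)
    result = ga_select(filtered, config=config, classifier=classifier, protocol=protocol)
    if not result.best_mask.any():
        # degenerate but possible under a pathological objective: keep the
        # top-gain gene so downstream stages stay well-defined
        top = int(np.argmax(scores.gains[scores.gains > ig_threshold]))
        result.best_mask[top] = True
    selected = filtered.subset_genes(
        np.flatnonzero(result.best_mask), provenance=f"{ds.provenance}|phase1"
    )
    return selected, scores, result
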