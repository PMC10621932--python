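"""Phase 2: mRMR relevance/redundancy ranking plus binary-PSO refinement.

Minimum-redundancy-maximum-relevance greedily ranks the phase-1 genes by
their mutual information with the class label, penalising the average
mutual information with genes already picked (difference form "MID" by
default, quotient form "MIQ" available).  The top-ranked pool then seeds
a binary particle swarm whose fitness is cross-validated classification
accuracy; particle bits are resampled through a sigmoid of the velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset, FeatureSubset, SplitPlan
from .info import discretize_gene, mutual_information
from .wrapper import SubsetFitness

MIQ_EPS = 1e-6  # floor for the quotient-form denominator


@dataclass
class MrmrScores:
    """Greedy mRMR ranking with the statistics behind each pick.

    ``redundancy[t]`` holds the mutual information between the gene picked
    at step ``t`` and every gene, so the matrix is selection-steps x genes
    (pairwise values are only materialised where the greedy rule needs
    them; mutual information itself is symmetric).
    """

    relevance: np.ndarray
    redundancy: np.ndarray
    selection_order: np.ndarray
    greedy_scores: np.ndarray
    scheme: str
    gene_ids: np.ndarray


def _binned_matrix(ds: ExpressionDataset, method: str, bins: int) -> list[np.ndarray]:
    cols = []
    for j in range(ds.n_genes):
        codes, _ = discretize_gene(ds.matrix[:, j], ds.labels, method=method, bins=bins)
        cols.append(codes)
    return cols


def mrmr_rank(
    ds: ExpressionDataset,
    k: int,
    scheme: str = "MID",
    method: str = "mdl",
    bins: int = 4,
) -> MrmrScores:
    """Rank ``k`` genes by greedy maximum-relevance minimum-redundancy.

    First pick: the gene with maximal mutual information with the labels.
    Step ``t``: argmax over unselected genes of ``relevance - mean
    redundancy`` (MID) or ``relevance / max(mean redundancy, eps)`` (MIQ),
    redundancy being the mean MI with the already-selected genes.  Ties
    break toward the lower gene index.
    """
    scheme = scheme.upper()
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    if not 1 <= k <= ds.n_genes:
        raise ValueError(f"k must lie in [1, {ds.n_genes}], got {k}")
    binned = _binned_matrix(ds, method, bins)
    relevance = np.asarray(
        [mutual_information(b, ds.labels) for b in binned]
    )

    selected: list[int] = []
    scores: list[float] = []
    redundancy_rows: list[np.ndarray] = []
    red_sum = np.zeros(ds.n_genes)
    available = np.ones(ds.n_genes, dtype=bool)

    for step in range(k):
        if step == 0:
            objective = relevance.copy()
        else:
            mean_red = red_sum / step
            if scheme == "MID":
                objective = relevance - mean_red
            else:
                objective = relevance / np.maximum(mean_red, MIQ_EPS)
        objective[~available] = -np.inf
        pick = int(np.argmax(objective))  # argmax takes the lowest index on ties
        selected.append(pick)
        scores.append(float(objective[pick]))
        available[pick] = False
        row = np.asarray(
            [mutual_information(binned[pick], binned[j]) for j in range(ds.n_genes)]
        )
        redundancy_rows.append(row)
        red_sum += row

    return MrmrScores(
        relevance=relevance,
        redundancy=np.asarray(redundancy_rows),
        selection_order=np.asarray(selected, dtype=int),
        greedy_scores=np.asarray(scores),
        scheme=scheme,
        gene_ids=ds.gene_ids.copy(),
    )


@dataclass
class PSOConfig:
    """Binary-PSO settings (constriction-style constants by default)."""

    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    v_max: float = 4.0
    patience: int = 20
    pool_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class SwarmState:
    """Final swarm snapshot plus the per-iteration best-fitness trace."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_masks: np.ndarray
    pbest_fitness: np.ndarray
    gbest_mask: np.ndarray
    gbest_fitness: float
    iteration: int
    gbest_history: list = field(default_factory=list)


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _better(fit_a: float, mask_a: np.ndarray, fit_b: float, mask_b: np.ndarray) -> bool:
    """True when (fit_a, mask_a) improves on (fit_b, mask_b): higher fitness,
    then more selected genes, then lexicographically smaller mask.

    The candidate pool is already redundancy-screened, so at equal
    accuracy ties resolve toward retaining more of the relevant genes
    (mirroring the phase-1 wrapper).
    """
    ka = (-fit_a, -int(mask_a.sum()), tuple(mask_a.astype(int)))
    kb = (-fit_b, -int(mask_b.sum()), tuple(mask_b.astype(int)))
    return ka < kb


def bpso_fitness(
    mask,
    ds: ExpressionDataset,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    seed: int = 0,
) -> float:
    """Pure cross-validated accuracy of the masked subset (no size term)."""
    return SubsetFitness(ds, classifier, protocol, size_weight=0.0, seed=seed)(mask)


def bpso_select(
    ds: ExpressionDataset,
    candidates,
    config: PSOConfig | None = None,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    fitness_fn=None,
    init_prob=None,
) -> tuple[FeatureSubset, SwarmState]:
    """Binary particle swarm over masks of the candidate genes.

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``
    clamped to ``±v_max``; each bit is then resampled to 1 with
    probability ``sigmoid(v)``.  Personal and global bests update on
    strict improvement (higher fitness, ties toward more genes), so the
    gbest fitness trace is non-decreasing.  ``fitness_fn`` (full-length
    mask -> float) overrides the CV objective; ``init_prob`` biases the
    initial per-bit on-probability (scalar or per-candidate vector).
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate set is empty")
    config = config or PSOConfig()
    rng = np.random.default_rng(config.seed)
    L = candidates.size
    S = config.swarm_size

    if fitness_fn is None:
        scorer = SubsetFitness(ds, classifier, protocol, size_weight=0.0, seed=config.seed)
        fitness_fn = scorer

    def expand(mask_l: np.ndarray) -> np.ndarray:
        full = np.zeros(ds.n_genes, dtype=bool)
        full[candidates[mask_l]] = True
        return full

    p_init = np.full(L, 0.5) if init_prob is None else np.broadcast_to(
        np.asarray(init_prob, dtype=float), (L,)
    )
    positions = rng.random((S, L)) < p_init
    velocities = np.zeros((S, L))

    fits = np.asarray([fitness_fn(expand(p)) for p in positions])
    pbest = positions.copy()
    pbest_fit = fits.copy()
    g = min(range(S), key=lambda i: (-pbest_fit[i], -int(pbest[i].sum()), tuple(pbest[i].astype(int))))
    gbest = pbest[g].copy()
    gbest_fit = float(pbest_fit[g])
    history = [gbest_fit]
    stagnant = 0
    it = 0

    for it in range(1, config.iterations + 1):
        r1 = rng.random((S, L))
        r2 = rng.random((S, L))
        velocities = (
            config.inertia * velocities
            + config.cognitive * r1 * (pbest.astype(float) - positions.astype(float))
            + config.social * r2 * (gbest.astype(float)[None, :] - positions.astype(float))
        )
        np.clip(velocities, -config.v_max, config.v_max, out=velocities)
        positions = rng.random((S, L)) < sigmoid(velocities)
        fits = np.asarray([fitness_fn(expand(p)) for p in positions])

        improved = False
        for i in range(S):
            if _better(fits[i], positions[i], pbest_fit[i], pbest[i]):
                pbest[i] = positions[i].copy()
                pbest_fit[i] = fits[i]
                if _better(pbest_fit[i], pbest[i], gbest_fit, gbest):
                    gbest = pbest[i].copy()
                    gbest_fit = float(pbest_fit[i])
                    improved = True
        history.append(gbest_fit)
        stagnant = 0 if improved else stagnant + 1
        if stagnant >= config.patience:
            break

    if not gbest.any():
        # all-zero optimum only arises under degenerate objectives; keep the
        # first candidate so the returned subset is usable downstream
        gbest[0] = True
        gbest_fit = float(fitness_fn(expand(gbest)))

    subset = FeatureSubset(
        indices=candidates[np.flatnonzero(gbest)],
        gene_ids=ds.gene_ids[candidates[np.flatnonzero(gbest)]],
        provenance="phase2:bpso",
    )
    state = SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_masks=pbest,
        pbest_fitness=pbest_fit,
        gbest_mask=gbest,
        gbest_fitness=gbest_fit,
        iteration=it,
        gbest_history=history,
    )
    return subset, state


def phase2(
    ds_phase1: ExpressionDataset,
    mrmr_k: int | None = None,
    pso_config: PSOConfig | None = None,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    scheme: str = "MID",
    return_details: bool = False,
):
    """mRMR ranking then binary-PSO refinement of the phase-1 genes.

    The candidate pool is the top ``pool_size`` mRMR-ranked genes that
    pass a duplicate screen: a gene sharing more mutual information with
    any single higher-ranked gene than it carries about the class label
    is a near-copy of that gene — exactly the "redundant,
    non-informative" case the ranking exists to eliminate — and never
    reaches the swarm.  (The greedy rule's *mean* redundancy dilutes a
    single high-MI pair once several genes are selected, so the screen
    uses the pairwise maximum.)  Particles are initialised with a
    per-bit on-probability decaying linearly from 0.9 (top rank) to 0.1
    (bottom of the pool), so the search starts from relevance-ordered,
    redundancy-penalised subsets.
    Returns the selected :class:`FeatureSubset` (indices into
    ``ds_phase1``), plus the mRMR scores and swarm state when
    ``return_details`` is set.
    """
    pso_config = pso_config or PSOConfig()
    k = mrmr_k if mrmr_k is not None else ds_phase1.n_genes
    k = min(k, ds_phase1.n_genes)
    scores = mrmr_rank(ds_phase1, k=k, scheme=scheme)

    # duplicate screen: drop genes whose MI with some higher-ranked gene
    # exceeds their MI with the class
    keep = np.ones(len(scores.selection_order), dtype=bool)
    for t, g in enumerate(scores.selection_order):
        if t == 0:
            continue  # the max-relevance pick always qualifies
        max_pair = scores.redundancy[:t, g].max()
        keep[t] = scores.relevance[g] > max_pair
    eligible = scores.selection_order[keep]

    pool_size = pso_config.pool_size
    if pool_size > len(scores.selection_order):
        warnings.warn(
            f"pool_size {pool_size} exceeds ranked gene count "
            f"{len(scores.selection_order)}; clipping",
            stacklevel=2,
        )
    pool_size = min(pool_size, len(eligible))
    candidates = eligible[:pool_size]

    if pool_size == 1:
        subset = FeatureSubset(
            indices=candidates,
            gene_ids=ds_phase1.gene_ids[candidates],
            provenance="phase2:mrmr-top1",
        )
        state = None
    else:
        init_prob = np.linspace(0.9, 0.1, pool_size)
        subset, state = bpso_select(
            ds_phase1,
            candidates,
            config=pso_config,
            classifier=classifier,
            protocol=protocol,
            init_prob=init_prob,
        )
    if return_details:
        return subset, scores, state
    return subset
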