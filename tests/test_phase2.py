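"""mRMR ranking and binary particle-swarm refinement."""

import itertools

import numpy as np
import pytest

from hmlfsm import (
    PSOConfig,
    SplitPlan,
    SyntheticSpec,
    bpso_fitness,
    bpso_select,
    ga_fitness,
    generate,
    mrmr_rank,
    phase2,
)
from hmlfsm.info import discretize_gene, mutual_information
from hmlfsm.phase2 import sigmoid


# -- independent brute-force greedy oracle ---------------------------------


def mrmr_oracle_order(ds, k, scheme="MID", eps=1e-6):
    """Re-implementation of the greedy rule with explicit loops."""
    binned = [
        discretize_gene(ds.matrix[:, j], ds.labels, method="mdl")[0]
        for j in range(ds.n_genes)
    ]
    rel = [mutual_information(binned[j], ds.labels) for j in range(ds.n_genes)]
    pair = [[mutual_information(binned[i], binned[j]) for j in range(ds.n_genes)]
            for i in range(ds.n_genes)]
    selected = []
    for _ in range(k):
        best, best_score = None, None
        for g in range(ds.n_genes):
            if g in selected:
                continue
            if not selected:
                score = rel[g]
            else:
                red = sum(pair[s][g] for s in selected) / len(selected)
                score = rel[g] - red if scheme == "MID" else rel[g] / max(red, eps)
            if best is None or score > best_score:  # strict: ties keep lower g
                best, best_score = g, score
        selected.append(best)
    return selected


class TestMrmrRank:
    def test_k1_is_max_relevance(self, make_dataset, rng):
        labels = np.tile([0, 1], 15)
        matrix = rng.normal(size=(30, 4))
        matrix[:, 2] = labels * 6.0 + rng.normal(scale=0.2, size=30)
        ds = make_dataset(matrix, labels)
        scores = mrmr_rank(ds, k=1)
        assert scores.selection_order.tolist() == [2]
        assert scores.greedy_scores[0] == pytest.approx(scores.relevance[2])

    def test_duplicate_penalised_after_parent(self, make_dataset):
        # A and B identical and max-relevance; C independent with slightly
        # lower relevance: greedy MID order must be A, C, B
        r = np.random.default_rng(2)
        labels = np.tile([0, 1], 20)
        a = labels * 2.0 + r.normal(scale=1.0, size=40)
        c = labels * 2.0 + r.normal(scale=1.0, size=40)
        ds = make_dataset(np.column_stack([a, a.copy(), c]), labels,
                          gene_ids=["A", "B", "C"])
        rel = mrmr_rank(ds, k=1).relevance
        assert rel[0] == rel[1] > rel[2]  # the planted relevance pattern holds
        scores = mrmr_rank(ds, k=3, scheme="MID")
        assert [str(g) for g in scores.gene_ids[scores.selection_order]] == ["A", "C", "B"]
        assert scores.selection_order.tolist() == mrmr_oracle_order(ds, 3)

    def test_full_ranking_is_permutation_matching_oracle(self, make_dataset, rng):
        labels = np.tile([0, 1], 12)
        matrix = rng.normal(size=(24, 6))
        matrix[:, 0] = labels * 3 + rng.normal(scale=0.5, size=24)
        matrix[:, 4] = matrix[:, 0] + rng.normal(scale=0.4, size=24)
        ds = make_dataset(matrix, labels)
        scores = mrmr_rank(ds, k=6)
        assert sorted(scores.selection_order.tolist()) == list(range(6))
        assert scores.selection_order.tolist() == mrmr_oracle_order(ds, 6)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for rep in range(25):
            n_genes = int(rng.integers(3, 9))
            scheme = "MID" if rep % 2 == 0 else "MIQ"
            ds, _ = generate(SyntheticSpec(
                n_samples=40, n_genes=n_genes,
                n_informative=min(2, n_genes), effect_size=1.5,
                seed=int(rng.integers(0, 2**31)),
            ))
            k = int(rng.integers(1, n_genes + 1))
            got = mrmr_rank(ds, k=k, scheme=scheme).selection_order.tolist()
            assert got == mrmr_oracle_order(ds, k, scheme=scheme)

    def test_k_out_of_range(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(10, 3)), np.tile([0, 1], 5))
        with pytest.raises(ValueError):
            mrmr_rank(ds, k=0)
        with pytest.raises(ValueError):
            mrmr_rank(ds, k=4)

    def test_relevance_and_redundancy_nonnegative(self, make_dataset, rng):
        ds, _ = generate(SyntheticSpec(n_samples=30, n_genes=8, n_informative=3, seed=11))
        scores = mrmr_rank(ds, k=8)
        assert (scores.relevance >= 0).all()
        assert (scores.redundancy >= -1e-12).all()


class TestBpso:
    def test_sigmoid_midpoint(self):
        assert sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_zero_velocity_resamples_half(self, make_dataset, rng):
        # with velocity 0 each bit is an independent fair coin
        draws = rng.random((4000,)) < sigmoid(np.zeros(4000))
        assert 0.45 < draws.mean() < 0.55

    def test_fitness_shares_implementation_with_ga(self, separable_dataset, rng):
        ds, _ = separable_dataset
        plan = SplitPlan("kfold", k=5, seed=2)
        for _ in range(20):
            mask = rng.random(ds.n_genes) < 0.5
            if not mask.any():
                continue
            assert bpso_fitness(mask, ds, "1nn", plan) == pytest.approx(
                ga_fitness(mask, ds, "1nn", plan, size_weight=0.0)
            )

    def test_bitcount_surrogate_reaches_all_ones(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(8, 8)), np.tile([0, 1], 4))
        cfg = PSOConfig(swarm_size=10, iterations=50, seed=0)
        subset, state = bpso_select(
            ds, np.arange(8), cfg, fitness_fn=lambda m: m.sum() / m.size
        )
        # oracle: exhaustive search over all 256 masks puts the optimum at all-ones
        assert state.gbest_fitness == pytest.approx(1.0)
        assert len(subset) == 8

    def test_gbest_trace_monotone(self, separable_dataset):
        ds, _ = separable_dataset
        cfg = PSOConfig(swarm_size=8, iterations=15, seed=5)
        _, state = bpso_select(ds, np.arange(ds.n_genes), cfg,
                               protocol=SplitPlan("kfold", k=5, seed=5))
        assert all(b >= a for a, b in itertools.pairwise(state.gbest_history))
        assert state.gbest_fitness == max(state.pbest_fitness)

    def test_bit_identical_reruns(self, separable_dataset):
        ds, _ = separable_dataset
        cfg = PSOConfig(swarm_size=6, iterations=10, seed=8)
        plan = SplitPlan("kfold", k=5, seed=8)
        sa, sta = bpso_select(ds, np.arange(ds.n_genes), cfg, protocol=plan)
        sb, stb = bpso_select(ds, np.arange(ds.n_genes), cfg, protocol=plan)
        np.testing.assert_array_equal(sa.indices, sb.indices)
        assert sta.gbest_history == stb.gbest_history

    def test_empty_candidates_rejected(self, separable_dataset):
        ds, _ = separable_dataset
        with pytest.raises(ValueError):
            bpso_select(ds, np.array([], dtype=int), PSOConfig(seed=0))


class TestPhase2:
    def test_singleton_pool_returns_top_mrmr_gene(self, make_dataset, rng):
        labels = np.tile([0, 1], 15)
        matrix = rng.normal(size=(30, 5))
        matrix[:, 4] = labels * 6.0 + rng.normal(scale=0.2, size=30)
        ds = make_dataset(matrix, labels)
        subset = phase2(ds, pso_config=PSOConfig(pool_size=1, seed=0))
        assert subset.indices.tolist() == [4]

    def test_subset_never_larger_than_input(self):
        ds, _ = generate(SyntheticSpec(n_samples=60, n_genes=25, n_informative=5,
                                       n_redundant=5, seed=3))
        with pytest.warns(UserWarning, match="pool_size"):
            subset = phase2(ds, pso_config=PSOConfig(seed=3, iterations=20))
        assert 1 <= len(subset) <= ds.n_genes

    def test_redundant_copies_screened_out(self):
        ds, truth = generate(SyntheticSpec(n_samples=150, n_genes=30, n_informative=5,
                                           n_redundant=5, effect_size=2.0, seed=1))
        with pytest.warns(UserWarning, match="pool_size"):
            subset, scores, state = phase2(
                ds, pso_config=PSOConfig(seed=1), return_details=True
            )
        chosen = set(subset.indices.tolist())
        assert len(chosen & set(truth.informative_indices.tolist())) >= 4
        assert len(chosen & set(truth.redundant_map)) <= 1
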