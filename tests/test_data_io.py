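"""Loading, preprocessing and split construction."""

import numpy as np
import pytest

from hmlfsm import (
    ExpressionDataset,
    LoadError,
    SplitPlan,
    load_expression_table,
    make_split,
    pca_project,
    remove_duplicate_genes,
    shuffle_samples,
    zscore_normalize,
)


def _write_samples_in_rows(tmp_path, name="expr.csv"):
    path = tmp_path / name
    path.write_text(
        "sample,geneA,label\n"
        "s1,1.5,tumour\n"
        "s2,2.5,normal\n"
        "s3,3.5,tumour\n"
    )
    return path


class TestLoad:
    def test_minimal_parse(self, tmp_path):
        ds = load_expression_table(_write_samples_in_rows(tmp_path), label_column="label")
        assert ds.n_samples == 3 and ds.n_genes == 1
        assert list(ds.gene_ids) == ["geneA"]
        np.testing.assert_array_equal(ds.labels, [1, 0, 1])
        np.testing.assert_allclose(ds.matrix.ravel(), [1.5, 2.5, 3.5])

    def test_orientation_symmetry(self, tmp_path):
        straight = load_expression_table(
            _write_samples_in_rows(tmp_path), label_column="label"
        )
        t_path = tmp_path / "transposed.csv"
        t_path.write_text("gene,s1,s2,s3\ngeneA,1.5,2.5,3.5\n")
        lab_path = tmp_path / "labels.csv"
        lab_path.write_text("sample,label\ns1,tumour\ns2,normal\ns3,tumour\n")
        flipped = load_expression_table(
            t_path, orientation="genes-in-rows", labels_path=lab_path
        )
        np.testing.assert_allclose(straight.matrix, flipped.matrix)
        np.testing.assert_array_equal(straight.labels, flipped.labels)
        assert list(straight.gene_ids) == list(flipped.gene_ids)

    def test_na_cell_rejected_with_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,geneA,label\ns1,NA,tumour\ns2,2.0,normal\n")
        with pytest.raises(LoadError, match="geneA"):
            load_expression_table(path, label_column="label")

    def test_na_cell_mean_imputed_on_request(self, tmp_path):
        path = tmp_path / "imp.csv"
        path.write_text(
            "sample,geneA,label\ns1,NA,tumour\ns2,2.0,normal\ns3,4.0,tumour\n"
        )
        ds = load_expression_table(path, label_column="label", impute="mean")
        assert ds.matrix[0, 0] == pytest.approx(3.0)

    def test_more_than_two_label_values_rejected(self, tmp_path):
        path = tmp_path / "tri.csv"
        path.write_text(
            "sample,geneA,label\ns1,1,tumour\ns2,2,normal\ns3,3,other\n"
        )
        with pytest.raises(LoadError, match="2 label values"):
            load_expression_table(path, label_column="label")

    def test_missing_labels_rejected(self, tmp_path):
        path = tmp_path / "nolab.csv"
        path.write_text("sample,geneA\ns1,1\ns2,2\n")
        with pytest.raises(LoadError, match="label"):
            load_expression_table(path)


class TestDeduplicate:
    def test_first_occurrence_kept(self, make_dataset):
        ds = make_dataset([[1, 2, 3], [4, 5, 6]], [0, 1], gene_ids=["g1", "g1", "g2"])
        out, removed = remove_duplicate_genes(ds)
        assert removed == 1
        assert list(out.gene_ids) == ["g1", "g2"]
        np.testing.assert_allclose(out.matrix, [[1, 3], [4, 6]])

    def test_no_duplicates_is_identity(self, make_dataset):
        ds = make_dataset([[1, 2], [3, 4]], [0, 1])
        out, removed = remove_duplicate_genes(ds)
        assert removed == 0
        np.testing.assert_allclose(out.matrix, ds.matrix)

    def test_two_duplicate_pairs(self, make_dataset):
        ds = make_dataset(
            np.arange(10).reshape(2, 5), [0, 1], gene_ids=["a", "b", "a", "c", "b"]
        )
        out, removed = remove_duplicate_genes(ds)
        assert removed == 2 and out.n_genes == 3
        assert list(out.gene_ids) == ["a", "b", "c"]

    def test_profile_collapse_optional(self, make_dataset):
        ds = make_dataset([[1, 1, 2], [3, 3, 4]], [0, 1], gene_ids=["a", "b", "c"])
        out, removed = remove_duplicate_genes(ds, by_profile=True)
        assert removed == 1 and list(out.gene_ids) == ["a", "c"]


class TestZscore:
    def test_three_point_gene(self, make_dataset):
        ds = make_dataset([[1.0], [2.0], [3.0]], [0, 1, 1])
        out = zscore_normalize(ds)
        np.testing.assert_allclose(
            out.matrix.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_idempotent_on_standardized_gene(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(20, 3)), rng.integers(0, 2, 20))
        once = zscore_normalize(ds)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-12)

    def test_constant_gene_zeroed_with_warning(self, make_dataset):
        ds = make_dataset([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], [0, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_normalize(ds)
        np.testing.assert_array_equal(out.matrix[:, 0], 0.0)

    def test_moments_on_random_inputs(self, make_dataset, rng):
        ds = make_dataset(rng.gamma(2.0, size=(40, 25)), rng.integers(0, 2, 40))
        out = zscore_normalize(ds)
        assert np.abs(out.matrix.mean(axis=0)).max() < 1e-9
        assert np.abs(out.matrix.std(axis=0) ** 2 - 1).max() < 1e-9

    def test_commutes_with_dedup_on_kept_genes(self, make_dataset, rng):
        m = rng.normal(size=(15, 4))
        ds = make_dataset(m, rng.integers(0, 2, 15), gene_ids=["a", "b", "a", "c"])
        dedup_then_z = zscore_normalize(remove_duplicate_genes(ds)[0])
        z_then_dedup = remove_duplicate_genes(zscore_normalize(ds))[0]
        np.testing.assert_allclose(dedup_then_z.matrix, z_then_dedup.matrix, atol=1e-12)


class TestShuffle:
    def test_deterministic(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(10, 3)), rng.integers(0, 2, 10))
        a = shuffle_samples(ds, seed=7)
        b = shuffle_samples(ds, seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_label_multiset_preserved(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(4, 2)), [1, 1, 0, 1])
        out = shuffle_samples(ds, seed=0)
        assert sorted(out.labels) == sorted(ds.labels)

    def test_row_label_pairing_preserved(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(12, 3)), rng.integers(0, 2, 12))
        out = shuffle_samples(ds, seed=3)
        # every output row must be an input row carrying its own label
        for i in range(out.n_samples):
            src = np.flatnonzero((ds.matrix == out.matrix[i]).all(axis=1))
            assert len(src) == 1 and ds.labels[src[0]] == out.labels[i]

    def test_contiguous_block_broken(self, make_dataset, rng):
        labels = np.repeat([1, 0], 18)
        ds = make_dataset(rng.normal(size=(36, 2)), labels)
        out = shuffle_samples(ds, seed=0)
        first_half = out.labels[:18]
        assert 0 < first_half.sum() < 18  # positives no longer contiguous


class TestSplits:
    def test_holdout_62_samples(self, make_dataset, rng):
        labels = np.concatenate([np.ones(40, int), np.zeros(22, int)])
        ds = make_dataset(rng.normal(size=(62, 3)), labels)
        train, test = make_split(ds, SplitPlan("holdout", 0.7, seed=0))
        assert len(train) == 43 and len(test) == 19
        assert len(np.intersect1d(train, test)) == 0
        # stratified: test split close to 40/22 proportions
        assert ds.labels[test].sum() in (12, 13)

    def test_kfold_36_samples(self, make_dataset, rng):
        labels = np.repeat([0, 1], 18)
        ds = make_dataset(rng.normal(size=(36, 2)), labels)
        folds = make_split(ds, SplitPlan("kfold", k=10, seed=1))
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [3, 3, 3, 3, 4, 4, 4, 4, 4, 4]
        all_test = np.concatenate([test for _, test in folds])
        np.testing.assert_array_equal(np.sort(all_test), np.arange(36))

    def test_kfold_even_split(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(10, 2)), np.tile([0, 1], 5))
        folds = make_split(ds, SplitPlan("kfold", k=2, seed=0))
        assert [len(test) for _, test in folds] == [5, 5]

    def test_every_index_in_exactly_one_test_fold(self, make_dataset, rng):
        for n, k in [(23, 4), (40, 7), (15, 3)]:
            labels = rng.integers(0, 2, n)
            while min(np.bincount(labels, minlength=2)) < k:
                labels = rng.integers(0, 2, n)
            ds = make_dataset(rng.normal(size=(n, 2)), labels)
            folds = make_split(ds, SplitPlan("kfold", k=k, seed=2))
            all_test = np.sort(np.concatenate([t for _, t in folds]))
            np.testing.assert_array_equal(all_test, np.arange(n))
            sizes = [len(t) for _, t in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_small_class_stratification_error(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(10, 2)), [1] + [0] * 9)
        with pytest.raises(ValueError, match="stratification"):
            make_split(ds, SplitPlan("kfold", k=5, seed=0))


class TestPCA:
    def test_collinear_data_rank_one(self, make_dataset, rng):
        base = rng.normal(size=20)
        m = np.column_stack([base, 2 * base])
        ds = make_dataset(m, rng.integers(0, 2, 20))
        _, evr = pca_project(ds, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition(self, make_dataset):
        m = np.array([[1.0, 2.0, 0.5], [3.0, 0.0, 1.0], [2.0, 1.0, 4.0]])
        ds = make_dataset(m, [0, 1, 1])
        coords, evr = pca_project(ds, 2)
        centred = m - m.mean(axis=0)
        w, v = np.linalg.eigh(centred.T @ centred / 3)
        order = np.argsort(w)[::-1]
        expected = centred @ v[:, order[:2]]
        for j in range(2):  # components defined up to sign
            assert np.allclose(coords[:, j], expected[:, j], atol=1e-8) or np.allclose(
                coords[:, j], -expected[:, j], atol=1e-8
            )
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_too_many_components_rejected(self, make_dataset, rng):
        ds = make_dataset(rng.normal(size=(3, 5)), [0, 1, 1])
        with pytest.raises(ValueError):
            pca_project(ds, 4)
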