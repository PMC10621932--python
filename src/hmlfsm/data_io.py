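"""Loading, validation and preprocessing of expression datasets.

The central container is :class:`ExpressionDataset`: a samples x genes
real-valued matrix with one binary class label per sample (tumour = 1,
normal = 0).  Loaders accept delimited text in either orientation and
normalise everything to the samples-in-rows convention; preprocessing
follows the usual microarray recipe of duplicate-gene removal, per-gene
z-scoring, record shuffling and a stratified holdout or k-fold split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class LoadError(ValueError):
    """Raised when an expression table cannot be parsed or validated."""


@dataclass
class ExpressionDataset:
    """Expression matrix (samples x genes) with gene ids and binary labels.

    Labels are coded 1 for the positive (tumour) class and 0 for the
    negative (normal) class.
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x genes)")
        if self.matrix.shape[1] != self.gene_ids.shape[0]:
            raise ValueError(
                f"{self.gene_ids.shape[0]} gene ids for {self.matrix.shape[1]} columns"
            )
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.labels.shape[0]} labels for {self.matrix.shape[0]} rows"
            )
        if not np.isfinite(self.matrix).all():
            raise LoadError("matrix contains missing or non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be coded 0/1")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, indices: Sequence[int], provenance: str | None = None) -> "ExpressionDataset":
        """Dataset restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            gene_ids=self.gene_ids[idx],
            labels=self.labels.copy(),
            provenance=provenance if provenance is not None else self.provenance,
        )


@dataclass
class FeatureSubset:
    """An ordered set of gene indices with provenance.

    Indices refer to columns of the dataset the producing stage ran on;
    ``gene_ids`` carries the corresponding identifiers so a subset stays
    meaningful after the matrix has been re-sliced.
    """

    indices: np.ndarray
    gene_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.indices.shape != self.gene_ids.shape:
            raise ValueError("indices and gene_ids must have equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("feature subset contains repeated indices")

    def __len__(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class SplitPlan:
    """Evaluation protocol: stratified holdout or k-fold cross-validation."""

    kind: str = "holdout"  # "holdout" | "kfold"
    train_fraction: float = 0.7
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "kfold"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "holdout" and not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k-fold requires k >= 2")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"could not parse {path}: {exc}") from exc


_NA_SPELLINGS = {"", "na", "nan", "n/a", "null", "none", "missing"}


def _coerce_numeric(frame: pd.DataFrame, impute: str | None) -> np.ndarray:
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    # split failures into recognised missing values vs. genuine garbage
    raw = frame.to_numpy(dtype=object)
    for i, j in np.argwhere(bad):
        cell = raw[i, j]
        is_missing = pd.isna(cell) or str(cell).strip().lower() in _NA_SPELLINGS
        if not is_missing or impute != "mean":
            raise LoadError(
                f"{'missing' if is_missing else 'non-numeric'} expression value "
                f"{cell!r} at row {frame.index[i]!r}, column {frame.columns[j]!r}"
            )
    col_means = np.nanmean(np.where(bad, np.nan, values), axis=0)
    values[bad] = np.take(col_means, np.argwhere(bad)[:, 1])
    if not np.isfinite(values).all():
        raise LoadError("imputation failed: a column has no numeric values")
    return values


def map_labels(raw: Sequence, positive_label=None) -> np.ndarray:
    """Map raw label values onto the 0/1 (normal/tumour) coding.

    With ``positive_label`` unset, values already in ``{0, 1}`` pass
    through, and the common tumour/normal spellings are recognised.
    """
    raw = pd.Series(list(raw))
    uniques = raw.unique()
    if len(uniques) > 2:
        raise LoadError(f"expected 2 label values, found {len(uniques)}: {list(uniques)[:5]}")
    if positive_label is not None:
        return (raw == positive_label).to_numpy(dtype=int)
    lowered = raw.astype(str).str.strip().str.lower()
    known_pos = {"1", "tumour", "tumor", "positive", "t", "cancer", "abnormal"}
    known_neg = {"0", "normal", "negative", "n", "benign", "-1"}
    if set(lowered.unique()) <= known_pos | known_neg:
        return lowered.isin(known_pos).to_numpy(dtype=int)
    raise LoadError(
        f"cannot map labels {list(uniques)} to tumour/normal; pass positive_label"
    )


def load_expression_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    label_column: str | None = None,
    labels_path: str | Path | None = None,
    positive_label=None,
    impute: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    orientation
        ``"samples-in-rows"`` (index = sample ids, columns = gene ids plus
        optionally the label column) or ``"genes-in-rows"`` (index = gene
        ids, columns = sample ids; labels must come from ``labels_path``).
    label_column
        Name of the label column when samples are in rows.
    labels_path
        Two-column sample,label file used when the table itself carries no
        labels.
    impute
        ``None`` rejects missing/non-numeric cells (the default);
        ``"mean"`` imputes the per-gene mean.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_delimited(path)

    label_series = None
    if label_column is not None:
        if orientation != "samples-in-rows":
            raise LoadError("label_column requires samples-in-rows orientation")
        if label_column not in frame.columns:
            raise LoadError(f"label column {label_column!r} not found in {path}")
        label_series = frame[label_column]
        frame = frame.drop(columns=[label_column])

    if orientation == "genes-in-rows":
        frame = frame.T  # now samples x genes

    if label_series is None:
        if labels_path is None:
            raise LoadError("no labels: pass label_column or labels_path")
        lab = pd.read_csv(labels_path, index_col=0).iloc[:, 0]
        missing = [s for s in frame.index if s not in lab.index]
        if missing:
            raise LoadError(f"labels missing for samples {missing[:5]}")
        label_series = lab.loc[frame.index]

    matrix = _coerce_numeric(frame, impute)
    labels = map_labels(label_series.to_numpy(), positive_label)
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=frame.columns.to_numpy(dtype=object),
        labels=labels,
        provenance=str(path),
    )


def remove_duplicate_genes(
    ds: ExpressionDataset, by_profile: bool = False
) -> tuple[ExpressionDataset, int]:
    """Drop duplicated genes, keeping the first occurrence.

    Duplication means an identical gene identifier; with ``by_profile``
    genes with bit-identical expression vectors are also collapsed.
    Returns the reduced dataset and the number of genes removed.
    """
    _, first = np.unique(ds.gene_ids.astype(str), return_index=True)
    keep = np.zeros(ds.n_genes, dtype=bool)
    keep[first] = True
    if by_profile:
        seen: dict[bytes, int] = {}
        for j in range(ds.n_genes):
            key = ds.matrix[:, j].tobytes()
            if key in seen:
                keep[j] = False
            else:
                seen[key] = j
    kept = np.flatnonzero(keep)
    removed = ds.n_genes - kept.size
    if removed == 0:
        return ds, 0
    return ds.subset_genes(kept), removed


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardise each gene to mean 0 and unit population variance.

    Constant genes cannot be scaled and are mapped to all-zeros with a
    warning instead of raising, so simulated degenerate genes never crash
    a pipeline run.
    """
    mean = ds.matrix.mean(axis=0)
    sd = ds.matrix.std(axis=0)  # population convention (divide by n)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) mapped to zeros during z-scoring",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    out = (ds.matrix - mean) / safe_sd
    out[:, constant] = 0.0
    return replace(ds, matrix=out)


def shuffle_samples(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permute sample rows (and labels identically) with a seeded RNG."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    return replace(ds, matrix=ds.matrix[perm], labels=ds.labels[perm])


def _stratified_holdout(labels: np.ndarray, test_size: int, rng: np.random.Generator):
    classes, counts = np.unique(labels, return_counts=True)
    n = labels.size
    exact = counts * test_size / n
    alloc = np.floor(exact).astype(int)
    # distribute the remainder by largest fractional part; ties to the larger class
    remainder = test_size - alloc.sum()
    order = sorted(range(len(classes)), key=lambda c: (-(exact[c] - alloc[c]), -counts[c]))
    for c in order[:remainder]:
        alloc[c] += 1
    test_idx = []
    for c, take in zip(classes, alloc):
        members = np.flatnonzero(labels == c)
        picked = rng.permutation(members)[:take]
        test_idx.append(picked)
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def _stratified_kfold(labels: np.ndarray, k: int, rng: np.random.Generator):
    """Round-robin per-class assignment with a carried fold pointer.

    Carrying the pointer across classes keeps total fold sizes within one
    of each other while preserving per-class proportions up to rounding.
    """
    n = labels.size
    assign = np.empty(n, dtype=int)
    pointer = 0
    for c in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == c))
        for m in members:
            assign[m] = pointer % k
            pointer += 1
    folds = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[assign == f]
        train = all_idx[assign != f]
        folds.append((train, test))
    return folds


def make_split(ds: ExpressionDataset, plan: SplitPlan):
    """Build train/test indices (holdout) or a list of folds (k-fold).

    Holdout returns ``(train, test)`` with ``len(test) = round((1 -
    train_fraction) * n)``; k-fold returns ``[(train, test), ...]`` with
    every sample in exactly one test fold and fold sizes differing by at
    most one.
    """
    labels = ds.labels
    rng = np.random.default_rng(plan.seed)
    if plan.kind == "holdout":
        test_size = int(round((1.0 - plan.train_fraction) * ds.n_samples))
        test_size = min(max(test_size, 1), ds.n_samples - 1)
        if plan.stratified:
            return _stratified_holdout(labels, test_size, rng)
        perm = rng.permutation(ds.n_samples)
        return np.sort(perm[test_size:]), np.sort(perm[:test_size])
    # kfold
    classes, counts = np.unique(labels, return_counts=True)
    if plan.stratified and counts.min() < plan.k:
        raise ValueError(
            f"stratification error: smallest class has {int(counts.min())} "
            f"members, fewer than k={plan.k}"
        )
    if plan.k > ds.n_samples:
        raise ValueError(f"k={plan.k} exceeds sample count {ds.n_samples}")
    if plan.stratified:
        return _stratified_kfold(labels, plan.k, rng)
    assign = rng.permutation(ds.n_samples) % plan.k
    all_idx = np.arange(ds.n_samples)
    return [(all_idx[assign != f], all_idx[assign == f]) for f in range(plan.k)]


def iter_folds(ds: ExpressionDataset, plan: SplitPlan):
    """Uniform iteration over (train, test) pairs for either split kind."""
    split = make_split(ds, plan)
    if plan.kind == "holdout":
        yield split
    else:
        yield from split


def pca_project(ds: ExpressionDataset, n_components: int):
    """Project samples onto the leading principal components.

    Returns ``(coordinates, explained_variance_fractions)`` where the
    coordinates are samples x components and the variance fractions are
    non-increasing.
    """
    limit = min(ds.n_samples, ds.n_genes)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}], got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(ds.matrix)
    return coords, pca.explained_variance_ratio_


def write_gene_list(gene_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in gene_ids) + "\n")


def read_gene_list(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return np.asarray([ln for ln in lines if ln], dtype=object)
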