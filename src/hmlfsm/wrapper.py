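"""Cross-validated subset fitness shared by the GA and binary-PSO wrappers.

The metaheuristics search over binary gene masks; each candidate mask is
scored by the pooled out-of-fold accuracy of a classifier trained on the
selected genes only.  A per-search memo keyed on the mask bytes avoids
re-fitting when the population revisits a subset, and the folds are drawn
once per search so every mask is scored on identical partitions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import clone

from .classifiers import make_classifier
from .data_io import ExpressionDataset, SplitPlan, iter_folds


def _effective_protocol(ds: ExpressionDataset, plan: SplitPlan) -> SplitPlan:
    """Clip the fold count to the minority-class size so CV stays valid."""
    if plan.kind != "kfold":
        return plan
    _, counts = np.unique(ds.labels, return_counts=True)
    k = max(2, min(plan.k, int(counts.min())))
    if k == plan.k:
        return plan
    return SplitPlan(kind="kfold", k=k, seed=plan.seed, stratified=plan.stratified)


class SubsetFitness:
    """Callable scoring binary masks by cross-validated accuracy.

    ``fitness = (1 - size_weight) * cv_accuracy + size_weight * (1 - |mask| / L)``.
    The default ``size_weight = 0`` is pure accuracy.  The empty mask is
    defined as fitness 0 (with a warning) so metaheuristic search never
    raises mid-run.
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        classifier="1nn",
        protocol: SplitPlan | None = None,
        size_weight: float = 0.0,
        seed: int = 0,
    ):
        if not 0.0 <= size_weight <= 1.0:
            raise ValueError("size_weight must lie in [0, 1]")
        self.ds = ds
        self.size_weight = size_weight
        protocol = protocol or SplitPlan(kind="kfold", k=5, seed=seed, stratified=True)
        self.protocol = _effective_protocol(ds, protocol)
        self.folds = list(iter_folds(ds, self.protocol))
        self._template = make_classifier(classifier, seed=seed)
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0

    def cv_accuracy(self, mask: np.ndarray) -> float:
        """Pooled out-of-fold accuracy of the classifier on the masked genes."""
        cols = np.flatnonzero(mask)
        X = self.ds.matrix[:, cols]
        y = self.ds.labels
        correct = 0
        total = 0
        for train, test in self.folds:
            model = clone(self._template)
            model.fit(X[train], y[train])
            correct += int((model.predict(X[test]) == y[test]).sum())
            total += test.size
        return correct / total

    def __call__(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.ds.n_genes:
            raise ValueError(
                f"mask length {mask.shape[0]} != gene count {self.ds.n_genes}"
            )
        if not mask.any():
            warnings.warn("empty gene mask scored as fitness 0", stacklevel=2)
            return 0.0
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            acc = self.cv_accuracy(mask)
            penalty = 1.0 - mask.sum() / mask.size
            self._cache[key] = (
                (1.0 - self.size_weight) * acc + self.size_weight * penalty
            )
            self.evaluations += 1
        return self._cache[key]


def subset_cv_accuracy(
    ds: ExpressionDataset,
    mask,
    classifier="1nn",
    protocol: SplitPlan | None = None,
    seed: int = 0,
) -> float:
    """One-shot convenience wrapper around :class:`SubsetFitness`."""
    return SubsetFitness(ds, classifier, protocol, size_weight=0.0, seed=seed)(mask)
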