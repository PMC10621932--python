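"""Entropy, supervised discretization and mutual information.

All quantities are Shannon measures in bits (base-2 logarithms) estimated
by plug-in counting.  Continuous expression values are discretized before
any information measure is taken; the default is the recursive
entropy-minimisation scheme with the minimum-description-length (MDL)
stopping rule of Fayyad & Irani, which yields zero cut points — a single
bin, hence zero information gain — for features carrying no class signal.
"""

from __future__ import annotations

import numpy as np


def entropy(labels) -> float:
    """Shannon entropy of a categorical vector, in bits (0*log 0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _counts_entropy(counts: np.ndarray) -> float:
    """Entropy in bits from a vector of non-negative counts."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(binned, labels) -> float:
    """Class-entropy reduction from partitioning samples by bin.

    ``H(y) - sum_b (n_b / n) H(y | bin = b)``; a single bin gives 0.
    """
    binned = np.asarray(binned)
    labels = np.asarray(labels)
    if binned.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {binned.shape[0]} bins vs {labels.shape[0]} labels"
        )
    n = labels.size
    parent = entropy(labels)
    child = 0.0
    for b in np.unique(binned):
        sub = labels[binned == b]
        child += (sub.size / n) * entropy(sub)
    return parent - child


def mutual_information(x_binned, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Estimated from the joint contingency table:
    ``sum_ij p_ij log2(p_ij / (p_i p_j))``.
    """
    x_binned = np.asarray(x_binned)
    y = np.asarray(y)
    if x_binned.shape != y.shape:
        raise ValueError(
            f"length mismatch: {x_binned.shape[0]} vs {y.shape[0]}"
        )
    if x_binned.size == 0:
        raise ValueError("mutual information of empty vectors is undefined")
    _, xi = np.unique(x_binned, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# supervised discretization


def _class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    np.add.at(counts, labels, 1.0)
    return counts


def _mdl_cuts(values: np.ndarray, labels: np.ndarray, n_classes: int) -> list[float]:
    """Recursive entropy-based binary splitting with the MDL stop rule.

    Candidate cut points are midpoints between adjacent distinct values;
    a cut is accepted when its information gain exceeds
    ``(log2(N-1) + log2(3^k - 2) - k H(S) + k1 H(S1) + k2 H(S2)) / N``
    with k the number of classes present in each partition.
    """
    n = values.size
    if n < 2:
        return []
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    y = labels[order]

    # prefix class counts: prefix[i] = counts of y[:i]
    onehot = np.zeros((n + 1, n_classes))
    onehot[np.arange(1, n + 1), y] = 1.0
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]
    ent_s = _counts_entropy(total)
    k = int((total > 0).sum())
    if ent_s == 0.0:
        return []

    best = None  # (gain, threshold, split_position, left_counts, right_counts)
    distinct_break = np.flatnonzero(v[1:] > v[:-1]) + 1  # split positions
    for pos in distinct_break:
        left = prefix[pos]
        right = total - left
        e1 = _counts_entropy(left)
        e2 = _counts_entropy(right)
        gain = ent_s - (pos / n) * e1 - ((n - pos) / n) * e2
        if best is None or gain > best[0]:
            best = (gain, (v[pos - 1] + v[pos]) / 2.0, pos, left, right, e1, e2)
    if best is None:
        return []
    gain, thr, pos, left, right, e1, e2 = best
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * e1 - k2 * e2)
    threshold = (np.log2(n - 1.0) + delta) / n
    if gain <= threshold:
        return []
    left_cuts = _mdl_cuts(v[:pos], y[:pos], n_classes)
    right_cuts = _mdl_cuts(v[pos:], y[pos:], n_classes)
    return sorted(left_cuts + [thr] + right_cuts)


def discretize_gene(values, labels=None, method: str = "mdl", bins: int = 4):
    """Bin one gene's expression values; returns ``(codes, boundaries)``.

    ``method="mdl"`` (supervised, needs ``labels``) may return zero
    boundaries, i.e. a single bin.  ``method="equal_frequency"`` cuts at
    quantiles and requires ``bins >= 2``.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if method == "mdl":
        if labels is None:
            raise ValueError("mdl discretization requires labels")
        labels = np.asarray(labels)
        if labels.shape != values.shape:
            raise ValueError("values and labels must have equal length")
        _, y = np.unique(labels, return_inverse=True)
        boundaries = np.asarray(_mdl_cuts(values, y, int(y.max()) + 1), dtype=float)
    elif method == "equal_frequency":
        if bins < 2:
            raise ValueError("equal_frequency requires bins >= 2")
        qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
        boundaries = np.unique(qs)
        if boundaries.size and values.min() == values.max():
            boundaries = np.asarray([], dtype=float)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    codes = np.searchsorted(boundaries, values, side="right")
    return codes, boundaries
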