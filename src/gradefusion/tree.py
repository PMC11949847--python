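"""Gain-ratio decision tree with optional reduced-error pruning.

Internal nodes test a single numeric feature against a threshold; the split
is chosen by gain ratio (information gain divided by the split information
of the binary partition), the C4.5 criterion. Reduced-error pruning grows
the tree on 75% of the training data and replaces any subtree whose leaf
version does no worse on the held-out 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Node:
    counts: np.ndarray                 # training class counts at the node
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _best_threshold(x: np.ndarray, codes: np.ndarray, n_classes: int,
                    min_leaf: int):
    """Best threshold for one feature by information gain."""
    order = np.argsort(x, kind="stable")
    xs, cs = x[order], codes[order]
    n = len(xs)
    total = np.bincount(cs, minlength=n_classes)
    ent = _entropy(total)
    left = np.zeros(n_classes)
    best = None
    for i in range(n - 1):
        left[cs[i]] += 1
        n_l = i + 1
        if n_l < min_leaf or n - n_l < min_leaf or xs[i + 1] <= xs[i]:
            continue
        right = total - left
        gain = ent - (n_l * _entropy(left) + (n - n_l) * _entropy(right)) / n
        if best is None or gain > best[1]:
            best = ((xs[i] + xs[i + 1]) / 2.0, gain, n_l)
    return best


@dataclass
class GainRatioTree:
    """C4.5-style classifier on numeric features."""

    min_leaf: int = 2
    pruning: str = "reduced_error"  # or "none"
    seed: int = 0

    classes_: np.ndarray = field(default=None, repr=False)
    root_: _Node = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GainRatioTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to fit")
        if self.pruning not in ("reduced_error", "none"):
            raise ValueError(f"unknown pruning {self.pruning!r}")
        if self.pruning == "reduced_error" and len(y) >= 8:
            grow_idx, prune_idx = self._prune_split(codes)
            self.root_ = self._grow(X[grow_idx], codes[grow_idx])
            self._rep(self.root_, X[prune_idx], codes[prune_idx])
        else:
            self.root_ = self._grow(X, codes)
        return self

    def _prune_split(self, codes: np.ndarray):
        """Stratified 75/25 grow/prune split."""
        rng = np.random.default_rng(self.seed)
        grow, prune = [], []
        for c in range(len(self.classes_)):
            idx = np.flatnonzero(codes == c)
            idx = idx[rng.permutation(len(idx))]
            n_p = max(1, len(idx) // 4)
            prune.extend(idx[:n_p])
            grow.extend(idx[n_p:])
        return np.sort(np.array(grow)), np.sort(np.array(prune))

    def _grow(self, X: np.ndarray, codes: np.ndarray) -> _Node:
        n_classes = len(self.classes_)
        counts = np.bincount(codes, minlength=n_classes).astype(float)
        node = _Node(counts=counts)
        n = len(codes)
        if n < 2 * self.min_leaf or (counts > 0).sum() < 2:
            return node
        best = None  # (gain_ratio, feature, threshold)
        for f in range(X.shape[1]):
            found = _best_threshold(X[:, f], codes, n_classes, self.min_leaf)
            if found is None:
                continue
            thr, gain, n_l = found
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([n_l, n - n_l], dtype=float))
            ratio = gain / split_info if split_info > 0 else 0.0
            if best is None or ratio > best[0]:
                best = (ratio, f, thr)
        if best is None:
            return node
        _, f, thr = best
        mask = X[:, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._grow(X[mask], codes[mask])
        node.right = self._grow(X[~mask], codes[~mask])
        return node

    def _rep(self, node: _Node, X: np.ndarray, codes: np.ndarray) -> int:
        """Bottom-up reduced-error pruning; returns subtree errors on (X, codes)."""
        majority = int(np.argmax(node.counts))
        leaf_err = int((codes != majority).sum())
        if node.is_leaf:
            return leaf_err
        mask = X[:, node.feature] <= node.threshold
        sub_err = (self._rep(node.left, X[mask], codes[mask])
                   + self._rep(node.right, X[~mask], codes[~mask]))
        if leaf_err <= sub_err:
            node.feature = node.threshold = node.left = node.right = None
            return leaf_err
        return sub_err

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_classes = len(self.classes_)
        out = np.empty((len(X), n_classes))
        for i, row in enumerate(X):
            node = self.root_
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = (node.counts + 1.0) / (node.counts.sum() + n_classes)
        return out
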