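"""Discrete Bayesian-network classifier with optional K2 structure search.

Features are entropy/MDL-discretized on the training data. The base
structure is the naive one — the class is the sole parent of every feature.
K2 search (with the node ordering given by table column order) may add up
to ``max_parents`` extra parents per feature from earlier columns, keeping
an addition only when it increases the Cooper–Herskovits marginal
likelihood of that node's family. Conditional probability tables are
estimated with additive smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .cfs import apply_cuts, mdl_discretize


def _k2_family_score(child: np.ndarray, r: int,
                     parent_cfg: np.ndarray, q: int) -> float:
    """Log Cooper–Herskovits score of one node given its parent configs."""
    score = 0.0
    for j in range(q):
        sel = child[parent_cfg == j]
        n_j = len(sel)
        n_jk = np.bincount(sel, minlength=r)
        score += gammaln(r) - gammaln(n_j + r) + gammaln(n_jk + 1).sum()
    return float(score)


@dataclass
class BayesNetClassifier:
    """K2/naive Bayesian network over MDL-discretized features."""

    search: str = "k2"  # "naive" or "k2"
    max_parents: int = 1
    alpha: float = 0.5

    # fitted state
    classes_: np.ndarray = field(default=None, repr=False)
    cuts_: list = field(default=None, repr=False)
    parents_: list = field(default=None, repr=False)
    cpts_: list = field(default=None, repr=False)
    prior_: np.ndarray = field(default=None, repr=False)
    n_bins_: list = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BayesNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to fit")
        n, d = X.shape
        n_classes = len(self.classes_)

        self.cuts_ = [mdl_discretize(X[:, f], y) for f in range(d)]
        bins = np.column_stack(
            [apply_cuts(X[:, f], self.cuts_[f]) for f in range(d)]
        ) if d else np.empty((n, 0), dtype=int)
        self.n_bins_ = [len(c) + 1 for c in self.cuts_]

        # structure: class parent always; K2 may add earlier-column parents
        self.parents_ = [[] for _ in range(d)]
        if self.search == "k2" and self.max_parents > 0:
            for f in range(d):
                r = self.n_bins_[f]
                if r < 2:
                    continue
                current: list[int] = []
                cfg = y_codes.copy()
                q = n_classes
                best = _k2_family_score(bins[:, f], r, cfg, q)
                while len(current) < self.max_parents:
                    gain_best, pick = 0.0, None
                    for p in range(f):
                        if p in current or self.n_bins_[p] < 2:
                            continue
                        q_new = q * self.n_bins_[p]
                        cfg_new = cfg * self.n_bins_[p] + bins[:, p]
                        s = _k2_family_score(bins[:, f], r, cfg_new, q_new)
                        if s > best + gain_best:
                            gain_best, pick = s - best, (p, cfg_new, q_new, s)
                    if pick is None:
                        break
                    p, cfg, q, best = pick
                    current.append(p)
                self.parents_[f] = current
        elif self.search not in ("k2", "naive"):
            raise ValueError(f"unknown search {self.search!r}")

        # CPTs with additive smoothing
        counts_c = np.bincount(y_codes, minlength=n_classes).astype(float)
        self.prior_ = (counts_c + self.alpha) / (n + self.alpha * n_classes)
        self.cpts_ = []
        for f in range(d):
            r = self.n_bins_[f]
            q = n_classes
            cfg = y_codes.copy()
            for p in self.parents_[f]:
                cfg = cfg * self.n_bins_[p] + bins[:, p]
                q *= self.n_bins_[p]
            table = np.zeros((q, r))
            np.add.at(table, (cfg, bins[:, f]), 1.0)
            table = (table + self.alpha) / (
                table.sum(axis=1, keepdims=True) + self.alpha * r
            )
            self.cpts_.append(table)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        n_classes = len(self.classes_)
        bins = np.column_stack(
            [apply_cuts(X[:, f], self.cuts_[f]) for f in range(d)]
        ) if d else np.empty((n, 0), dtype=int)
        logp = np.tile(np.log(self.prior_), (n, 1))
        for c in range(n_classes):
            for f in range(d):
                cfg = np.full(n, c)
                for p in self.parents_[f]:
                    cfg = cfg * self.n_bins_[p] + bins[:, p]
                logp[:, c] += np.log(self.cpts_[f][cfg, bins[:, f]])
        logp -= logp.max(axis=1, keepdims=True)
        proba = np.exp(logp)
        return proba / proba.sum(axis=1, keepdims=True)
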