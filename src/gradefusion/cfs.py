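"""Correlation-based feature selection (CFS) with best-first search.

CFS scores a feature subset S of size k by the merit

    M_S = k · r̄_cf / sqrt(k + k(k−1) · r̄_ff)

where r̄_cf is the mean feature–class correlation over S and r̄_ff the mean
pairwise feature–feature correlation within S: good subsets correlate with
the class and not with each other. Correlation is realized as symmetrical
uncertainty, SU(X, Y) = 2·[H(X) + H(Y) − H(X,Y)] / [H(X) + H(Y)], after
entropy/MDL (Fayyad–Irani) discretization of continuous features.

The subset space is explored by forward best-first search from the empty
set; the search halts after five consecutive node expansions that fail to
improve the best merit found so far.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from .tables import FeatureTable

STOP_AFTER_NON_IMPROVING = 5
MERIT_TOL = 1e-10


# ---------------------------------------------------------------------------
# MDL discretization (Fayyad–Irani)

def _class_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _counts(codes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(codes, minlength=n_classes)


def _best_split(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Best boundary by class-information gain; returns (cut, gain, stats)."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    v, c = values[order], codes[order]
    total = _counts(c, n_classes)
    ent = _class_entropy(total)
    best = None
    left = np.zeros(n_classes)
    for idx in range(n - 1):
        left[c[idx]] += 1
        if v[idx + 1] <= v[idx]:  # no boundary between equal values
            continue
        right = total - left
        n_l = idx + 1
        e_l = _class_entropy(left)
        e_r = _class_entropy(right)
        gain = ent - (n_l * e_l + (n - n_l) * e_r) / n
        if best is None or gain > best[1]:
            cut = (v[idx] + v[idx + 1]) / 2.0
            k_l = int((left > 0).sum())
            k_r = int((right > 0).sum())
            best = (cut, gain, (ent, e_l, e_r, k_l, k_r, n_l))
    return best


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Entropy/MDL cut points for one continuous feature.

    Recursive binary splitting on class-information gain; a split is kept
    only when the gain exceeds the minimum-description-length cost

        [log2(n − 1) + log2(3^k − 2) − (k·E − k1·E1 − k2·E2)] / n,

    with k the class count in the partition and E the class entropies.
    Constant or class-uninformative features yield no cuts.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    classes, codes = np.unique(labels, return_inverse=True)
    n_classes = len(classes)
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        v, c = values[mask], codes[mask]
        n = len(v)
        if n < 2:
            return
        found = _best_split(v, c, n_classes)
        if found is None:
            return
        cut, gain, (ent, e_l, e_r, k_l, k_r, n_l) = found
        k = int((_counts(c, n_classes) > 0).sum())
        delta = np.log2(3 ** k - 2) - (k * ent - k_l * e_l - k_r * e_r)
        threshold = (np.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cuts.append(cut)
        recurse(mask & (values < cut))
        recurse(mask & (values >= cut))

    recurse(np.ones(len(values), dtype=bool))
    return sorted(cuts)


def apply_cuts(values: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Map values to integer bins defined by the cut points."""
    return np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")


@dataclass
class DiscretizedTable:
    """Per-feature integer bin assignments plus the defining cut points."""

    bins: dict[str, np.ndarray]
    cuts: dict[str, list[float]]
    labels: np.ndarray

    @classmethod
    def from_table(cls, table: FeatureTable) -> "DiscretizedTable":
        labels = np.asarray(table.labels)
        bins, cuts = {}, {}
        for name in table.feature_names:
            col = table.values[name].to_numpy(dtype=float)
            c = mdl_discretize(col, labels)
            cuts[name] = c
            bins[name] = apply_cuts(col, c)
        return cls(bins=bins, cuts=cuts, labels=labels)


# ---------------------------------------------------------------------------
# Symmetrical uncertainty and the merit function

def _entropy_of(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return _class_entropy(counts)


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X, Y) = 2·I(X; Y) / (H(X) + H(Y)) ∈ [0, 1], logs base 2.

    Defined as 0 when both entropies vanish (two constants).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    hx = _entropy_of(x)
    hy = _entropy_of(y)
    if hx + hy == 0.0:
        return 0.0
    # joint entropy via paired codes; counts sorted so SU(x,y) == SU(y,x)
    # exactly regardless of summation order
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    _, joint = np.unique(xi * (yi.max() + 1) + yi, return_counts=True)
    hxy = _class_entropy(np.sort(joint))
    su = 2.0 * (hx + hy - hxy) / (hx + hy)
    return float(min(1.0, max(0.0, su)))


@dataclass
class CorrelationCache:
    """Feature–class and pairwise feature–feature SU values."""

    feature_names: list[str]
    r_cf: dict[str, float]
    _bins: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _r_ff: dict[frozenset, float] = field(default_factory=dict, repr=False)

    @classmethod
    def from_table(cls, table: FeatureTable) -> "CorrelationCache":
        disc = DiscretizedTable.from_table(table)
        r_cf = {
            name: symmetrical_uncertainty(disc.bins[name], disc.labels)
            for name in table.feature_names
        }
        return cls(feature_names=list(table.feature_names), r_cf=r_cf,
                   _bins=disc.bins)

    def feature_feature(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key not in self._r_ff:
            self._r_ff[key] = symmetrical_uncertainty(self._bins[a],
                                                      self._bins[b])
        return self._r_ff[key]


def cfs_merit(subset, cache: CorrelationCache) -> float:
    """Evaluate the CFS merit of a non-empty feature subset."""
    names = sorted(subset)
    k = len(names)
    if k == 0:
        raise ValueError("subset must be non-empty")
    missing = [n for n in names if n not in cache.r_cf]
    if missing:
        raise KeyError(f"features not in cache: {missing}")
    rcf = float(np.mean([cache.r_cf[n] for n in names]))
    if k == 1:
        rff = 0.0
    else:
        pairs = list(itertools.combinations(names, 2))
        rff = float(np.mean([cache.feature_feature(a, b) for a, b in pairs]))
    denom = np.sqrt(k + k * (k - 1) * rff)
    return 0.0 if denom == 0 else k * rcf / denom


@dataclass
class CFSResult:
    """Selected subset, its merit, and the search trace."""

    selected: list[str]
    merit: float
    search_trace: list[tuple[tuple[str, ...], float]]
    stop_reason: str


def best_first_select(
    table: FeatureTable,
    cache: CorrelationCache | None = None,
    stop_after: int = STOP_AFTER_NON_IMPROVING,
    tol: float = MERIT_TOL,
) -> CFSResult:
    """Forward best-first CFS search.

    Starting from the empty set, the highest-merit unexpanded subset is
    expanded by adding each unused feature; the search stops after
    ``stop_after`` consecutive expansions that fail to strictly improve the
    best merit seen (tolerance ``tol``), or when the frontier is exhausted.
    Ties on merit are broken towards smaller subsets, then lexicographic
    feature order; the selected names are returned in table column order.
    """
    names = list(table.feature_names)
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(np.asarray(table.labels))) < 2:
        raise ValueError("need at least 2 classes")
    if cache is None:
        cache = CorrelationCache.from_table(table)

    merits: dict[frozenset, float] = {}

    def merit_of(s: frozenset) -> float:
        if s not in merits:
            merits[s] = cfs_merit(s, cache)
        return merits[s]

    def better(m: float, s: tuple, best_m: float, best_s: tuple) -> bool:
        if m > best_m + tol:
            return True
        if m < best_m - tol:
            return False
        return (len(s), s) < (len(best_s), best_s)

    # heap entries: (-merit, len, sorted-name tuple); empty set expands first
    frontier: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, ())]
    seen: set[frozenset] = {frozenset()}
    expanded: set[frozenset] = set()
    best_subset: tuple[str, ...] = ()
    best_merit = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    non_improving = 0
    stop_reason = "exhausted"

    while frontier:
        _, _, node = heapq.heappop(frontier)
        fnode = frozenset(node)
        if fnode in expanded:
            continue
        expanded.add(fnode)
        improved = False
        for name in names:
            if name in fnode:
                continue
            child = frozenset(fnode | {name})
            if child in seen:
                continue
            seen.add(child)
            m = merit_of(child)
            child_key = tuple(sorted(child))
            heapq.heappush(frontier, (-m, len(child), child_key))
            if better(m, child_key, best_merit, best_subset):
                if m > best_merit + tol:
                    improved = True
                best_merit = m
                best_subset = child_key
        trace.append((best_subset, best_merit))
        if node:  # expanding the empty root is not a generated subset
            non_improving = 0 if improved else non_improving + 1
            if non_improving >= stop_after:
                stop_reason = "no_improvement"
                break

    order = {n: i for i, n in enumerate(names)}
    selected = sorted(best_subset, key=order.get)
    return CFSResult(selected=selected, merit=float(best_merit),
                     search_trace=trace, stop_reason=stop_reason)
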