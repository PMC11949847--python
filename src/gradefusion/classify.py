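"""Feature-level fusion, the three classifier families, and evaluation.

The grading protocol: feature tables from the two modalities are fused by
column-wise concatenation; a classifier — support-vector machine (four
kernels, including the Pearson VII universal kernel), discrete Bayesian
network, or gain-ratio decision tree — is assessed by a stratified 70/30
calibration/evaluation split with pooled stratified 10-fold
cross-validation on the calibration part. Reported metrics are accuracy,
the probabilistic root-mean-squared error

    RMSE = sqrt( Σ_samples Σ_classes (p̂ − 1{true})² / (n·C) ),

and the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bn import BayesNetClassifier
from .tables import FeatureTable
from .tree import GainRatioTree


# ---------------------------------------------------------------------------
# Fusion

def fuse_features(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Feature-level fusion: column-wise concatenation of two tables.

    Requires the same samples in the same order and disjoint feature names.
    """
    if not a.values.index.equals(b.values.index):
        raise ValueError("tables describe different samples or orders")
    if not (np.asarray(a.labels) == np.asarray(b.labels)).all():
        raise ValueError("tables disagree on sample labels")
    overlap = set(a.feature_names) & set(b.feature_names)
    if overlap:
        raise ValueError(f"duplicate feature names: {sorted(overlap)}")
    values = pd.concat([a.values, b.values], axis=1)
    return FeatureTable(values, a.labels.copy(), provenance="fused")


# ---------------------------------------------------------------------------
# Kernels

def puk_kernel(x: np.ndarray, y: np.ndarray,
               omega: float = 1.0, sigma: float = 1.0) -> float:
    """Pearson VII universal kernel between two vectors.

    K = 1 / [1 + (2·‖x−y‖·sqrt(2^{1/ω} − 1) / σ)²]^ω, so K(x, x) = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    return float(_puk_gram(x[None, :], y[None, :], omega, sigma)[0, 0])


def _puk_gram(xa: np.ndarray, xb: np.ndarray,
              omega: float, sigma: float) -> np.ndarray:
    d = cdist(xa, xb)
    z = 2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + z ** 2) ** omega


def _normalized_poly_gram(xa: np.ndarray, xb: np.ndarray,
                          degree: float) -> np.ndarray:
    raw = (xa @ xb.T + 1.0) ** degree
    da = np.sqrt((xa * xa).sum(axis=1) + 1.0) ** degree
    db = np.sqrt((xb * xb).sum(axis=1) + 1.0) ** degree
    return raw / np.outer(da, db)


# ---------------------------------------------------------------------------
# Specs and models

@dataclass
class ClassifierSpec:
    """Declarative description of one classifier configuration."""

    family: str = "svm"  # svm | bayes_net | tree
    kernel: str = "puk"  # polynomial | normalized_polynomial | puk | rbf
    degree: int = 2
    gamma: float | str = "scale"
    omega: float = 1.0
    sigma: float = 1.0
    C: float = 1.0
    bn_search: str = "k2"  # naive | k2
    max_parents: int = 1
    alpha: float = 0.5
    min_leaf: int = 2
    pruning: str = "reduced_error"  # reduced_error | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm", "bayes_net", "tree"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "svm":
            if self.kernel not in ("polynomial", "normalized_polynomial",
                                   "puk", "rbf"):
                raise ValueError(f"unknown kernel {self.kernel!r}")
            if self.C <= 0 or self.omega <= 0 or self.sigma <= 0:
                raise ValueError("C, omega and sigma must be positive")

    @property
    def name(self) -> str:
        if self.family == "svm":
            return f"svm_{self.kernel}"
        if self.family == "bayes_net":
            return f"bn_{self.bn_search}"
        return f"tree_{self.pruning}"


@dataclass
class PredictionMatrix:
    """Per-sample class probabilities plus argmax labels."""

    probs: pd.DataFrame  # columns = class labels

    def __post_init__(self) -> None:
        arr = self.probs.to_numpy()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise ValueError("probabilities out of [0, 1]")
        if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("probability rows must sum to 1")

    @property
    def predicted(self) -> np.ndarray:
        arr = self.probs.to_numpy()
        return self.probs.columns.to_numpy()[arr.argmax(axis=1)]


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    classes: np.ndarray
    _impl: object = field(repr=False, default=None)

    def predict(self, values: pd.DataFrame) -> PredictionMatrix:
        proba = self._impl.predict_proba(np.asarray(values, dtype=float))
        proba = np.clip(proba, 0.0, None)
        proba = proba / proba.sum(axis=1, keepdims=True)
        return PredictionMatrix(
            pd.DataFrame(proba, index=values.index, columns=self.classes)
        )


def _build_svm(spec: ClassifierSpec) -> Pipeline:
    if spec.kernel == "polynomial":
        svc = SVC(kernel="poly", degree=spec.degree, gamma=1.0, coef0=1.0,
                  C=spec.C, probability=True, random_state=spec.seed)
    elif spec.kernel == "rbf":
        svc = SVC(kernel="rbf", gamma=spec.gamma, C=spec.C,
                  probability=True, random_state=spec.seed)
    elif spec.kernel == "normalized_polynomial":
        deg = spec.degree
        svc = SVC(kernel=lambda a, b: _normalized_poly_gram(a, b, deg),
                  C=spec.C, probability=True, random_state=spec.seed)
    else:  # puk
        om, sg = spec.omega, spec.sigma
        svc = SVC(kernel=lambda a, b: _puk_gram(a, b, om, sg),
                  C=spec.C, probability=True, random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def train(spec: ClassifierSpec, table: FeatureTable) -> TrainedModel:
    """Fit one classifier on a full feature table."""
    X = table.values.to_numpy(dtype=float)
    y = np.asarray(table.labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data holds a single class")
    if spec.family == "svm":
        impl = _build_svm(spec)
        with warnings.catch_warnings():
            # SVC(probability=True) is the pairwise Platt calibration we
            # want; sklearn 1.9 deprecates the flag in favor of a wrapper.
            warnings.simplefilter("ignore", FutureWarning)
            impl.fit(X, y)
        # expose sklearn's class order (sorted, same as np.unique)
        classes = impl.named_steps["svc"].classes_
    elif spec.family == "bayes_net":
        impl = BayesNetClassifier(search=spec.bn_search,
                                  max_parents=spec.max_parents,
                                  alpha=spec.alpha).fit(X, y)
        classes = impl.classes_
    else:
        impl = GainRatioTree(min_leaf=spec.min_leaf, pruning=spec.pruning,
                             seed=spec.seed).fit(X, y)
        classes = impl.classes_
    return TrainedModel(spec=spec, classes=classes, _impl=impl)


# ---------------------------------------------------------------------------
# Metrics

def probabilistic_rmse(probs: pd.DataFrame, true_labels) -> float:
    """RMSE between probability rows and one-hot true labels (n·C terms)."""
    true_labels = np.asarray(true_labels)
    onehot = (probs.columns.to_numpy()[None, :] == true_labels[:, None])
    err = probs.to_numpy() - onehot.astype(float)
    return float(np.sqrt(np.mean(err ** 2)))


def confusion_table(true_labels, predicted, classes) -> pd.DataFrame:
    """Confusion counts: rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    classes = list(classes)
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    lookup = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted):
        mat[lookup[t], lookup[p]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


@dataclass
class PhaseMetrics:
    accuracy: float  # percent
    rmse: float
    confusion: pd.DataFrame
    n: int


@dataclass
class EvaluationReport:
    """Calibration (CV) and evaluation (hold-out) performance of one model."""

    spec: ClassifierSpec
    classes: list
    calibration: PhaseMetrics
    evaluation: PhaseMetrics
    fold_metrics: list[dict]
    calibration_index: list
    evaluation_index: list

    def summary_row(self) -> dict:
        return {
            "model": self.spec.name,
            "cal_accuracy": self.calibration.accuracy,
            "cal_rmse": self.calibration.rmse,
            "eval_accuracy": self.evaluation.accuracy,
            "eval_rmse": self.evaluation.rmse,
        }


def _phase_metrics(probs: pd.DataFrame, true_labels, classes) -> PhaseMetrics:
    pred = PredictionMatrix(probs).predicted
    acc = 100.0 * float((pred == np.asarray(true_labels)).mean())
    return PhaseMetrics(
        accuracy=acc,
        rmse=probabilistic_rmse(probs, true_labels),
        confusion=confusion_table(true_labels, pred, classes),
        n=len(probs),
    )


def stratified_split(labels, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split: floor(train_fraction·n_c) calibration, rest evaluation.

    With 15 samples per grade this yields the 10/5 per-grade calibration/
    evaluation marginals of the emulated protocol.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    cal, ev = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_cal = int(np.floor(train_fraction * len(idx)))
        cal.extend(idx[:n_cal])
        ev.extend(idx[n_cal:])
    return np.sort(np.array(cal)), np.sort(np.array(ev))


def cross_val_probs(spec: ClassifierSpec, table: FeatureTable,
                    n_folds: int = 10, seed: int = 0
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Pooled stratified k-fold cross-validated class probabilities."""
    y = np.asarray(table.labels)
    classes = np.unique(y)
    min_count = min(np.bincount(pd.factorize(y)[0]))
    folds = min(n_folds, int(min_count))
    if folds < n_folds:
        warnings.warn(
            f"reducing CV folds from {n_folds} to {folds}: smallest class "
            f"has {min_count} samples", stacklevel=2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    probs = pd.DataFrame(np.zeros((table.n_samples, len(classes))),
                         index=table.values.index, columns=classes)
    fold_metrics = []
    for k, (tr, te) in enumerate(skf.split(table.values, y)):
        sub = FeatureTable(table.values.iloc[tr], table.labels.iloc[tr],
                           table.provenance)
        model = train(spec, sub)
        pm = model.predict(table.values.iloc[te])
        probs.iloc[te] = pm.probs[classes].to_numpy()
        fold_acc = 100.0 * float((pm.predicted == y[te]).mean())
        fold_metrics.append({"fold": k, "n": len(te), "accuracy": fold_acc,
                             "rmse": probabilistic_rmse(pm.probs, y[te])})
    return probs, fold_metrics


def evaluate(spec: ClassifierSpec, table: FeatureTable,
             split_seed: int = 0, n_folds: int = 10,
             train_fraction: float = 0.7) -> EvaluationReport:
    """The full protocol: stratified 70/30 split, 10-fold CV, hold-out test."""
    y = np.asarray(table.labels)
    classes = sorted(np.unique(y))
    cal_idx, ev_idx = stratified_split(y, train_fraction, split_seed)
    cal = FeatureTable(table.values.iloc[cal_idx], table.labels.iloc[cal_idx],
                       table.provenance)
    cal_probs, fold_metrics = cross_val_probs(spec, cal, n_folds, split_seed)
    cal_metrics = _phase_metrics(cal_probs, np.asarray(cal.labels), classes)

    model = train(spec, cal)
    ev_pm = model.predict(table.values.iloc[ev_idx])
    ev_metrics = _phase_metrics(ev_pm.probs, y[ev_idx], classes)
    return EvaluationReport(
        spec=spec,
        classes=list(classes),
        calibration=cal_metrics,
        evaluation=ev_metrics,
        fold_metrics=fold_metrics,
        calibration_index=list(table.values.index[cal_idx]),
        evaluation_index=list(table.values.index[ev_idx]),
    )


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """One spec per family, mirroring the study's model line-up."""
    return [
        ClassifierSpec(family="svm", kernel="puk", seed=seed),
        ClassifierSpec(family="bayes_net", bn_search="k2", seed=seed),
        ClassifierSpec(family="tree", pruning="reduced_error", seed=seed),
    ]
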