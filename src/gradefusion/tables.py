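"""Labeled feature tables — the common currency passed between pipeline stages.

A :class:`FeatureTable` couples a samples × features matrix with per-sample
grade labels and a provenance tag saying which sensing modality produced it
(``"enose"``, ``"image"``, or ``"fused"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRADES = ("Grade1", "Grade2", "Grade3")


@dataclass
class FeatureTable:
    """Named feature columns × labeled samples.

    Parameters
    ----------
    values : pandas.DataFrame
        One row per sample, one column per named feature. The index holds
        sample identifiers.
    labels : pandas.Series
        Grade label per sample, aligned with ``values`` row for row.
    provenance : str
        Which modality produced the features: ``enose``, ``image`` or
        ``fused``.
    """

    values: pd.DataFrame
    labels: pd.Series
    provenance: str = "enose"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels, index=self.values.index)
        names = list(self.values.columns)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        if len(self.labels) != len(self.values):
            raise ValueError(
                f"label vector length {len(self.labels)} does not match "
                f"{len(self.values)} samples"
            )
        if not self.labels.index.equals(self.values.index):
            self.labels = pd.Series(
                np.asarray(self.labels), index=self.values.index
            )
        if len(self.values) and self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureTable":
        """Restrict to the given feature columns (order preserved)."""
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.values[names].copy(), self.labels.copy(),
                            self.provenance)

    def to_csv(self, path) -> None:
        """Write as CSV: sample_id first column, grade last column."""
        out = self.values.copy()
        out.insert(0, "sample_id", self.values.index)
        out["grade"] = self.labels.values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "enose") -> "FeatureTable":
        df = pd.read_csv(path)
        df = df.set_index("sample_id")
        labels = df.pop("grade")
        return cls(df, labels, provenance)
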