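"""E-nose signal preprocessing and the six per-sensor response descriptors.

Raw sensor voltages are fractionally normalized against the clean-air
baseline, ``y = (V − V0)/V0``, and six descriptors are computed per sensor
over the headspace window (201–240 s by default):

==========  =====================================================
MSR         maximum fractional response in the window
INV         area under the response curve (trapezoidal integral)
T_im        impregnation time — time from window start to the max
S_asce      mean instantaneous slope over the ascending segment
S_max       maximum instantaneous slope
MDCV        mean differential coefficient — mean of all slopes
==========  =====================================================

At 9 sensors the resulting table has 6 × 9 = 54 named columns
(``MSR_MQ2``, ``INV_TGS2611``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EnoseRecording
from .tables import FeatureTable

FEATURE_ORDER = ("MSR", "INV", "Tim", "Sasce", "Smax", "MDCV")

#: Default reference span: the final 10 s of the baseline phase.
DEFAULT_BASELINE_SPAN_S = 10.0
#: Default extraction window (inclusive), seconds.
DEFAULT_WINDOW = (201.0, 240.0)


@dataclass
class NormalizedResponse:
    """Fractional sensor response with its extraction window."""

    times: np.ndarray
    response: np.ndarray  # sensors × timepoints, dimensionless
    sensor_names: tuple[str, ...]
    window: tuple[float, float] = DEFAULT_WINDOW

    def window_slice(self, sensor_index: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.window
        mask = (self.times >= lo) & (self.times <= hi)
        return self.times[mask], self.response[sensor_index, mask]


@dataclass
class SensorFeatureSet:
    """The six response descriptors of one sensor."""

    MSR: float
    INV: float
    Tim: float
    Sasce: float
    Smax: float
    MDCV: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FEATURE_ORDER}


def fractional_normalize(
    recording: EnoseRecording,
    baseline_span: tuple[float, float] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> NormalizedResponse:
    """Fractional baseline normalization ``y = (V − V0)/V0``.

    ``V0`` is the per-sensor mean voltage over ``baseline_span`` (a
    half-open ``[start, end)`` interval in seconds; default the final 10 s
    of the baseline phase).
    """
    t_inj = recording.phase_boundaries[0]
    if baseline_span is None:
        baseline_span = (t_inj - DEFAULT_BASELINE_SPAN_S, t_inj)
    lo, hi = baseline_span
    if lo < recording.times[0] or hi > t_inj:
        raise ValueError(
            f"baseline_span {baseline_span} lies outside the baseline phase "
            f"[{recording.times[0]}, {t_inj}]"
        )
    mask = (recording.times >= lo) & (recording.times < hi)
    if not mask.any():
        raise ValueError(f"baseline_span {baseline_span} contains no samples")
    v0 = recording.voltages[:, mask].mean(axis=1)
    zero = np.isclose(v0, 0.0)
    if zero.any():
        bad = [recording.sensor_names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero baseline reference for sensors: {bad}")
    y = (recording.voltages - v0[:, None]) / v0[:, None]
    return NormalizedResponse(
        times=recording.times,
        response=y,
        sensor_names=recording.sensor_names,
        window=window,
    )


def extract_sensor_features(
    normalized: NormalizedResponse, sensor: str
) -> SensorFeatureSet:
    """Compute the six descriptors for one sensor over the window.

    With window samples ``y_1..y_n`` at uniform step Δ: MSR is the maximum,
    attained first at index ``i*``; T_im = (i* − 1)·Δ; INV is the
    trapezoidal integral; instantaneous slopes ``d_i = (y_{i+1} − y_i)/Δ``
    give S_max (max), MDCV (mean of all), and S_asce (mean of the slopes on
    the ascending segment up to the max, 0 when the max is the first
    sample).
    """
    try:
        idx = normalized.sensor_names.index(sensor)
    except ValueError:
        raise KeyError(f"unknown sensor {sensor!r}") from None
    t, y = normalized.window_slice(idx)
    if y.size < 3:
        raise ValueError(
            f"window {normalized.window} holds only {y.size} samples; ≥ 3 required"
        )
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("window sampling is not uniform")
    step = dt[0]

    i_star = int(np.argmax(y))  # first occurrence
    msr = float(y[i_star])
    t_im = i_star * step
    inv = float(np.trapezoid(y, dx=step))
    slopes = np.diff(y) / step
    s_max = float(slopes.max())
    mdcv = float(slopes.mean())
    s_asce = float(slopes[:i_star].mean()) if i_star > 0 else 0.0
    return SensorFeatureSet(MSR=msr, INV=inv, Tim=t_im, Sasce=s_asce,
                            Smax=s_max, MDCV=mdcv)


def enose_feature_table(
    recordings: list[EnoseRecording],
    baseline_span: tuple[float, float] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Build the e-nose feature table: one row per recording.

    Columns are ``<FEATURE>_<SENSOR>`` for the six descriptors × every
    sensor — 54 columns for the default 9-sensor array. Column order is
    feature-major and fixed by the sensor order of the recordings.
    """
    if not recordings:
        raise ValueError("no recordings given")
    names = recordings[0].sensor_names
    for k, rec in enumerate(recordings):
        if rec.sensor_names != names:
            raise ValueError(
                f"recording {k} has sensors {rec.sensor_names}, expected {names}"
            )
    columns = [f"{feat}_{s}" for feat in FEATURE_ORDER for s in names]
    rows = []
    for rec in recordings:
        norm = fractional_normalize(rec, baseline_span, window)
        per_sensor = {s: extract_sensor_features(norm, s) for s in names}
        rows.append(
            [getattr(per_sensor[s], feat) for feat in FEATURE_ORDER for s in names]
        )
    if sample_ids is None:
        sample_ids = [f"sample_{i:03d}" for i in range(len(recordings))]
    values = pd.DataFrame(rows, columns=columns, index=sample_ids)
    labels = pd.Series([rec.grade for rec in recordings], index=sample_ids)
    return FeatureTable(values, labels, provenance="enose")
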