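"""Per-sensor response-curve features: 7 time-domain + 5 frequency-domain.

Each sensor's 180-point response x_t yields twelve descriptors:

====  =========================================================
F1    mean of x_t over the whole record
F2    maximum of x_t
F3    area (sum) of x_t over the injection phase, t = 0..T_b
F4    mean over the stable window [T_a, T_b] (first peak to end
      of injection)
F5    maximum first difference (max slope, 1 s sampling)
F6    mean first difference
F7    maximum second difference
F8-12 five largest FFT magnitude amplitudes, DC excluded,
      sorted descending (unnormalized length-180 transform)
====  =========================================================

T_a is the first index at which the injection-phase maximum is attained;
T_b is the last injection index (89, 0-based, for the 90 s phase).
A sample therefore contributes 12 sensors x 12 features = 144 values,
named ``S{sensor}_F{k}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ResponseMatrix
from .synthdata import N_SENSORS, RECORD_SECONDS, INJECTION_SECONDS

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "feature_names",
    "detect_first_peak",
    "extract_sensor_features",
    "extract_features",
]

N_FEATURES = 12

FEATURE_NAMES = [f"S{s}_F{k}" for s in range(1, N_SENSORS + 1)
                 for k in range(1, N_FEATURES + 1)]


def feature_names() -> list[str]:
    """The 144 feature-column names, sensor-major."""
    return list(FEATURE_NAMES)


@dataclass(frozen=True)
class WindowSpec:
    """Record timing: total length T and end-of-injection index T_b (0-based)."""

    T: int = RECORD_SECONDS
    T_b: int = INJECTION_SECONDS - 1

    def __post_init__(self) -> None:
        if not 0 <= self.T_b < self.T:
            raise ValueError("require 0 <= T_b < T")


def detect_first_peak(x: np.ndarray, window: WindowSpec = WindowSpec()) -> int:
    """First index in [0, T_b] attaining the injection-phase maximum.

    For a flat series this is 0 (earliest-index tie-break).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    seg = x[: window.T_b + 1]
    return int(np.argmax(seg))  # argmax returns the first maximal index


def extract_sensor_features(x: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """The 12 descriptors of one sensor's response series.

    Differences use forward differencing of adjacent 1 Hz samples; the
    spectrum is the magnitude of the unnormalized length-T discrete
    Fourier transform, one-sided, DC bin excluded.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (window.T,):
        raise ValueError(f"expected series of length {window.T}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    t_a = detect_first_peak(x, window)
    t_b = window.T_b

    f1 = x.mean()
    f2 = x.max()
    f3 = x[: t_b + 1].sum()
    f4 = x[t_a: t_b + 1].mean()
    d1 = np.diff(x)  # dt = 1 s
    f5 = d1.max()
    f6 = d1.mean()
    f7 = np.diff(d1).max()

    spectrum = np.abs(np.fft.rfft(x))[1:]  # one-sided, DC excluded
    top5 = np.sort(spectrum)[::-1][:5]
    if top5.size < 5:  # short series: pad with zeros
        top5 = np.pad(top5, (0, 5 - top5.size))

    return np.array([f1, f2, f3, f4, f5, f6, f7, *top5])


def extract_features(responses: list[ResponseMatrix]) -> pd.DataFrame:
    """Feature table: one row per sample, 144 named feature columns.

    Columns ``sample_id``, ``label`` and ``environment`` carry the sample
    metadata through the pipeline.
    """
    if not responses:
        raise ValueError("no response matrices given")
    window = WindowSpec()
    rows = []
    for rm in responses:
        if rm.x.shape != (N_SENSORS, window.T):
            raise ValueError(f"record {rm.sample_id}: inconsistent shape {rm.x.shape}")
        feats = np.concatenate([extract_sensor_features(rm.x[s], window)
                                for s in range(N_SENSORS)])
        rows.append((rm.sample_id, rm.class_label, rm.environment, *feats))
    return pd.DataFrame(rows, columns=["sample_id", "label", "environment", *FEATURE_NAMES])
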