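"""Baseline correction and feature normalization.

A MOS sensor's raw resistance drops when reducing gases adsorb on its
heated oxide surface. Expressing the signal as the relative conductivity
x_t = R_air / R_S(t) = G(t) / G_0 (clean-air resistance over in-sample
resistance) cancels part of the sensors' long-term drift and puts all
sensors on a common dimensionless scale, with x = 1 in clean air.

Feature normalization is plain min-max scaling to [0, 1]; the statistics
are fitted on a training split only and applied with clipping elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .synthdata import RawRecord, N_SENSORS, RECORD_SECONDS

__all__ = [
    "ResponseMatrix",
    "NormalizationStats",
    "baseline_correct",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass
class ResponseMatrix:
    """Baseline-corrected responses of one sample: x[sensor, t], 12 x 180."""

    sample_id: str
    class_label: str
    environment: str
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (N_SENSORS, RECORD_SECONDS):
            raise ValueError(f"response matrix must be ({N_SENSORS}, {RECORD_SECONDS})")
        if not np.all(np.isfinite(self.x)) or np.any(self.x <= 0):
            raise ValueError(f"record {self.sample_id}: non-finite or non-positive response")


def baseline_correct(record: RawRecord) -> ResponseMatrix:
    """Convert raw resistances to relative-conductivity responses.

    R_air for each sensor is the arithmetic mean of its pre-clean window;
    the response at time t is x_t = R_air / R_S(t). Records containing
    non-positive resistances are rejected with a diagnostic.
    """
    if record.preclean_resistance.size == 0:
        raise ValueError("empty pre-clean window")
    if np.any(record.preclean_resistance <= 0) or np.any(record.resistance <= 0):
        raise ValueError(f"record {record.sample_id}: non-positive resistance")
    r_air = record.preclean_resistance.mean(axis=1)
    x = r_air[:, None] / record.resistance
    return ResponseMatrix(record.sample_id, record.class_label, record.environment, x)


@dataclass
class NormalizationStats:
    """Column-wise min/max of a fitting set, keyed by feature name."""

    f_min: pd.Series
    f_max: pd.Series

    def __post_init__(self) -> None:
        if not self.f_min.index.equals(self.f_max.index):
            raise ValueError("min/max indices disagree")
        if np.any(self.f_max.to_numpy() < self.f_min.to_numpy()):
            raise ValueError("F_max < F_min")

    @property
    def degenerate(self) -> pd.Index:
        return self.f_min.index[self.f_min.to_numpy() == self.f_max.to_numpy()]


def _feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"sample_id", "label", "environment"}
    return [c for c in table.columns if c not in meta]


def fit_normalizer(table: pd.DataFrame) -> NormalizationStats:
    """Column-wise min and max over a fitting set of feature rows."""
    if len(table) < 2:
        raise ValueError("need at least 2 samples to fit a normalizer")
    cols = _feature_columns(table)
    vals = table[cols]
    stats = NormalizationStats(vals.min(axis=0), vals.max(axis=0))
    if len(stats.degenerate):
        warnings.warn(
            f"{len(stats.degenerate)} constant feature column(s) "
            f"(F_min == F_max); they will normalize to 0",
            stacklevel=2,
        )
    return stats


def apply_normalizer(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Min-max scale features to [0, 1], clipping out-of-range values.

    Degenerate columns (F_min == F_max on the fitting set) map to 0.
    """
    cols = _feature_columns(table)
    if set(cols) != set(stats.f_min.index):
        raise ValueError("feature columns do not match the fitted statistics")
    out = table.copy()
    lo = stats.f_min[cols].to_numpy()
    hi = stats.f_max[cols].to_numpy()
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (table[cols].to_numpy(dtype=float) - lo) / safe
    scaled = np.where(span == 0, 0.0, scaled)
    out[cols] = np.clip(scaled, 0.0, 1.0)
    return out
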