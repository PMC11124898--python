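"""Supervised class-overlap feature discretization.

For each feature the per-class value ranges [min, max] are computed on a
fitting set. The endpoints of those ranges that fall strictly inside the
feature's global range become breakpoints, partitioning the range into
segments: regions covered by a single class range are "pure", regions
covered by several are "overlap" (where class-irrelevant interference such
as ambient gases dominates), and gaps between disjoint ranges keep their
own tag. Values are mapped to the 1-based left-to-right index of their
segment (half-open [b_k, b_{k+1}) convention, last segment closed; values
outside the fitted range are clipped into the first/last segment), and the
tags are re-encoded as one-hot vectors whose width is the segment count.

Collapsing each overlap region to a single tag removes the within-segment
variation that interference creates, which is what makes the encoding
useful for classifiers in odor-polluted environments.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

__all__ = [
    "ClassRange",
    "DiscretizationModel",
    "fit_discretizer",
    "transform",
    "one_hot_encode",
    "overlap_fraction",
]

_META = ("sample_id", "label", "environment")


@dataclass(frozen=True)
class ClassRange:
    class_label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo > hi")


@dataclass
class DiscretizationModel:
    """Per-feature breakpoints and segment widths fitted on labelled data."""

    breakpoints: dict[str, np.ndarray]  # strictly increasing, interior points
    widths: dict[str, int]  # K = number of segments = len(breakpoints)+1
    class_ranges: dict[str, list[ClassRange]]
    global_range: dict[str, tuple[float, float]]

    @property
    def feature_names(self) -> list[str]:
        return list(self.breakpoints)

    def to_json(self) -> str:
        payload = {
            f: {
                "breakpoints": list(map(float, self.breakpoints[f])),
                "width": self.widths[f],
                "global_range": list(self.global_range[f]),
                "class_ranges": [
                    {"class": r.class_label, "lo": r.lo, "hi": r.hi}
                    for r in self.class_ranges[f]
                ],
            }
            for f in self.breakpoints
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationModel":
        payload = json.loads(text)
        return cls(
            breakpoints={f: np.asarray(d["breakpoints"]) for f, d in payload.items()},
            widths={f: int(d["width"]) for f, d in payload.items()},
            class_ranges={
                f: [ClassRange(r["class"], r["lo"], r["hi"]) for r in d["class_ranges"]]
                for f, d in payload.items()
            },
            global_range={f: tuple(d["global_range"]) for f, d in payload.items()},
        )


def fit_discretizer(table: pd.DataFrame, labels: np.ndarray | None = None) -> DiscretizationModel:
    """Fit per-feature breakpoints from per-class value ranges.

    Breakpoints are the sorted distinct class-range endpoints strictly
    inside the global [min, max]; K = breakpoints + 1 segments result.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    if labels is None:
        labels = table["label"].to_numpy()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit")
    cols = [c for c in table.columns if c not in _META]

    breakpoints, widths, ranges, glob = {}, {}, {}, {}
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        crs = [ClassRange(str(y), float(v[labels == y].min()), float(v[labels == y].max()))
               for y in classes]
        lo, hi = min(r.lo for r in crs), max(r.hi for r in crs)
        ends = np.unique([e for r in crs for e in (r.lo, r.hi) if lo < e < hi])
        breakpoints[c] = ends
        widths[c] = len(ends) + 1
        ranges[c] = crs
        glob[c] = (lo, hi)
    return DiscretizationModel(breakpoints, widths, ranges, glob)


def _tag_values(v: np.ndarray, bp: np.ndarray) -> np.ndarray:
    # half-open [b_k, b_{k+1}) segments, 1-based tags; values outside the
    # fitted global range clip into the first/last segment automatically
    return np.searchsorted(bp, v, side="right") + 1


def transform(model: DiscretizationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Map every feature value to its 1-based segment tag."""
    cols = [c for c in table.columns if c not in _META]
    if set(cols) != set(model.feature_names):
        raise ValueError("feature names do not match the fitted model")
    out = table.copy()
    for c in cols:
        out[c] = _tag_values(table[c].to_numpy(dtype=float), model.breakpoints[c])
    return out


def one_hot_encode(tagged: pd.DataFrame, model: DiscretizationModel) -> pd.DataFrame:
    """Expand each tag column to K binary columns ``{feature}_seg{j}``."""
    cols = [c for c in tagged.columns if c not in _META]
    meta = [c for c in tagged.columns if c in _META]
    blocks = [tagged[meta]] if meta else []
    for c in cols:
        k = model.widths[c]
        tags = tagged[c].to_numpy(dtype=int)
        if tags.min() < 1 or tags.max() > k:
            raise ValueError(f"tag out of range for feature {c!r}")
        block = np.zeros((len(tagged), k), dtype=int)
        block[np.arange(len(tagged)), tags - 1] = 1
        blocks.append(pd.DataFrame(
            block, index=tagged.index,
            columns=[f"{c}_seg{j}" for j in range(1, k + 1)]))
    return pd.concat(blocks, axis=1)


def overlap_fraction(model: DiscretizationModel) -> pd.Series:
    """Per-feature fraction of the global range covered by >= 2 class ranges.

    A summary of inter-class redundancy: 0 for fully separated class
    ranges, 1 when every class spans the whole range.
    """
    out = {}
    for f in model.feature_names:
        lo, hi = model.global_range[f]
        span = hi - lo
        if span == 0:
            out[f] = 1.0
            continue
        edges = np.concatenate([[lo], model.breakpoints[f], [hi]])
        overlap = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            cover = sum(1 for r in model.class_ranges[f] if r.lo <= mid <= r.hi)
            if cover >= 2:
                overlap += b - a
        out[f] = overlap / span
    return pd.Series(out)
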