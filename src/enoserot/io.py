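"""On-disk formats: long-format record CSVs, feature tables, selections.

Records are stored as two UTF-8 CSVs with header rows and '.' decimals:

* ``records.csv`` — columns ``sample_id,label,environment,sensor,t,resistance``,
  one row per (sample, sensor, time point), t = 0..179;
* ``baseline.csv`` — companion file with columns
  ``sample_id,sensor,mean_preclean_resistance``.

The baseline companion keeps the clean-air reference compact (the mean is
sufficient for baseline correction); reading reconstructs a constant
pre-clean window from it.
"""

from __future__ import annotations

from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .synthdata import RawRecord, N_SENSORS, PRECLEAN_SECONDS, RECORD_SECONDS

__all__ = ["write_records", "read_records", "write_feature_table",
           "read_feature_table"]

RECORDS_FILE = "records.csv"
BASELINE_FILE = "baseline.csv"


def write_records(records: list[RawRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write a dataset to ``records.csv`` + ``baseline.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_rows, base_rows = [], []
    for r in records:
        for s in range(N_SENSORS):
            base_rows.append((r.sample_id, s + 1, r.preclean_resistance[s].mean()))
            for t in range(RECORD_SECONDS):
                rec_rows.append((r.sample_id, r.class_label, r.environment,
                                 s + 1, t, r.resistance[s, t]))
    rec_path, base_path = out / RECORDS_FILE, out / BASELINE_FILE
    pd.DataFrame(rec_rows, columns=["sample_id", "label", "environment",
                                    "sensor", "t", "resistance"]).to_csv(
        rec_path, index=False)
    pd.DataFrame(base_rows, columns=["sample_id", "sensor",
                                     "mean_preclean_resistance"]).to_csv(
        base_path, index=False)
    return rec_path, base_path


def read_records(path: str | Path) -> list[RawRecord]:
    """Read a dataset directory (or records.csv path) back into records.

    Shape violations (missing sensors or time points) are reported with the
    offending sample id; an empty file yields an empty list with a warning.
    """
    p = Path(path)
    rec_path = p / RECORDS_FILE if p.is_dir() else p
    base_path = rec_path.with_name(BASELINE_FILE)
    if not base_path.exists():
        raise FileNotFoundError(f"missing baseline companion file {base_path}")
    rec = pd.read_csv(rec_path)
    base = pd.read_csv(base_path)
    if rec.empty:
        warnings.warn(f"{rec_path}: no records", stacklevel=2)
        return []
    base_map = {(r.sample_id, int(r.sensor)): float(r.mean_preclean_resistance)
                for r in base.itertuples()}
    records = []
    for sid, grp in rec.groupby("sample_id", sort=False):
        resistance = np.zeros((N_SENSORS, RECORD_SECONDS))
        preclean = np.zeros((N_SENSORS, PRECLEAN_SECONDS))
        for s in range(1, N_SENSORS + 1):
            sg = grp[grp["sensor"] == s].sort_values("t")
            if len(sg) != RECORD_SECONDS or not np.array_equal(
                    sg["t"].to_numpy(), np.arange(RECORD_SECONDS)):
                raise ValueError(
                    f"sample {sid!r}, sensor S{s}: expected {RECORD_SECONDS} "
                    f"time points 0..{RECORD_SECONDS - 1}, got {len(sg)} rows")
            if (sid, s) not in base_map:
                raise ValueError(f"sample {sid!r}, sensor S{s}: no baseline row")
            resistance[s - 1] = sg["resistance"].to_numpy()
            preclean[s - 1] = base_map[(sid, s)]
        records.append(RawRecord(
            sample_id=str(sid),
            class_label=str(grp["label"].iloc[0]),
            environment=str(grp["environment"].iloc[0]),
            preclean_resistance=preclean,
            resistance=resistance,
        ))
    return records


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
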