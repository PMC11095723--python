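"""Dataset and table readers/writers (delimited text only).

Dataset CSV schema: condition_id, replicate, time_h, observable, value
(+ optional split).  Values are validated on read and write; malformed
rows are reported with their line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import OBSERVABLES, Trajectory
from .synthetic import SPLIT_LABELS, TimeSeriesDataset

DATASET_COLUMNS = ("condition_id", "replicate", "time_h", "observable", "value")


class DatasetFormatError(ValueError):
    pass


def _validate_records(records: pd.DataFrame, where: str) -> None:
    missing = set(DATASET_COLUMNS) - set(records.columns)
    if missing:
        raise DatasetFormatError(f"{where}: missing columns {sorted(missing)}")
    bad_obs = ~records["observable"].isin(OBSERVABLES)
    if bad_obs.any():
        rows = (records.index[bad_obs] + 2).tolist()[:5]
        raise DatasetFormatError(f"{where}: unknown observable at line(s) {rows}")
    vals = pd.to_numeric(records["value"], errors="coerce")
    bad_val = vals.isna() | (vals < 0) | ~np.isfinite(vals)
    if bad_val.any():
        rows = (records.index[bad_val] + 2).tolist()[:5]
        raise DatasetFormatError(
            f"{where}: non-numeric or negative value at line(s) {rows}"
        )
    times = pd.to_numeric(records["time_h"], errors="coerce")
    if (times.isna() | (times < 0)).any():
        rows = (records.index[times.isna() | (times < 0)] + 2).tolist()[:5]
        raise DatasetFormatError(f"{where}: invalid time_h at line(s) {rows}")
    if "split" in records.columns:
        bad = ~records["split"].isin(SPLIT_LABELS)
        if bad.any():
            rows = (records.index[bad] + 2).tolist()[:5]
            raise DatasetFormatError(f"{where}: unknown split label at line(s) {rows}")


def write_dataset(dataset: TimeSeriesDataset, path: str | Path) -> Path:
    path = Path(path)
    _validate_records(dataset.records, str(path))
    cols = [c for c in (*DATASET_COLUMNS, "split") if c in dataset.records.columns]
    dataset.records[cols].to_csv(path, index=False)
    return path


def read_dataset(path: str | Path) -> TimeSeriesDataset:
    path = Path(path)
    records = pd.read_csv(path)
    _validate_records(records, str(path))
    records["time_h"] = records["time_h"].astype(float)
    records["value"] = records["value"].astype(float)
    records["replicate"] = records["replicate"].astype(int)
    return TimeSeriesDataset(records, meta={"source": str(path)})


def write_summaries(dataset: TimeSeriesDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.summaries.to_csv(path, index=False)
    return path


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    trajectory.to_frame().to_csv(path, index=False)
    return path
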