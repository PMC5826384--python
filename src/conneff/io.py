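"""Plain-text I/O: labeled square-matrix TSVs, time-series and motion TSVs,
cohort tables, and results JSON.

All floats are written with 17 significant digits so that a write/read
round trip reproduces values to better than 1e-12; missing values are
encoded as "NA".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .preprocess import MotionParams, RoiTimeSeries

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_motion_tsv",
    "read_motion_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_results_json",
    "read_results_json",
]

FLOAT_FMT = "%.17g"
MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_pitch_rad", "rot_roll_rad", "rot_yaw_rad"]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    """pandas TSV read with parse errors re-raised naming the file."""
    try:
        frame = pd.read_csv(path, sep="\t", na_values=["NA"],
                            keep_default_na=False,
                            float_precision="round_trip", **kwargs)
    except ParserError as err:  # pandas names the offending line
        raise ValueError(f"malformed TSV {path}: {err}") from err
    return frame


def _require_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    try:
        return frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for row_pos, (_, row) in enumerate(frame.iterrows()):
            for col, value in row.items():
                if pd.isna(value):
                    continue
                try:
                    float(value)
                except (TypeError, ValueError):
                    # +2: header line plus 1-based numbering
                    raise ValueError(
                        f"non-numeric cell {value!r} in column {col!r} "
                        f"at line {row_pos + 2} of {path}"
                    ) from None
        raise


def write_matrix_tsv(path, matrix: np.ndarray, labels: list[str]) -> None:
    """Square matrix with ROI labels as both header row and first column."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with one label per row")
    frame = pd.DataFrame(matrix, index=labels, columns=labels)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="ROI",
                 na_rep="NA")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    frame = _read_tsv(path, index_col=0)
    labels = [str(c) for c in frame.columns]
    if list(frame.index.astype(str)) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate ROI labels")
    return _require_numeric(frame, path), labels


def write_timeseries_tsv(path, ts: RoiTimeSeries) -> None:
    """Rows = time points, columns = ROI labels (header row)."""
    frame = pd.DataFrame(ts.data, columns=ts.roi_labels)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False,
                 na_rep="NA")


def read_timeseries_tsv(path, tr_seconds: float,
                        subject_id: str | None = None) -> RoiTimeSeries:
    frame = _read_tsv(path)
    labels = [str(c) for c in frame.columns]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate ROI labels")
    data = _require_numeric(frame, path)
    return RoiTimeSeries(
        subject_id=subject_id or Path(path).stem,
        data=data,
        tr_seconds=tr_seconds,
        roi_labels=labels,
    )


def write_motion_tsv(path, mp: MotionParams) -> None:
    frame = pd.DataFrame(mp.data, columns=MOTION_COLUMNS)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)


def read_motion_tsv(path, subject_id: str | None = None) -> MotionParams:
    frame = _read_tsv(path)
    data = _require_numeric(frame, path)
    return MotionParams(subject_id=subject_id or Path(path).stem, data=data)


def write_cohort_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False,
                 na_rep="NA")


def read_cohort_tsv(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    if "subject_id" not in frame.columns or "group" not in frame.columns:
        raise ValueError(f"{path}: cohort table needs subject_id and group columns")
    if frame["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    return frame


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return None if not np.isfinite(value) else value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results_json(path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, no timestamps, NaN/inf as null."""
    Path(path).write_text(
        json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n"
    )


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())
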