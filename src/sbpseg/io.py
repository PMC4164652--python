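"""CSV/JSON readers and writers for every pipeline stage.

All files are plain text: beat series as two-column CSV (``beat_index``,
``sbp_mmHg``), annotations as (``start_beat``, ``end_beat``, ``label``) with
0-based half-open intervals, segmentations as (``start``, ``end``,
``length``, ``mean``, ``variance``), features as one row per subject, and
reports as JSON.  Beat indices must be gap-free from 0 — a gapped series
means missing beats, which must be handled upstream of this pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .patch_stats import SubjectFeatures
from .series import Annotation, BeatSeries, Segment, SegmentationResult

__all__ = [
    "read_beat_series",
    "write_beat_series",
    "read_annotations",
    "write_annotations",
    "read_segments",
    "write_segments",
    "read_features",
    "write_features",
    "write_json",
]

_VALUE_COLUMNS = ("sbp_mmHg", "value")


def read_beat_series(path: str | Path, annotations_path: str | Path | None = None) -> BeatSeries:
    """Read a beat series CSV; validates contiguous 0-based beat indices.

    The value column may be named ``sbp_mmHg`` or ``value``.  If
    ``annotations_path`` is omitted, a ``<stem>.annotations.csv`` sidecar is
    attached when present.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "beat_index" not in df.columns:
        raise ValueError(f"{path}: missing required column 'beat_index'")
    value_col = next((c for c in _VALUE_COLUMNS if c in df.columns), None)
    if value_col is None:
        raise ValueError(f"{path}: need a value column named one of {_VALUE_COLUMNS}")
    idx = pd.to_numeric(df["beat_index"], errors="coerce")
    if idx.isna().any():
        row = int(idx.isna().idxmax())
        raise ValueError(f"{path}: non-numeric beat_index at data row {row + 1}")
    idx = idx.to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(idx, expected):
        bad = int(np.flatnonzero(idx != expected)[0])
        raise ValueError(
            f"{path}: beat_index must run 0..N-1 without gaps; first mismatch at "
            f"data row {bad + 1} (found {int(idx[bad])}, expected {bad})"
        )
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise ValueError(f"{path}: missing/non-numeric {value_col} at data row {row + 1}")
    annotations = None
    if annotations_path is None:
        sidecar = path.parent / (path.stem + ".annotations.csv")
        if sidecar.exists():
            annotations_path = sidecar
    if annotations_path is not None:
        annotations = read_annotations(annotations_path)
    return BeatSeries(vals.to_numpy(), annotations=annotations)


def write_beat_series(series: BeatSeries, path: str | Path,
                      write_annotations_sidecar: bool = True) -> None:
    path = Path(path)
    pd.DataFrame(
        {"beat_index": np.arange(series.n_beats), "sbp_mmHg": series.values}
    ).to_csv(path, index=False)
    if write_annotations_sidecar and series.annotations:
        write_annotations(series.annotations, path.parent / (path.stem + ".annotations.csv"))


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"start_beat", "end_beat"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    labels = df["label"] if "label" in df.columns else ["apnea"] * len(df)
    return [
        Annotation(int(s), int(e), str(lab))
        for s, e, lab in zip(df["start_beat"], df["end_beat"], labels)
    ]


def write_annotations(annotations, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_beat": [a.start for a in annotations],
            "end_beat": [a.end for a in annotations],
            "label": [a.label for a in annotations],
        }
    ).to_csv(path, index=False)


def write_segments(result: SegmentationResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start": [s.start for s in result.segments],
            "end": [s.end for s in result.segments],
            "length": [s.length for s in result.segments],
            "mean": [s.local_mean for s in result.segments],
            "variance": [s.local_var for s in result.segments],
        }
    ).to_csv(path, index=False)


def read_segments(path: str | Path) -> SegmentationResult:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"start", "end", "mean", "variance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: segments CSV needs columns {sorted(required)}")
    segments = [
        Segment(int(r.start), int(r.end), float(r.mean), float(r.variance))
        for r in df.itertuples()
    ]
    return SegmentationResult(segments=segments, n_beats=int(df["end"].max()))


_FEATURE_COLUMNS = ["subject_id", "group", "ahi", "mean_L", "mean_var", "mean_mu",
                    "a_max", "n_segments", "n_beats"]


def write_features(features: list[SubjectFeatures], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(f, c) for c in _FEATURE_COLUMNS} for f in features]
    ).to_csv(path, index=False, float_format="%.10g")


def read_features(path: str | Path) -> list[SubjectFeatures]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_FEATURE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: features CSV missing columns {sorted(missing)}")
    return [
        SubjectFeatures(
            subject_id=str(r.subject_id), group=str(r.group), ahi=float(r.ahi),
            mean_L=float(r.mean_L), mean_var=float(r.mean_var),
            mean_mu=float(r.mean_mu), a_max=float(r.a_max),
            n_segments=int(getattr(r, "n_segments", 0)),
            n_beats=int(getattr(r, "n_beats", 0)),
        )
        for r in df.itertuples()
    ]


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
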