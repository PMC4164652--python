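"""Core containers for beat-to-beat blood-pressure series and their segmentations.

The pipeline's raw input is a systolic blood pressure (SBP) value per heartbeat,
indexed by beat number (not wall-clock time).  Annotations, when present, mark
half-open beat-index intervals (e.g. scored apnea events).  A segmentation is an
ordered, gap-free cover of ``[0, N)`` by stationarity patches, each carrying its
sample mean and (unbiased) sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Annotation", "BeatSeries", "Segment", "SegmentationResult"]


@dataclass(frozen=True)
class Annotation:
    """A labelled half-open beat-index interval ``[start, end)``."""

    start: int
    end: int
    label: str = "apnea"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty annotation interval [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("annotation start must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


class BeatSeries:
    """Per-beat SBP signal (mmHg) with optional interval annotations.

    Parameters
    ----------
    values : array-like of float
        One SBP value per heartbeat; no missing values allowed (gap handling is
        an upstream concern).
    annotations : sequence of Annotation, optional
        Disjoint, sorted half-open beat intervals.
    """

    def __init__(self, values, annotations: Sequence[Annotation] | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("BeatSeries values must be one-dimensional")
        if values.size < 1:
            raise ValueError("BeatSeries must contain at least one beat")
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise ValueError(f"non-finite SBP values at beat indices {bad[:5].tolist()}")
        self.values = values
        anns = sorted(annotations or [], key=lambda a: a.start)
        for prev, cur in zip(anns, anns[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping annotations [{prev.start},{prev.end}) and "
                    f"[{cur.start},{cur.end})"
                )
        if anns and anns[-1].end > values.size:
            raise ValueError("annotation extends past the end of the series")
        self.annotations = tuple(anns)

    @property
    def n_beats(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_beats

    def annotation_mask(self, label: str | None = None) -> np.ndarray:
        """Boolean per-beat mask of annotated beats (optionally one label only)."""
        mask = np.zeros(self.n_beats, dtype=bool)
        for a in self.annotations:
            if label is None or a.label == label:
                mask[a.start : a.end] = True
        return mask

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BeatSeries(n_beats={self.n_beats}, annotations={len(self.annotations)})"


@dataclass(frozen=True)
class Segment:
    """One stationarity patch ``[start, end)`` with its local sample statistics.

    ``local_var`` uses the unbiased estimator (denominator ``L - 1``); a
    single-beat segment (only possible when the whole series is one beat long)
    has variance 0 by convention.
    """

    start: int
    end: int
    local_mean: float
    local_var: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("Segment must satisfy end > start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_values(cls, values: np.ndarray, start: int, end: int) -> "Segment":
        chunk = np.asarray(values[start:end], dtype=float)
        mean = float(chunk.mean())
        var = float(chunk.var(ddof=1)) if chunk.size > 1 else 0.0
        return cls(start=start, end=end, local_mean=mean, local_var=var)


@dataclass
class SegmentationResult:
    """Ordered, contiguous, gap-free cover of a series by stationarity patches."""

    segments: list[Segment]
    n_beats: int
    config: "object | None" = None
    series: BeatSeries | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("SegmentationResult needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.start)
        if segs[0].start != 0 or segs[-1].end != self.n_beats:
            raise ValueError("segments do not cover [0, N)")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ValueError(f"gap/overlap between segments at beat {a.end}")
        self.segments = segs

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def changepoints(self) -> np.ndarray:
        """Interior cut positions (starts of all segments but the first)."""
        return np.array([s.start for s in self.segments[1:]], dtype=int)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=int)

    @property
    def means(self) -> np.ndarray:
        return np.array([s.local_mean for s in self.segments], dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return np.array([s.local_var for s in self.segments], dtype=float)

    def local_mean_series(self) -> np.ndarray:
        """Per-beat step function of the local means (one value per beat)."""
        out = np.empty(self.n_beats, dtype=float)
        for s in self.segments:
            out[s.start : s.end] = s.local_mean
        return out

    def segment_index(self) -> np.ndarray:
        """Per-beat index of the containing segment."""
        out = np.empty(self.n_beats, dtype=int)
        for i, s in enumerate(self.segments):
            out[s.start : s.end] = i
        return out
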