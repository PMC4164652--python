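"""Per-subject quantifiers and group comparisons from segmentations.

A segmentation portrait of one subject is summarized by three numbers: the
mean stationarity-patch length ``<L>`` (beats), the mean of the patch
variances ``<s2>`` (mmHg^2), and the mean of the patch means ``<m>`` (mmHg).
All three are *unweighted* per-segment averages by default ("mean length of
the segments" reads as an average over segments); beat-weighted variants are
available through ``weighted='beats'`` since the weighting convention is a
genuine choice.

Group-level analyses: complementary cumulative distributions of segment
lengths P(L >= l) (per subject or pooled over a group), two-sample KS tests
between groups, quartile summaries, and Pearson correlation of a quantifier
with the apnea-hypopnea index (AHI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .segmentation import ks_distance
from .series import SegmentationResult

__all__ = [
    "SubjectFeatures",
    "LengthDistribution",
    "subject_features",
    "length_ccdf",
    "pooled_ccdf",
    "ks_two_sample",
    "quartiles",
    "pearson",
]


@dataclass
class SubjectFeatures:
    """The quantifiers of one subject, plus its metadata."""

    subject_id: str
    group: str
    ahi: float
    mean_L: float
    mean_var: float
    mean_mu: float
    a_max: float = np.nan
    n_segments: int = 0
    n_beats: int = 0

    @property
    def is_apneic(self) -> bool:
        return self.group != "C"


@dataclass
class LengthDistribution:
    """Complementary cumulative distribution P(L >= l) of segment lengths."""

    lengths: np.ndarray  # distinct observed lengths, ascending
    ccdf: np.ndarray  # P(L >= lengths[i]); non-increasing, starts at 1
    scope: str = "subject"

    def __call__(self, ell) -> np.ndarray | float:
        """P(L >= ell) for arbitrary ell (right-continuous step function)."""
        ell_arr = np.atleast_1d(np.asarray(ell, dtype=float))
        idx = np.searchsorted(self.lengths, ell_arr, side="left")
        padded = np.append(self.ccdf, 0.0)
        out = np.where(idx == 0, 1.0, padded[idx])
        return float(out[0]) if np.asarray(ell).ndim == 0 else out


def subject_features(
    segmentation: SegmentationResult,
    a_max: float = np.nan,
    subject_id: str = "",
    group: str = "C",
    ahi: float = 0.0,
    weighted: str = "segments",
) -> SubjectFeatures:
    """Summarize one subject's segmentation into ``<L>``, ``<s2>``, ``<m>``.

    ``weighted='segments'`` (default) averages one value per segment;
    ``weighted='beats'`` weights each segment by its length.
    """
    if segmentation is None or segmentation.n_segments == 0:
        raise ValueError("subject_features requires a non-empty segmentation")
    lengths = segmentation.lengths.astype(float)
    if weighted == "segments":
        w = np.ones_like(lengths)
    elif weighted == "beats":
        w = lengths
    else:
        raise ValueError("weighted must be 'segments' or 'beats'")
    w = w / w.sum()
    return SubjectFeatures(
        subject_id=subject_id,
        group=group,
        ahi=float(ahi),
        mean_L=float(w @ lengths),
        mean_var=float(w @ segmentation.variances),
        mean_mu=float(w @ segmentation.means),
        a_max=float(a_max),
        n_segments=segmentation.n_segments,
        n_beats=segmentation.n_beats,
    )


def length_ccdf(lengths: Sequence[float], scope: str = "subject") -> LengthDistribution:
    """P(L >= l) evaluated at each distinct observed length."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("length_ccdf requires at least one segment length")
    distinct, first_idx = np.unique(lengths, return_index=True)
    sorted_lengths = np.sort(lengths)
    # count of values >= each distinct length
    n_ge = lengths.size - np.searchsorted(sorted_lengths, distinct, side="left")
    return LengthDistribution(lengths=distinct, ccdf=n_ge / lengths.size, scope=scope)


def pooled_ccdf(per_subject_lengths: Sequence[Sequence[float]],
                scope: str = "group") -> LengthDistribution:
    """Group-level curve: the ccdf of all subjects' segment lengths pooled."""
    pooled = np.concatenate([np.asarray(v, float) for v in per_subject_lengths])
    return length_ccdf(pooled, scope=scope)


def ks_two_sample(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sample KS test: ``(D, p)``.

    ``D`` is the same empirical-CDF distance used by the segmentation scan.
    ``method='auto'`` (default) uses the exact small-sample null distribution
    — indistinguishable from a permutation test for continuous data — and
    falls back to the asymptotic distribution (effective size
    ``n_a n_b / (n_a + n_b)``) for large samples; ``'asymp'`` forces the
    asymptotic formula.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_two_sample requires at least 2 values per sample")
    res = stats.ks_2samp(a, b, method=method)
    d = ks_distance(a, b)
    return d, float(res.pvalue)


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation of the empirical CDF."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quartiles requires at least one value")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(q2), float(q3)


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("pearson requires equal-length inputs")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
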