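"""Synthetic beat-to-beat SBP cohorts with ground truth.

No clinical recordings accompany this package, so every downstream stage is
exercised on synthetic series that reproduce the statistical structure the
analysis assumes:

* a piecewise-stationary baseline — block-constant mean SBP with occasional
  spontaneous level shifts (blood-pressure regulation acting on minute
  scales), plus i.i.d. Gaussian beat-scale noise;
* apneic oscillatory epochs — each scored apnea/hypopnea event drives a slow
  SBP swing, modelled as a sinusoid near 0.02 cycles/beat confined to the
  event interval, with the phase restarting at each event (events are
  physiologically independent);
* an AHI-graded apnea load — the fraction of the night spent in apnea grows
  linearly with the apnea-hypopnea index (AHI, events/hour) through a fixed
  mean event length.

Healthy controls get a *higher* spontaneous level-shift rate than apneic
subjects, so that control records break into shorter stationarity patches — a
modelling choice that encodes the more active blood-pressure regulation
expected in healthy sleep, not a measured clinical parameter.

Ground truth (true change points, true apnea intervals) is carried alongside
every generated subject so recovery can be scored exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .series import Annotation, BeatSeries

__all__ = [
    "GROUPS",
    "SubjectSpec",
    "SyntheticSubject",
    "gen_piecewise_stationary",
    "gen_apnea_oscillation",
    "gen_subject",
    "gen_cohort",
    "default_spec",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_AHI_RANGES",
]

logger = logging.getLogger(__name__)

GROUPS = ("HT", "NT", "C")

#: study design: 10 hypertensive apneic, 16 normotensive apneic, 7 controls
DEFAULT_GROUP_SIZES: Mapping[str, int] = {"HT": 10, "NT": 16, "C": 7}

#: AHI sampling ranges (events/hour).  Apneic groups satisfy the AHI > 15
#: inclusion rule; controls are non-apneic (AHI < 5).  Hypertensive subjects
#: are given the heavier apnea load so the groups' mean apnea occupancy is
#: ordered HT > NT, as observed clinically.
DEFAULT_AHI_RANGES: Mapping[str, tuple[float, float]] = {
    "HT": (16.0, 35.0),
    "NT": (15.0, 22.0),
    "C": (0.0, 4.0),
}

#: nominal heart rate used to convert events/hour into beats
BEATS_PER_HOUR = 3600

#: ceiling on the fraction of the night spent in apnea
MAX_APNEA_FRACTION = 0.9


@dataclass(frozen=True)
class SubjectSpec:
    """Generative parameters for one synthetic subject.

    ``apnea_fraction`` defaults to ``min(0.9, ahi * event_len_beats / 3600)``:
    AHI events per hour, each occupying ``event_len_beats`` beats at a nominal
    60 beats/min.  The default event length of 50 beats (~50 s) is consistent
    with the >= 10 s clinical event definition plus the recovery swing, and
    matches the ~0.02 cycles/beat oscillation the events imprint.
    """

    group: str
    ahi: float
    n_beats: int = 14400
    baseline_mmHg: float = 120.0
    baseline_sd_mmHg: float = 4.0
    seg_rate: float = 0.7  # expected baseline mean shifts per 1000 beats
    shift_sd_mmHg: float = 6.0
    osc_period_beats: int = 50
    osc_amp_mmHg: float = 6.0
    apnea_fraction: float | None = None
    event_len_beats: int = 50
    events_per_epoch: float = 6.0  # mean run of back-to-back events (cyclic trains)
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.ahi < 0:
            raise ValueError("ahi must be >= 0")
        if self.osc_period_beats < 2:
            raise ValueError("osc_period_beats must be >= 2")
        if self.event_len_beats < 1:
            raise ValueError("event_len_beats must be >= 1")
        if self.baseline_sd_mmHg < 0 or self.shift_sd_mmHg < 0 or self.osc_amp_mmHg < 0:
            raise ValueError("noise/shift/oscillation scales must be >= 0")
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2")
        if self.apnea_fraction is None:
            frac = 0.0 if self.group == "C" else min(
                MAX_APNEA_FRACTION, self.ahi * self.event_len_beats / BEATS_PER_HOUR
            )
            object.__setattr__(self, "apnea_fraction", frac)
        if not 0.0 <= self.apnea_fraction <= 1.0:
            raise ValueError("apnea_fraction must lie in [0, 1]")
        if self.group == "C" and self.apnea_fraction != 0.0:
            raise ValueError("control subjects (group C) must have apnea_fraction = 0")


@dataclass
class SyntheticSubject:
    """A generated series plus the ground truth used to score recovery."""

    series: BeatSeries
    true_changepoints: np.ndarray
    true_apnea_intervals: list[tuple[int, int]]
    spec: SubjectSpec
    subject_id: str = ""

    @property
    def realized_apnea_fraction(self) -> float:
        beats = sum(b - a for a, b in self.true_apnea_intervals)
        return beats / self.series.n_beats

    def __post_init__(self) -> None:
        n = self.series.n_beats
        cps = np.asarray(self.true_changepoints, dtype=int)
        if cps.size and not (np.all(cps > 0) and np.all(cps < n)):
            raise ValueError("change points must lie strictly inside (0, n_beats)")
        ivs = sorted(self.true_apnea_intervals)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("apnea intervals must be disjoint")
        if ivs and (ivs[0][0] < 0 or ivs[-1][1] > n):
            raise ValueError("apnea intervals must lie within [0, n_beats)")
        self.true_apnea_intervals = ivs
        self.true_changepoints = np.sort(cps)


def gen_piecewise_stationary(n_beats, changepoints, means, sds, seed) -> BeatSeries:
    """Block-wise i.i.d. Gaussian series: the segmentation's null/recovery fixture.

    ``changepoints`` are strictly increasing interior cut indices; block ``k``
    spans ``[changepoints[k-1], changepoints[k])`` and draws
    ``Normal(means[k], sds[k]**2)``.  Reproducible for a fixed ``seed``.
    """
    changepoints = [int(c) for c in changepoints]
    if any(b <= a for a, b in zip(changepoints, changepoints[1:])):
        raise ValueError("changepoints must be strictly increasing")
    if changepoints and (changepoints[0] <= 0 or changepoints[-1] >= n_beats):
        raise ValueError("changepoints must lie strictly inside (0, n_beats)")
    if len(means) != len(changepoints) + 1 or len(sds) != len(changepoints) + 1:
        raise ValueError("need exactly len(changepoints) + 1 means and sds")
    if any(s < 0 for s in sds):
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    bounds = [0, *changepoints, int(n_beats)]
    values = np.empty(int(n_beats))
    for (a, b), mu, sd in zip(zip(bounds, bounds[1:]), means, sds):
        values[a:b] = mu + sd * rng.standard_normal(b - a)
    return BeatSeries(values)


def gen_apnea_oscillation(n_beats, period_beats, amp, epoch_intervals) -> np.ndarray:
    """Additive oscillation: a sinusoid inside each epoch, zero elsewhere.

    The phase restarts at each epoch start (epochs are independent events, so
    no phase coherence is imposed across them).
    """
    if period_beats < 2:
        raise ValueError("period_beats must be >= 2")
    if amp < 0:
        raise ValueError("amplitude must be >= 0")
    ivs = sorted((int(a), int(b)) for a, b in epoch_intervals)
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping epoch intervals [{a0},{b0}) and [{a1},{b1})")
    if ivs and (ivs[0][0] < 0 or ivs[-1][1] > n_beats):
        raise ValueError("epoch intervals must lie within [0, n_beats)")
    signal = np.zeros(int(n_beats))
    for a, b in ivs:
        phase = np.arange(b - a) * (2.0 * np.pi / period_beats)
        signal[a:b] = amp * np.sin(phase)
    return signal


def _draw_changepoints(rng: np.random.Generator, n_beats: int, seg_rate: float) -> np.ndarray:
    """Poisson process of baseline level shifts (rate per 1000 beats)."""
    if seg_rate <= 0:
        return np.array([], dtype=int)
    gaps = []
    pos = 0.0
    mean_gap = 1000.0 / seg_rate
    while True:
        pos += rng.exponential(mean_gap)
        if pos >= n_beats - 1:
            break
        gaps.append(int(round(pos)))
    return np.unique([g for g in gaps if 0 < g < n_beats])


def _draw_block_means(rng: np.random.Generator, n_blocks: int, baseline: float,
                      shift_sd: float) -> np.ndarray:
    """Mean-reverting (AR(1), phi=0.5) block means around the baseline level."""
    means = np.empty(n_blocks)
    level = 0.0
    for k in range(n_blocks):
        means[k] = baseline + level
        level = 0.5 * level + shift_sd * rng.standard_normal()
    return means


def _draw_apnea_intervals(rng: np.random.Generator, n_beats: int, fraction: float,
                          event_len: int, events_per_epoch: float) -> list[tuple[int, int]]:
    """Place disjoint apnea *epochs* — contiguous trains of back-to-back events.

    Apnea events recur cyclically: a ``round(fraction * n / event_len)`` event
    budget is partitioned into epochs whose sizes are geometric with mean
    ``events_per_epoch``, and the epochs are placed uniformly at random
    subject to disjointness (free space split by a symmetric multinomial
    draw).  Realized coverage differs from the request only by the rounding
    of the event count.
    """
    if fraction <= 0:
        return []
    n_events = int(round(fraction * n_beats / event_len))
    if n_events == 0:
        return []
    if n_events * event_len > n_beats:
        raise ValueError(
            f"cannot fit {n_events} events of {event_len} beats into {n_beats} beats"
        )
    sizes = []
    remaining = n_events
    p = 1.0 / max(events_per_epoch, 1.0)
    while remaining > 0:
        k = min(int(rng.geometric(p)), remaining)
        sizes.append(k)
        remaining -= k
    free = n_beats - n_events * event_len
    gaps = rng.multinomial(free, np.full(len(sizes) + 1, 1.0 / (len(sizes) + 1)))
    intervals = []
    pos = 0
    for k, size in enumerate(sizes):
        pos += int(gaps[k])
        intervals.append((pos, pos + size * event_len))
        pos += size * event_len
    return intervals


def gen_subject(spec: SubjectSpec, subject_id: str = "") -> SyntheticSubject:
    """Compose baseline, apneic oscillation and noise into one subject.

    The series is ``piecewise-stationary baseline (with Gaussian beat noise)
    + epoch-confined sinusoid``; true change points and apnea intervals are
    recorded.  Control subjects never receive apnea intervals.
    """
    rng = np.random.default_rng(spec.seed)
    cps = _draw_changepoints(rng, spec.n_beats, spec.seg_rate)
    means = _draw_block_means(rng, cps.size + 1, spec.baseline_mmHg, spec.shift_sd_mmHg)
    sds = [spec.baseline_sd_mmHg] * (cps.size + 1)
    baseline = gen_piecewise_stationary(
        spec.n_beats, cps.tolist(), means.tolist(), sds, rng
    )
    intervals = _draw_apnea_intervals(
        rng, spec.n_beats, spec.apnea_fraction, spec.event_len_beats,
        spec.events_per_epoch,
    )
    osc = gen_apnea_oscillation(
        spec.n_beats, spec.osc_period_beats, spec.osc_amp_mmHg, intervals
    )
    annotations = [Annotation(a, b, "apnea") for a, b in intervals]
    series = BeatSeries(baseline.values + osc, annotations=annotations)
    subject = SyntheticSubject(
        series=series,
        true_changepoints=cps,
        true_apnea_intervals=intervals,
        spec=spec,
        subject_id=subject_id,
    )
    if abs(subject.realized_apnea_fraction - spec.apnea_fraction) > 0.05:
        warnings.warn(
            f"realized apnea fraction {subject.realized_apnea_fraction:.3f} deviates "
            f"from requested {spec.apnea_fraction:.3f}", stacklevel=2,
        )
    return subject


def default_spec(group: str, ahi: float, seed, n_beats: int = 14400, **overrides) -> SubjectSpec:
    """Group defaults: hypertensive baseline 155 mmHg, others 120 mmHg; controls
    get a four-fold higher spontaneous level-shift rate (4 vs 0.7 per 1000
    beats) so their records break into shorter stationarity patches."""
    params = dict(
        group=group,
        ahi=ahi,
        n_beats=n_beats,
        baseline_mmHg=155.0 if group == "HT" else 120.0,
        seg_rate=4.0 if group == "C" else 0.7,
        seed=seed,
    )
    params.update(overrides)
    return SubjectSpec(**params)


def gen_cohort(
    group_sizes: Mapping[str, int] | None = None,
    ahi_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_beats: int = 14400,
    **spec_overrides,
) -> list[SyntheticSubject]:
    """Reproducible cohort of synthetic subjects.

    Per-subject AHIs are drawn uniformly from the group's range and child
    seeds are spawned deterministically from the root ``seed`` (one
    ``SeedSequence`` child per subject, in a fixed group order), so the cohort
    is reproducible subject by subject.
    """
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    ahi_ranges = {**DEFAULT_AHI_RANGES, **(ahi_ranges or {})}
    for g, size in group_sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if size < 1:
            raise ValueError("group sizes must be >= 1")
    for g in ("HT", "NT"):
        if g in group_sizes and ahi_ranges[g][0] < 15:
            logger.warning(
                "apneic group %s AHI range %s dips below the AHI > 15 inclusion rule",
                g, ahi_ranges[g],
            )
    root = np.random.SeedSequence(seed)
    order = [g for g in GROUPS if g in group_sizes]
    n_total = sum(group_sizes[g] for g in order)
    children = root.spawn(n_total)
    ahi_rng = np.random.default_rng(root.spawn(1)[0])
    subjects = []
    i = 0
    for g in order:
        lo, hi = ahi_ranges[g]
        if lo < 0:
            raise ValueError("AHI ranges must be non-negative")
        for k in range(group_sizes[g]):
            ahi = float(ahi_rng.uniform(lo, hi))
            sid = f"{g}{k + 1:02d}"
            spec = default_spec(g, ahi, seed=children[i], n_beats=n_beats,
                                **spec_overrides)
            subjects.append(gen_subject(spec, subject_id=sid))
            i += 1
    return subjects
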