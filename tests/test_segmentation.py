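"""Unit and property tests for the KS segmentation core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from sbpseg.segmentation import (
    CriticalCurve,
    KSSegmenter,
    SegmentationConfig,
    _null_dmax_sample,
    calibrate_critical_curve,
    find_max_cut,
    ks_distance,
    local_mean_series,
    segment,
)
from sbpseg.series import BeatSeries


def naive_max_cut(x, l0):
    """Exhaustive oracle: recompute every KS distance from scratch."""
    best_d, best_t = -1.0, -1
    for t in range(l0, x.size - l0 + 1):
        d = ks_distance(x[:t], x[t:])
        if d > best_d:
            best_d, best_t = d, t
    return best_t, best_d


class TestKSDistance:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((1, 2, 3), (1, 2, 3), 0.0),  # identical samples
            ((0, 0, 0), (1, 1, 1), 1.0),  # disjoint supports
            ((1, 2), (2, 3), 0.5),  # hand-computed pooled-CDF evaluation
        ],
    )
    def test_examples(self, left, right, expected):
        assert ks_distance(left, right) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_distance([], [1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_scipy_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(rng.integers(1, 40))
        b = rng.standard_normal(rng.integers(1, 40))
        if seed % 2:  # exercise ties
            a, b = np.round(a), np.round(b)
        d = ks_distance(a, b)
        assert d == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)
        assert d == ks_distance(b, a)
        assert 0.0 <= d <= 1.0


class TestFindMaxCut:
    def test_constant_series_has_zero_distance(self):
        t, d = find_max_cut(np.full(120, 7.0), 0, 120, l0=10)
        assert d == 0.0

    def test_noiseless_step_found_exactly(self):
        x = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        t, d = find_max_cut(x, 0, 200, l0=10)
        assert (t, d) == (100, 1.0)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(60, 200))
            l0 = int(rng.integers(2, n // 2 - 1))
            x = rng.standard_normal(n)
            assert find_max_cut(x, 0, n, l0) == naive_max_cut(x, l0)

    def test_tie_broken_to_smallest_index(self):
        # symmetric 0/1/0 profile: cuts at 50 and 100 tie at D = 0.5
        x = np.concatenate([np.zeros(50), np.ones(50), np.zeros(50)])
        t, d = find_max_cut(x, 0, 150, l0=10)
        assert d == pytest.approx(0.5)
        assert t == 50

    def test_subwindow_uses_absolute_indices(self, rng):
        x = np.concatenate([rng.standard_normal(50),
                            np.zeros(60), np.full(60, 9.0)])
        t, d = find_max_cut(x, 50, 170, l0=10)
        assert t == 110 and d == 1.0

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="2\\*l0"):
            find_max_cut(np.zeros(50), 0, 50, l0=30)

    def test_noisy_step_localization(self, rng):
        errors = []
        for _ in range(20):
            x = np.concatenate([rng.standard_normal(100),
                                5.0 + rng.standard_normal(100)])
            t, _ = find_max_cut(x, 0, 200, l0=10)
            errors.append(abs(t - 100))
        assert np.median(errors) <= 5


class TestCriticalCurve:
    def test_monotone_non_increasing_in_n(self, default_curve):
        grid = default_curve.lengths
        vals = default_curve(grid)
        assert np.all(np.diff(vals) <= 0)
        # also between grid points
        probe = np.linspace(grid[0], grid[-1], 50)
        assert np.all(np.diff(default_curve(probe)) <= 1e-12)

    def test_values_in_unit_interval(self, default_curve):
        assert np.all(default_curve.values > 0) and np.all(default_curve.values <= 1)

    def test_alpha_half_equals_null_median(self, tmp_path):
        curve = calibrate_critical_curve([70], alpha=0.5, l0=33, n_null=200,
                                         seed=3, cache_dir=tmp_path)
        null = _null_dmax_sample(70, 33, 200, (3, 70))
        assert curve.values[0] == pytest.approx(np.median(null))

    def test_cache_roundtrip(self, tmp_path):
        c1 = calibrate_critical_curve([70, 100], alpha=0.1, l0=33, n_null=50,
                                      seed=1, cache_dir=tmp_path)
        c2 = calibrate_critical_curve([70, 100], alpha=0.1, l0=33, n_null=50,
                                      seed=1, cache_dir=tmp_path)
        assert np.array_equal(c1.values, c2.values)
        assert len(list(tmp_path.glob("critical_curve_*.json"))) == 1

    def test_packaged_point_is_reproducible(self, default_curve):
        """Recomputing the smallest grid point from its recorded seed must
        reproduce the packaged threshold exactly."""
        prov = default_curve.provenance
        n = int(default_curve.lengths[0])
        n_null = prov["n_null"][0]
        null = _null_dmax_sample(n, default_curve.l0, n_null, (prov["seed"], n))
        expected = np.quantile(null, 1.0 - default_curve.alpha)
        assert default_curve.values[0] == pytest.approx(expected, rel=1e-12)

    def test_user_supplied_curve(self):
        curve = CriticalCurve.from_function(lambda n: 0.5 / np.log(n), alpha=0.05, l0=10)
        assert curve(100) == pytest.approx(0.5 / np.log(100), rel=0.02)

    def test_exceedance_matches_alpha(self, tmp_path):
        """Fresh null batch: P(D_max > D_crit) is binomially consistent with alpha."""
        alpha, n, reps = 0.1, 80, 400
        curve = calibrate_critical_curve([n], alpha=alpha, l0=33, n_null=1000,
                                         seed=11, cache_dir=tmp_path)
        fresh = _null_dmax_sample(n, 33, reps, (99, n))
        frac = np.mean(fresh > curve.values[0])
        half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(frac - alpha) <= half_width


class TestSegment:
    def test_partition_invariants(self, default_config, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 1, 260),
                            rng.normal(-3, 1, 200)])
        res = segment(x, default_config)
        starts = [s.start for s in res.segments]
        ends = [s.end for s in res.segments]
        assert starts[0] == 0 and ends[-1] == x.size
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))
        assert min(s.length for s in res.segments) >= default_config.l0
        for s in res.segments:
            assert s.local_mean == pytest.approx(x[s.start:s.end].mean())
            assert s.local_var == pytest.approx(x[s.start:s.end].var(ddof=1))

    def test_two_level_step_recovered(self, default_config, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])
        res = segment(x, default_config)
        assert res.n_segments == 2
        assert abs(res.segments[0].end - 200) <= default_config.l0 // 2

    def test_constant_series_single_segment(self, default_config):
        res = segment(np.full(500, 120.0), default_config)
        assert res.n_segments == 1

    def test_short_series_single_segment(self, default_config):
        res = segment(np.arange(40.0), default_config)
        assert res.n_segments == 1 and res.segments[0].length == 40

    def test_fixed_point_no_further_cuts(self, default_config, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        res = segment(x, default_config)
        for s in res.segments:
            sub = segment(x[s.start:s.end], default_config)
            assert sub.n_segments == 1

    def test_accepts_beat_series(self, default_config, rng):
        series = BeatSeries(rng.normal(120, 4, 200))
        res = segment(series, default_config)
        assert res.n_beats == 200


class TestLocalMeanSeries:
    def test_single_segment_constant(self, default_config, rng):
        x = rng.normal(0, 1, 100)
        res = segment(x, default_config)
        assert np.allclose(local_mean_series(res), x.mean())

    def test_step_function_and_zero_residuals(self, default_config, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])
        res = segment(x, default_config)
        lm = local_mean_series(res)
        assert lm.size == x.size
        for s in res.segments:
            assert np.sum(x[s.start:s.end] - lm[s.start:s.end]) == pytest.approx(0, abs=1e-9)


class TestKSSegmenterEstimator:
    def test_fit_transform_detrends(self, default_curve, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)])
        est = KSSegmenter(critical_curve=default_curve)
        filtered = est.fit(x).transform(x)
        assert est.n_beats_ == 400
        assert len(est.segments_) == est.result_.n_segments
        for s in est.segments_:
            assert filtered[s.start:s.end].mean() == pytest.approx(0, abs=1e-9)

    def test_sklearn_params_and_clone(self):
        est = KSSegmenter(alpha=0.05, l0=20)
        assert est.get_params()["alpha"] == 0.05
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_requires_fit_and_matching_length(self, default_curve, rng):
        est = KSSegmenter(critical_curve=default_curve)
        with pytest.raises(RuntimeError, match="not fitted"):
            est.transform(rng.normal(size=100))
        est.fit(rng.normal(size=100))
        with pytest.raises(ValueError, match="does not match"):
            est.transform(rng.normal(size=101))


def test_config_validation():
    with pytest.raises(ValueError, match="alpha"):
        SegmentationConfig(alpha=1.5)
    with pytest.raises(ValueError, match="l0"):
        SegmentationConfig(l0=1)
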