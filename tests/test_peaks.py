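"""NI peak detection, half-prominence widths, and incidence."""
import numpy as np
import pytest

from neurodyn import (Trace, WindowSpec, detect_peaks, duration_vs_magnitude,
                      incidence)

W = WindowSpec(length=60)


def trace_of(values, start=0.0):
    values = np.asarray(values, float)
    return Trace(values=values,
                 anchor_times=start + np.arange(values.size, dtype=float),
                 window=W)


def width_oracle(x, peak, prominence, rel=0.5):
    """Interpolated crossing search outward from the peak."""
    h = x[peak] - rel * prominence
    i = peak
    while x[i] > h:
        i -= 1
    left = i + (h - x[i]) / (x[i + 1] - x[i]) if x[i + 1] != x[i] else i
    j = peak
    while x[j] > h:
        j += 1
    right = j - (h - x[j]) / (x[j - 1] - x[j]) if x[j - 1] != x[j] else j
    return right - left


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        assert detect_peaks(trace_of(np.zeros(100))) == []

    def test_triangular_bump_geometry(self):
        up = np.linspace(0, 0.4, 21)
        x = np.concatenate([up, up[::-1][1:], np.zeros(10)])
        peaks = detect_peaks(trace_of(x), min_prominence=0.1)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.magnitude == pytest.approx(0.4)
        assert p.prominence == pytest.approx(0.4)
        # crossings at 0.2 sit 10 s either side of the apex
        assert p.duration == pytest.approx(20.0, abs=1e-9)
        assert p.left_edge < p.anchor_time < p.right_edge

    def test_gaussian_bump_has_fwhm_width(self):
        t = np.arange(201, dtype=float)
        sigma = 12.0
        x = 0.5 * np.exp(-((t - 100) ** 2) / (2 * sigma ** 2))
        peaks = detect_peaks(trace_of(x), min_prominence=0.1)
        assert len(peaks) == 1
        fwhm = sigma * 2 * np.sqrt(2 * np.log(2))
        assert peaks[0].duration == pytest.approx(fwhm, abs=1.0)

    def test_widths_match_crossing_oracle_on_random_traces(self, rng):
        checked = 0
        for _ in range(60):
            n = int(rng.integers(80, 200))
            raw = rng.normal(size=n)
            kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
            x = np.convolve(raw, kernel / kernel.sum(), mode="same")
            x = np.clip(x - x.min(), 0, None)
            for p in detect_peaks(trace_of(x), min_prominence=0.05):
                idx = int(p.anchor_time)
                checked += 1
                assert p.duration == pytest.approx(
                    width_oracle(x, idx, p.prominence), abs=1e-9)
        assert checked >= 50

    def test_raising_prominence_never_adds_peaks(self, rng):
        x = np.clip(np.convolve(rng.normal(size=300), np.ones(15) / 15,
                                mode="same"), 0, None)
        counts = [len(detect_peaks(trace_of(x), min_prominence=thr))
                  for thr in (0.01, 0.05, 0.1, 0.2, 0.4)]
        assert counts == sorted(counts, reverse=True)

    def test_each_interval_contains_its_anchor_maximum(self, rng):
        x = np.clip(np.convolve(rng.normal(size=400), np.ones(20) / 20,
                                mode="same"), 0, None)
        for p in detect_peaks(trace_of(x), min_prominence=0.05):
            assert p.left_edge < p.anchor_time < p.right_edge
            assert p.prominence <= p.magnitude + 1e-12

    def test_boundary_maxima_excluded(self):
        x = np.linspace(0.5, 0.0, 50)  # maximum at index 0
        assert detect_peaks(trace_of(x), min_prominence=0.1) == []

    def test_nan_gaps_split_the_trace(self):
        up = np.linspace(0, 0.4, 11)
        bump = np.concatenate([up, up[::-1][1:]])
        x = np.concatenate([bump, [np.nan] * 5, bump])
        peaks = detect_peaks(trace_of(x), min_prominence=0.1)
        assert len(peaks) == 2
        assert peaks[0].anchor_time < peaks[1].anchor_time


class TestDurationVsMagnitude:
    def bump(self, height, half=10):
        up = np.linspace(0, height, half + 1)
        return np.concatenate([up, up[::-1][1:]])

    def test_single_bump_constant_then_empty(self):
        x = np.concatenate([np.zeros(5), self.bump(0.2), np.zeros(5)])
        table = duration_vs_magnitude([trace_of(x)], [0.05, 0.1, 0.3])
        assert table.n_peaks.tolist() == [1, 1, 0]
        d = table.mean_duration_s
        assert d[0] == pytest.approx(d[1])
        assert np.isnan(d[2])

    def test_counts_drop_as_grid_crosses_prominences(self):
        x = np.concatenate([np.zeros(3), self.bump(0.15), np.zeros(5),
                            self.bump(0.3), np.zeros(3)])
        table = duration_vs_magnitude([trace_of(x)], [0.1, 0.2])
        assert table.n_peaks.tolist() == [2, 1]

    def test_matches_brute_force_re_detection(self, rng):
        traces = []
        for _ in range(5):
            x = np.clip(np.convolve(rng.normal(size=300), np.ones(15) / 15,
                                    mode="same"), 0, None)
            traces.append(trace_of(x))
        grid = [0.02, 0.05, 0.1]
        table = duration_vs_magnitude(traces, grid)
        for i, thr in enumerate(grid):
            durs = [p.duration for t in traces
                    for p in detect_peaks(t, min_prominence=thr)]
            assert table.n_peaks[i] == len(durs)
            if durs:
                assert table.mean_duration_s[i] == pytest.approx(
                    np.mean(durs))

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            duration_vs_magnitude([trace_of(np.zeros(10))], [0.2, 0.1])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            duration_vs_magnitude([trace_of(np.zeros(10))], [])


class TestIncidence:
    def test_no_peaks_zero_fraction(self):
        tr = trace_of(np.zeros(600))
        summary = incidence([[]], [tr])
        assert summary.fraction == 0.0
        assert summary.total_epochs == 600

    def test_single_interval_fraction(self):
        tr = trace_of(np.zeros(600))
        up = np.linspace(0, 0.4, 16)
        x = np.zeros(600)
        x[100:131] = np.concatenate([up, up[::-1][1:]])
        tr = trace_of(x)
        peaks = detect_peaks(tr, min_prominence=0.1)
        assert len(peaks) == 1
        summary = incidence([peaks], [tr])
        covered = peaks[0].right_edge - peaks[0].left_edge
        assert summary.fraction == pytest.approx(covered / 600, abs=2 / 600)

    def test_ten_streams_union_counting(self, rng):
        """10 streams x 600 s with 42 covered seconds each -> 0.07."""
        traces, plists = [], []
        for _ in range(10):
            x = np.zeros(600)
            up = np.linspace(0, 0.4, 43)  # half-prominence width 42 s
            x[200:285] = np.concatenate([up, up[::-1][1:]])
            tr = trace_of(x)
            peaks = detect_peaks(tr, min_prominence=0.1)
            traces.append(tr)
            plists.append(peaks)
        summary = incidence(plists, traces)
        assert summary.total_epochs == 6000
        assert summary.fraction == pytest.approx(0.07, abs=0.005)
        assert summary.percent == pytest.approx(7.0, abs=0.5)

    def test_overlapping_peaks_count_each_second_once(self, rng):
        """Union semantics against a brute-force interval-union oracle."""
        for _ in range(50):
            n = int(rng.integers(100, 300))
            x = np.clip(np.convolve(rng.normal(size=n), np.ones(12) / 12,
                                    mode="same"), 0, None)
            tr = trace_of(x)
            peaks = detect_peaks(tr, min_prominence=0.03)
            summary = incidence([peaks], [tr])
            covered = set()
            for p in peaks:
                covered |= {t for t in range(n)
                            if p.left_edge <= t <= p.right_edge}
            assert summary.epochs_in_peaks == len(covered)
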