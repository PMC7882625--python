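"""Windowed entropy, NI, randomized baselines and the MI decomposition."""
import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import binom

from neurodyn import (AlignmentError, NeurodynError, StratumError,
                      SymbolStream, TeamStream, WindowSpec, aggregate_ni,
                      compose_team, ni_from_entropy, ni_trace,
                      randomized_baseline, shared_information,
                      subtract_baseline, windowed_entropy)
from conftest import random_member_stream, random_team_stream

W60 = WindowSpec(length=60)


def entropy_oracle(symbols):
    """Histogram -sum p log2 p loop, independent of the vectorized path."""
    counts = Counter(symbols)
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


class TestWindowedEntropy:
    @pytest.mark.parametrize("symbols,expected", [
        ([3] * 60, 0.0),
        ([-1] * 20 + [1] * 20 + [3] * 20, math.log2(3)),
        ([-1] * 30 + [1] * 15 + [3] * 15, 1.5),
    ])
    def test_known_window_histograms(self, symbols, expected):
        tr = windowed_entropy(SymbolStream(np.array(symbols)), W60)
        assert tr.values == pytest.approx([expected])

    def test_matches_brute_force_oracle_on_random_streams(self, rng):
        for _ in range(60):
            n = int(rng.integers(20, 120))
            w = WindowSpec(length=int(rng.integers(5, n + 1)),
                           step=int(rng.integers(1, 4)))
            s = random_member_stream(rng, n=n)
            tr = windowed_entropy(s, w)
            for j, start in enumerate(range(0, n - w.length + 1, w.step)):
                expected = entropy_oracle(
                    s.symbols[start:start + w.length].tolist())
                assert tr.values[j] == pytest.approx(expected, abs=1e-12)

    def test_trailing_anchor_times(self):
        s = SymbolStream(np.array([-1, 1, 3] * 40), start_time=100.0)
        tr = windowed_entropy(s, W60)
        assert tr.anchor_times[0] == 100.0 + 59
        assert tr.anchor_times[-1] == 100.0 + 119
        assert len(tr) == 61

    def test_masked_epochs_use_unmasked_subset(self):
        syms = np.array([3] * 60)
        mask = np.ones(60, bool)
        mask[:10] = False
        tr = windowed_entropy(SymbolStream(syms, mask=mask), W60)
        assert tr.values[0] == 0.0
        assert tr.effective_n[0] == 50

    def test_low_occupancy_window_masked(self):
        mask = np.zeros(60, bool)
        mask[:10] = True
        tr = windowed_entropy(SymbolStream(np.array([3] * 60), mask=mask), W60)
        assert np.isnan(tr.values[0])

    def test_stream_shorter_than_window_raises(self):
        with pytest.raises(AlignmentError):
            windowed_entropy(SymbolStream(np.array([1] * 30)), W60)


class TestNIFromEntropy:
    @pytest.mark.parametrize("n_symbols,expected", [
        (9, 3.17), (27, 4.75), (3, 1.58)])
    def test_maximum_entropy_bounds(self, n_symbols, expected):
        assert ni_from_entropy(0.0, n_symbols) == pytest.approx(expected,
                                                                abs=0.005)

    def test_uniform_entropy_gives_zero_ni(self):
        assert ni_from_entropy(math.log2(9), 9) == pytest.approx(0.0)

    def test_entropy_above_bound_raises(self):
        with pytest.raises(NeurodynError):
            ni_from_entropy(np.array([1.7]), 3)

    def test_ni_bounds_hold_on_random_streams(self, rng):
        for _ in range(20):
            tr = ni_trace(random_team_stream(rng, n=200), W60)
            assert np.all(tr.values >= 0)
            assert np.all(tr.values <= tr.hmax + 1e-9)


class TestRandomizedBaseline:
    def test_constant_stream_baseline_equals_raw(self):
        s = SymbolStream(np.full(120, 3))
        raw = ni_trace(s, W60)
        base = randomized_baseline(s, W60, n_shuffles=3, seed=0)
        assert np.allclose(base.values, raw.values)

    @pytest.mark.parametrize("n_states,expected", [(9, 0.096), (3, 0.024)])
    def test_iid_uniform_baseline_matches_bias_oracle(self, rng, n_states,
                                                      expected):
        # Miller-Madow first-order bias (S-1)/(2N ln 2) for N = 60
        s = TeamStream(symbols=rng.integers(1, n_states + 1, 4000),
                       member_ids=("A", "B")[:2 if n_states == 9 else 1])
        base = randomized_baseline(s, W60, n_shuffles=6, seed=1)
        assert np.nanmean(base.values) == pytest.approx(expected, abs=0.02)

    def test_estimator_matches_exact_finite_sample_expectation(self, rng):
        """Plug-in NI mean equals the closed-form binomial expectation
        E[log2 S - H] for i.i.d. uniform streams, at every (S, N) cell."""
        for s_size in (3, 9, 27):
            for n_win in (30, 60, 120):
                x = np.arange(n_win + 1)
                pmf = binom.pmf(x, n_win, 1.0 / s_size)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = np.where(x > 0, (x / n_win) * np.log2(x / n_win), 0.0)
                exact = math.log2(s_size) + s_size * float((pmf * f).sum())
                draws = rng.integers(0, s_size, size=(400, n_win))
                ni = np.empty(400)
                for i in range(400):
                    counts = np.bincount(draws[i], minlength=s_size)
                    p = counts[counts > 0] / n_win
                    ni[i] = math.log2(s_size) + float((p * np.log2(p)).sum())
                se = ni.std(ddof=1) / 20
                assert abs(ni.mean() - exact) < 3 * se

    def test_invalid_shuffle_count(self, member_stream):
        with pytest.raises(ValueError):
            randomized_baseline(member_stream, W60, n_shuffles=0)


class TestSubtractBaseline:
    def test_identical_traces_give_zero(self, member_stream):
        raw = ni_trace(member_stream, W60)
        out = subtract_baseline(raw, raw)
        assert np.allclose(out.values, 0.0)
        assert out.corrected

    def test_elementwise_difference_floored_at_zero(self, member_stream):
        raw = ni_trace(member_stream, W60)
        base = randomized_baseline(member_stream, W60, seed=2)
        out = subtract_baseline(raw, base)
        expected = np.clip(raw.values - base.values, 0, None)
        assert np.allclose(out.values, expected)

    def test_corrected_iid_stream_mean_near_zero(self, rng):
        s = random_member_stream(rng, n=2000)
        out = subtract_baseline(ni_trace(s, W60),
                                randomized_baseline(s, W60, seed=3))
        # bias cancels in expectation; the zero floor keeps the mean >= 0
        assert 0 <= np.nanmean(out.values) < 0.02

    def test_mismatched_windows_raise(self, member_stream):
        raw = ni_trace(member_stream, W60)
        base = randomized_baseline(member_stream, WindowSpec(30), seed=0)
        with pytest.raises(AlignmentError):
            subtract_baseline(raw, base)


class TestSharedInformation:
    def test_identical_streams_mi_equals_marginal_entropy(self):
        syms = np.array([-1] * 20 + [1] * 20 + [3] * 20)
        a = SymbolStream(syms, member="A")
        b = SymbolStream(syms.copy(), member="B")
        mi = shared_information([a, b], W60)
        assert mi.values == pytest.approx([math.log2(3)])

    def test_decomposition_identity_per_window(self, dyad):
        a, b = dyad
        mi = shared_information([a, b], W60)
        team = compose_team([a, b])
        resid = (ni_trace(team, W60).values - ni_trace(a, W60).values
                 - ni_trace(b, W60).values - mi.values)
        assert np.abs(resid).max() < 1e-10

    def test_independent_streams_mi_within_estimator_bias(self, rng):
        a = random_member_stream(rng, n=5000, member="A")
        b = random_member_stream(rng, n=5000, member="B")
        mi = shared_information([a, b], W60)
        # plug-in MI of independent streams ~ (3-1)(3-1)/(2N ln 2)
        bias = 4 / (2 * 60 * math.log(2))
        assert np.nanmean(mi.values) == pytest.approx(bias, abs=0.02)

    def test_triads_unsupported(self, rng):
        members = [random_member_stream(rng, member=f"M{i}") for i in range(3)]
        with pytest.raises(NeurodynError, match="dyads"):
            shared_information(members, W60)


class TestAggregateNI:
    def test_single_trace_identity(self, member_stream):
        tr = ni_trace(member_stream, W60)
        agg = aggregate_ni([tr], level="scalp")
        assert np.allclose(agg.values, tr.values)

    def test_two_constant_traces_average(self, member_stream):
        tr = ni_trace(member_stream, W60)
        t1 = type(tr)(values=np.full(len(tr), 0.1),
                      anchor_times=tr.anchor_times, window=tr.window,
                      n_symbols=3)
        t2 = type(tr)(values=np.full(len(tr), 0.3),
                      anchor_times=tr.anchor_times, window=tr.window,
                      n_symbols=3)
        agg = aggregate_ni([t1, t2], level="scalp")
        assert np.allclose(agg.values, 0.2)

    def test_full_montage_mean_matches_brute_force(self, rng):
        channels = [f"ch{i}" for i in range(19)]
        bins = list(range(1, 41))
        traces = []
        for ch in channels:
            for b in bins:
                s = random_member_stream(rng, n=80, channel=ch,
                                         bin_hz=float(b))
                traces.append(ni_trace(s, W60))
        assert len(traces) == 760
        agg = aggregate_ni(traces, level="scalp")
        brute = np.mean(np.vstack([t.values for t in traces]), axis=0)
        assert np.allclose(agg.values, brute)
        by_freq = aggregate_ni(traces, level="frequency")
        assert len(by_freq) == 40
        one = np.mean(np.vstack([t.values for t in traces
                                 if t.coords["bin_hz"] == 7.0]), axis=0)
        assert np.allclose(by_freq["7.0"].values, one)

    def test_empty_stratum_raises(self):
        with pytest.raises(StratumError):
            aggregate_ni([], level="scalp")

    def test_region_level_requires_scheme(self, member_stream):
        tr = ni_trace(member_stream, W60)
        with pytest.raises(StratumError):
            aggregate_ni([tr], level="region")


def test_persistence_raises_mean_ni(rng):
    """Mean NI grows monotonically with the hold probability of a planted
    persistent symbol (synthetic ladder)."""
    from neurodyn import PlantedEpoch, SimConfig, simulate_symbols

    means = []
    for hold in (0.4, 0.6, 0.8, 1.0):
        cfg = SimConfig(seed=7, members=("M1",), duration_s=400, epochs=(
            PlantedEpoch(start=100, duration=200, member="M1", channel="C3",
                         bin_hz=10.0, held_symbol=3, hold_prob=hold),))
        streams, _ = simulate_symbols(cfg)
        tr = ni_trace(streams[("M1", "C3", 10.0)], W60)
        means.append(np.nanmean(tr.values))
    assert means == sorted(means)
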