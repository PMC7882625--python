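"""Numeric EEG power values (EEG-PV) and their correlation with NI.

The ternary symbols keep their activation meaning when read numerically:
-1 (deactivated), 1 (average), 3 (activated). A 60-s moving average of
these values — the EEG-PV trace — sits on the same window anchors as NI,
so the two can be correlated over time. Because symbolization enforces
equal occupancy, the whole-performance mean EEG-PV of any complete stream
is exactly 1.0; sustained excursions above/below 1 mark net activation/
deactivation.

Regional maps aggregate (average) the member streams within a scalp
region *before* correlating, one correlation series per stratum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, StratumError
from .neurodynamics import NITrace, Trace
from .symbolize import SymbolStream
from .windows import WindowSpec

__all__ = ["PVTrace", "RegionScheme", "DEFAULT_REGIONS", "eeg_pv",
           "ni_pv_correlation", "correlation_map"]

#: the standard four-region partition of the 19-channel 10-20 montage
DEFAULT_REGIONS: dict[str, str] = {
    **{ch: "frontal" for ch in ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")},
    **{ch: "central" for ch in ("T3", "C3", "Cz", "C4", "T4")},
    **{ch: "parietal" for ch in ("P7", "P3", "Pz", "P4", "P8")},
    **{ch: "occipital" for ch in ("O1", "O2")},
}


@dataclass
class PVTrace(Trace):
    """Moving-average numeric symbol value per window; range [-1, 3]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = np.isfinite(self.values)
        if finite.any():
            v = self.values[finite]
            if v.min() < -1 - 1e-9 or v.max() > 3 + 1e-9:
                raise ValueError(
                    f"EEG-PV outside [-1, 3]: [{v.min():.6g}, {v.max():.6g}]")


@dataclass(frozen=True)
class RegionScheme:
    """Channel label -> scalp region mapping (regions partition channels)."""

    mapping: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))

    def region_of(self, channel: str) -> str | None:
        return self.mapping.get(channel)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def unmapped(self, channels: Sequence[str]) -> tuple[str, ...]:
        return tuple(c for c in channels if c not in self.mapping)


def eeg_pv(stream: SymbolStream, window: WindowSpec | None = None) -> PVTrace:
    """Moving average of the numeric -1/1/3 symbol values.

    Emitted on the same anchors as NI (trailing by default). Masked epochs
    are excluded from each window's mean; windows below the occupancy
    floor are NaN.
    """
    window = window or WindowSpec()
    vals = stream.values()  # floats, NaN where masked
    n = vals.size
    nw = window.n_windows(n)
    if nw == 0:
        raise AlignmentError(
            f"stream length {n} shorter than window length {window.length}")
    finite = np.isfinite(vals)
    vsum = np.concatenate([[0.0], np.cumsum(np.where(finite, vals, 0.0))])
    vcnt = np.concatenate([[0.0], np.cumsum(finite.astype(float))])
    starts = np.arange(nw) * window.step
    ends = starts + window.length
    eff = vcnt[ends] - vcnt[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (vsum[ends] - vsum[starts]) / eff
    floor = int(np.ceil(window.min_occupancy * window.length))
    mean[eff < floor] = np.nan
    anchors = stream.start_time + starts + window.anchor_offset()
    return PVTrace(values=mean, anchor_times=anchors, window=window,
                   coords=stream.coords(), effective_n=eff)


def _check_aligned(a: Trace, b: Trace) -> None:
    if len(a) != len(b) or not np.array_equal(a.anchor_times, b.anchor_times):
        raise AlignmentError("traces are not on common anchors")


def ni_pv_correlation(ni: Trace, pv: Trace,
                      window: WindowSpec | str | None = "whole"):
    """Pearson correlation between aligned NI and EEG-PV traces.

    With ``window="whole"`` (default) returns one scalar r over all
    jointly finite points. With a :class:`WindowSpec`, emits a rolling r
    per step on the common anchors; windows with fewer than 3 joint points
    or zero variance in either input are NaN (masked, never fabricated).
    """
    _check_aligned(ni, pv)
    x = np.asarray(ni.values, float)
    y = np.asarray(pv.values, float)
    both = np.isfinite(x) & np.isfinite(y)

    if window is None or window == "whole":
        if both.sum() < 3:
            return np.nan
        xv, yv = x[both], y[both]
        if xv.std() == 0 or yv.std() == 0:
            return np.nan
        return float(np.corrcoef(xv, yv)[0, 1])

    sx = pd.Series(np.where(both, x, np.nan))
    sy = pd.Series(np.where(both, y, np.nan))
    roll = sx.rolling(window.length, min_periods=3)
    r = roll.corr(sy).to_numpy()
    # mask windows where either input is (numerically) constant
    vx = sx.rolling(window.length, min_periods=3).std().to_numpy()
    vy = sy.rolling(window.length, min_periods=3).std().to_numpy()
    with np.errstate(invalid="ignore"):
        r[(vx < 1e-12) | (vy < 1e-12)] = np.nan
        r = np.clip(r, -1.0, 1.0)
    # rolling emits one value per input index; keep full-window anchors at
    # the requested step
    idx = np.arange(window.length - 1, x.size, window.step)
    return Trace(values=r[idx], anchor_times=ni.anchor_times[idx],
                 window=window, coords=dict(ni.coords))


def correlation_map(ni_traces: Sequence[NITrace], pv_traces: Sequence[PVTrace],
                    scheme: RegionScheme | None = None,
                    granularity: str = "scalp",
                    window: WindowSpec | str | None = "whole"):
    """Correlate stratum-aggregated NI with stratum-aggregated EEG-PV.

    Streams are paired by (channel, bin_hz) coordinates, averaged within
    each stratum (aggregate-then-correlate), then correlated. Granularity
    "scalp" yields one series/scalar, "region" one per region,
    "region_frequency" one per (region, bin).
    """
    if len(ni_traces) != len(pv_traces):
        raise AlignmentError("need one PV trace per NI trace")
    pairs = {}
    pv_by_coord = {(t.coords.get("channel"), t.coords.get("bin_hz")): t
                   for t in pv_traces}
    for t in ni_traces:
        key = (t.coords.get("channel"), t.coords.get("bin_hz"))
        if key not in pv_by_coord:
            raise AlignmentError(f"no PV trace for stream {key}")
        pairs[key] = (t, pv_by_coord[key])

    scheme = scheme or RegionScheme()

    def stratum_of(key):
        ch, b = key
        if granularity == "scalp":
            return "scalp"
        if granularity == "region":
            return scheme.region_of(ch)
        if granularity == "region_frequency":
            reg = scheme.region_of(ch)
            return None if reg is None else (reg, b)
        raise ValueError(f"unknown granularity {granularity!r}")

    groups: dict = {}
    for key, pair in pairs.items():
        s = stratum_of(key)
        if s is None:
            continue
        groups.setdefault(s, []).append(pair)
    if not groups:
        raise StratumError(f"granularity {granularity!r} matched no streams")

    out = {}
    for s, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        ni0, pv0 = members[0]
        with np.errstate(invalid="ignore"):
            ni_mean = np.nanmean(np.vstack([a.values for a, _ in members]), 0)
            pv_mean = np.nanmean(np.vstack([b.values for _, b in members]), 0)
        agg_ni = Trace(values=ni_mean, anchor_times=ni0.anchor_times.copy(),
                       window=ni0.window, coords={"stratum": str(s)})
        agg_pv = Trace(values=pv_mean, anchor_times=pv0.anchor_times.copy(),
                       window=pv0.window, coords={"stratum": str(s)})
        out[s] = ni_pv_correlation(agg_ni, agg_pv, window=window)
    return out
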