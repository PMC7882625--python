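"""Synthetic symbol streams and raw EEG with known ground truth.

The generator emulates the one statistical feature the NI method detects:
intermittent *persistent activation/deactivation epochs* — stretches where
one power level dominates a (member, channel, 1-Hz bin) stream — embedded
in a disorganized baseline. Outside planted epochs symbols are i.i.d.
uniform over {-1, 1, 3} (or a sticky Markov chain); inside an epoch the
held symbol is emitted with probability ``hold_prob``, otherwise uniform.

``simulate_raw_eeg`` drives band-limited oscillators with three-level
amplitudes following the same symbol process, so the full
Welch -> symbolize -> NI path can be exercised end to end against the
planted truth. No attempt is made at biophysical realism (1/f spectra,
artifacts, volume conduction are out of scope).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .spectral import RawEEG
from .symbolize import SYMBOLS, SymbolStream

__all__ = ["PlantedEpoch", "SimConfig", "simulate_symbols", "simulate_raw_eeg"]

_SYMS = np.array(SYMBOLS, dtype=np.int8)


@dataclass(frozen=True)
class PlantedEpoch:
    """One persistent-organization episode planted in a target stream."""

    start: int              # s
    duration: int           # s
    member: str
    channel: str
    bin_hz: float
    held_symbol: int = 3
    hold_prob: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.hold_prob <= 1.0:
            raise ConfigurationError("hold_prob must be in (0, 1]")
        if self.held_symbol not in SYMBOLS:
            raise ConfigurationError("held_symbol must be one of -1, 1, 3")
        if self.duration <= 0 or self.start < 0:
            raise ConfigurationError("epoch must have start >= 0, duration > 0")

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic team performance.

    Defaults describe a dyad recorded on one sensor/one bin for 600 s with
    an i.i.d. uniform-thirds baseline (which makes the equal-occupancy
    assumption of the symbolization hold approximately by construction).
    ``member_coupling`` is the probability that a non-target member
    co-expresses a planted epoch (shared timing, independent emissions).
    A seed is mandatory: every run is exactly reproducible.
    """

    seed: int
    members: tuple[str, ...] = ("M1", "M2")
    channels: tuple[str, ...] = ("C3",)
    bins: tuple[float, ...] = (10.0,)
    duration_s: int = 600
    baseline: str = "uniform"          # "uniform" | "markov"
    markov_persistence: float = 0.0    # extra stay-probability, [0, 1)
    epochs: tuple[PlantedEpoch, ...] = ()
    member_coupling: float = 0.0
    snr: float = 10.0                  # signal-to-noise for raw-EEG synthesis

    def __post_init__(self) -> None:
        if self.baseline not in ("uniform", "markov"):
            raise ConfigurationError(f"unknown baseline {self.baseline!r}")
        for p, name in ((self.member_coupling, "member_coupling"),
                        (self.markov_persistence, "markov_persistence")):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.duration_s < 1:
            raise ConfigurationError("duration_s must be >= 1")
        # planted epochs within one stream must not overlap
        by_stream: dict = {}
        for e in self.epochs:
            if e.end > self.duration_s:
                raise ConfigurationError(
                    f"epoch [{e.start}, {e.end}) exceeds duration "
                    f"{self.duration_s}")
            key = (e.member, e.channel, e.bin_hz)
            for other in by_stream.get(key, []):
                if e.start < other.end and other.start < e.end:
                    raise ConfigurationError(
                        f"overlapping epochs on stream {key}")
            by_stream.setdefault(key, []).append(e)


def _baseline_symbols(rng: np.random.Generator, n: int, cfg: SimConfig
                      ) -> np.ndarray:
    if cfg.baseline == "uniform" or cfg.markov_persistence == 0.0:
        return _SYMS[rng.integers(0, 3, size=n)]
    stay = cfg.markov_persistence + (1 - cfg.markov_persistence) / 3
    out = np.empty(n, dtype=np.int8)
    state = rng.integers(0, 3)
    u = rng.random(n)
    jumps = rng.integers(0, 3, size=n)
    for t in range(n):
        if u[t] >= stay:
            state = jumps[t]
        out[t] = _SYMS[state]
    return out


def simulate_symbols(config: SimConfig
                     ) -> tuple[dict, pd.DataFrame]:
    """Generate member symbol streams plus the ground-truth epoch table.

    Returns ``(streams, truth)`` where ``streams`` maps
    (member, channel, bin_hz) -> :class:`SymbolStream` and ``truth`` lists
    every expressed epoch (including coupling-induced co-expressions) with
    columns member, channel, bin_hz, start_s, duration_s, held_symbol,
    hold_prob, coupled.
    """
    rng = np.random.default_rng(config.seed)
    n = config.duration_s

    # decide co-expression once per epoch per non-target member
    expressed: list[tuple[PlantedEpoch, str, bool]] = []
    for e in config.epochs:
        expressed.append((e, e.member, False))
        for m in config.members:
            if m == e.member:
                continue
            if config.member_coupling > 0 and \
                    rng.random() < config.member_coupling:
                expressed.append((e, m, True))

    streams: dict[tuple[str, str, float], SymbolStream] = {}
    truth_rows = []
    spans: dict = {}
    for e, m, coupled in expressed:
        key = (m, e.channel, e.bin_hz)
        # a co-expression that would overlap an existing epoch is dropped
        if any(e.start < b and a < e.end for a, b in spans.get(key, [])):
            continue
        spans.setdefault(key, []).append((e.start, e.end))
        truth_rows.append({"member": m, "channel": e.channel,
                           "bin_hz": e.bin_hz, "start_s": e.start,
                           "duration_s": e.duration,
                           "held_symbol": e.held_symbol,
                           "hold_prob": e.hold_prob, "coupled": coupled})

    epoch_by_stream: dict = {}
    for row in truth_rows:
        key = (row["member"], row["channel"], row["bin_hz"])
        epoch_by_stream.setdefault(key, []).append(row)

    for m in config.members:
        for ch in config.channels:
            for b in config.bins:
                syms = _baseline_symbols(rng, n, config)
                for row in epoch_by_stream.get((m, ch, b), []):
                    s0, s1 = row["start_s"], row["start_s"] + row["duration_s"]
                    hold = rng.random(s1 - s0) < row["hold_prob"]
                    syms[s0:s1] = np.where(
                        hold, np.int8(row["held_symbol"]),
                        _SYMS[rng.integers(0, 3, size=s1 - s0)])
                streams[(m, ch, b)] = SymbolStream(
                    symbols=syms, member=m, channel=ch, bin_hz=b)

    cols = ["member", "channel", "bin_hz", "start_s", "duration_s",
            "held_symbol", "hold_prob", "coupled"]
    truth = pd.DataFrame(truth_rows, columns=cols)
    return streams, truth


def simulate_raw_eeg(config: SimConfig, fs: float = 256.0,
                     amplitudes: tuple[float, float, float] = (2.0, 4.0, 8.0)
                     ) -> tuple[dict[str, RawEEG], dict, pd.DataFrame]:
    """Synthesize raw EEG whose band amplitudes follow the symbol process.

    Each (channel, bin) of each member carries a sinusoid at the bin
    frequency whose amplitude switches per second between three levels
    (``amplitudes``, mapped from symbols -1/1/3), plus white noise scaled
    so that mean signal power / noise power = ``config.snr``. Returns
    ``(raw_by_member, symbol_streams, truth)`` where the symbol streams
    are the planted level sequences the spectral pipeline should recover.
    """
    if config.snr <= 0:
        raise ConfigurationError("snr must be > 0")
    fmax = max(config.bins)
    if fs < 2 * fmax:
        raise ConfigurationError(f"fs = {fs} < 2 x max bin {fmax}")
    streams, truth = simulate_symbols(config)
    rng = np.random.default_rng(config.seed + 1)
    amp_of = {-1: amplitudes[0], 1: amplitudes[1], 3: amplitudes[2]}

    n_samp = int(round(config.duration_s * fs))
    tt = np.arange(n_samp) / fs
    raws: dict[str, RawEEG] = {}
    for m in config.members:
        data = np.zeros((len(config.channels), n_samp))
        for ci, ch in enumerate(config.channels):
            for b in config.bins:
                syms = streams[(m, ch, b)].symbols
                amp = np.repeat([amp_of[int(s)] for s in syms],
                                int(round(fs)))[:n_samp]
                phase = rng.uniform(0, 2 * np.pi)
                data[ci] += amp * np.sin(2 * np.pi * b * tt + phase)
        sig_power = float(np.mean(data ** 2))
        if sig_power > 0 and np.isfinite(config.snr):
            noise_sd = np.sqrt(sig_power / config.snr)
            data += rng.normal(0.0, noise_sd, size=data.shape)
        raws[m] = RawEEG(samples=data, fs=fs,
                         channel_labels=tuple(config.channels))
    return raws, streams, truth
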