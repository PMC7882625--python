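"""Per-second power spectral density of multi-channel EEG.

Converts cleaned raw EEG into the (time x channel x 1-Hz-bin) PSD tensor
the symbolization consumes: each 1-s epoch of each channel is reduced to
Welch PSD estimates integrated over forty 1-Hz bands (1-40 Hz). With the
default 1-s epoch and a single segment, Welch degenerates to a modified
(tapered) periodogram; 2-s segments stepped within longer epochs are
available for variance reduction.

This module assumes artifact-cleaned input; bad-channel rejection, line
noise removal and re-referencing are upstream concerns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError

__all__ = ["RawEEG", "PSDTensor", "welch_psd", "read_edf",
           "read_psd_table", "write_psd_table"]

logger = logging.getLogger(__name__)

DEFAULT_BINS = np.arange(1, 41)  # 1..40 Hz centre frequencies


@dataclass
class RawEEG:
    """Cleaned multi-channel EEG voltage (uV).

    ``samples`` is channels x time; NaN samples mark rejected stretches and
    propagate to masked PSD epochs. Sampling rate must support the highest
    analysis bin (>= 80 Hz for the default 1-40 Hz analysis).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ConfigurationError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class PSDTensor:
    """Per-second band power, axes (time s, channel, 1-Hz bin), uV^2/Hz
    integrated over each 1-Hz band (so entries are uV^2 per bin).

    NaN rows mark masked (dropped) epochs and propagate to masked symbols
    downstream, preserving time alignment.
    """

    values: np.ndarray
    channel_labels: tuple[str, ...]
    bins: np.ndarray = field(default_factory=lambda: DEFAULT_BINS.copy())
    epoch_length: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bins = np.asarray(self.bins, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.values.ndim != 3:
            raise ConfigurationError("PSD tensor must be 3-D (time, ch, bin)")
        nt, nc, nb = self.values.shape
        if nc != len(self.channel_labels) or nb != self.bins.size:
            raise ConfigurationError("tensor shape does not match labels/bins")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ConfigurationError("PSD values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def bin_index(self, bin_hz: float) -> int:
        idx = np.nonzero(self.bins == bin_hz)[0]
        if idx.size == 0:
            raise KeyError(f"no {bin_hz} Hz bin")
        return int(idx[0])


def welch_psd(raw: RawEEG, epoch_length: float = 1.0,
              segment_length: float | None = None, overlap: float = 0.5,
              window_taper: str = "hann",
              bins: np.ndarray | None = None) -> PSDTensor:
    """Welch PSD per epoch per channel, integrated over 1-Hz bands.

    Parameters
    ----------
    epoch_length : float
        Output cadence in seconds (one PSD row per epoch; default 1 s).
    segment_length : float, optional
        Welch segment length in seconds; defaults to ``epoch_length``
        (single segment, i.e. a modified periodogram per epoch).
    overlap : float
        Fractional overlap between Welch segments when more than one
        segment fits in an epoch.
    window_taper : str
        Any scipy.signal window name ("hann" default, "boxcar" for an
        untapered periodogram).
    bins : array, optional
        Band centre frequencies in Hz (default 1..40); each band spans
        centre +- 0.5 Hz and band power is density integrated over it.
    """
    bins = DEFAULT_BINS.copy() if bins is None else np.asarray(bins, float)
    fmax = float(bins.max())
    if raw.fs < 2 * fmax:
        raise ConfigurationError(
            f"fs = {raw.fs} Hz cannot resolve bins up to {fmax} Hz "
            f"(need >= {2 * fmax} Hz)")
    if segment_length is None:
        segment_length = epoch_length
    if epoch_length < segment_length:
        raise ConfigurationError("epoch_length must be >= segment_length")
    spe = int(round(epoch_length * raw.fs))
    nperseg = int(round(segment_length * raw.fs))
    if 1.0 / segment_length > 1.0:
        raise ConfigurationError(
            "segment shorter than 1 s cannot resolve 1-Hz bands")
    n_epochs = raw.samples.shape[1] // spe
    if n_epochs == 0:
        raise ConfigurationError("recording shorter than one epoch")

    x = raw.samples[:, :n_epochs * spe].reshape(raw.n_channels, n_epochs, spe)
    bad = ~np.isfinite(x).all(axis=2)  # (channel, epoch)
    x = np.where(np.isfinite(x), x, 0.0)
    noverlap = int(overlap * nperseg) if nperseg < spe else 0
    freqs, pxx = signal.welch(x, fs=raw.fs, window=window_taper,
                              nperseg=nperseg, noverlap=noverlap, axis=2,
                              detrend=False)
    df = freqs[1] - freqs[0]

    # integrate density over each 1-Hz band [c-0.5, c+0.5)
    values = np.empty((n_epochs, raw.n_channels, bins.size))
    for j, c in enumerate(bins):
        sel = (freqs >= c - 0.5) & (freqs < c + 0.5)
        values[:, :, j] = pxx[:, :, sel].sum(axis=2).T * df
    if bad.any():
        for ch, ep in zip(*np.nonzero(bad)):
            logger.warning("masked PSD epoch %d on channel %s", ep,
                           raw.channel_labels[ch])
        values[bad.T, :] = np.nan
    return PSDTensor(values=values, channel_labels=raw.channel_labels,
                     bins=bins, epoch_length=epoch_length,
                     start_time=raw.start_time)


def read_edf(path, channels: list[str] | None = None) -> RawEEG:
    """Load an EDF/BDF recording into a RawEEG (uV)."""
    import mne  # deferred: only needed for EDF input

    fn = str(path)
    reader = mne.io.read_raw_bdf if fn.lower().endswith(".bdf") \
        else mne.io.read_raw_edf
    rec = reader(fn, preload=True, verbose="error")
    if channels:
        rec.pick(channels)
    data = rec.get_data() * 1e6  # Volts -> uV
    return RawEEG(samples=data, fs=float(rec.info["sfreq"]),
                  channel_labels=tuple(rec.ch_names))


# ---------------------------------------------------------------------------
# delimited I/O: long format with columns time, channel, bin_hz, power

def write_psd_table(psd: PSDTensor, path) -> None:
    nt, nc, nb = psd.values.shape
    t = psd.start_time + np.arange(nt) * psd.epoch_length
    idx = pd.MultiIndex.from_product(
        [t, psd.channel_labels, psd.bins], names=["time", "channel", "bin_hz"])
    df = pd.DataFrame({"power": psd.values.ravel()}, index=idx).reset_index()
    df.to_csv(path, index=False)


def read_psd_table(path, epoch_length: float = 1.0) -> PSDTensor:
    df = pd.read_csv(path)
    times = np.sort(df["time"].unique())
    channels = tuple(sorted(df["channel"].unique()))
    bins = np.sort(df["bin_hz"].unique())
    pivot = df.set_index(["time", "channel", "bin_hz"])["power"]
    values = np.full((times.size, len(channels), bins.size), np.nan)
    for (t, ch, b), p in pivot.items():
        values[np.searchsorted(times, t), channels.index(ch),
               np.searchsorted(bins, b)] = p
    if times.size > 1:
        epoch_length = float(np.median(np.diff(times)))
    return PSDTensor(values=values, channel_labels=channels, bins=bins,
                     epoch_length=epoch_length, start_time=float(times[0]))
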