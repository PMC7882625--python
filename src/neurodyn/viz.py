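"""Optional figure export: time x frequency heatmaps and NI profile plots."""
from __future__ import annotations

from .pipeline import export_timefreq_map

__all__ = ["plot_timefreq", "plot_profile"]


def plot_timefreq(traces, title: str = "", cmap: str = "viridis",
                  path=None, ax=None):
    """Heatmap of NI (or EEG-PV) across time and 1-Hz frequency bins."""
    import matplotlib.pyplot as plt

    df = export_timefreq_map(traces)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    mesh = ax.pcolormesh(df.columns.to_numpy(float), df.index.to_numpy(float),
                         df.to_numpy(), cmap=cmap, shading="nearest")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(mesh, ax=ax, label="bits")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_profile(trace, peaks=(), title: str = "", path=None, ax=None):
    """NI trace over time with detected peaks and their half-prominence
    intervals marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    ax.plot(trace.anchor_times, trace.values, lw=1)
    for p in peaks:
        ax.axvspan(p.left_edge, p.right_edge, alpha=0.2, color="tab:orange")
        ax.plot([p.anchor_time], [p.magnitude], "v", color="tab:red", ms=5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("NI (bits)")
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
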