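"""End-to-end orchestration: symbols -> NI/PV -> correlations -> peaks.

Implements the drill-down workflow of the method: compute team and member
NI for every (channel, 1-Hz bin) stream, subtract randomized baselines,
derive EEG-PV traces and their correlations with NI, detect peaks, and
summarize incidence — then aggregate to scalp / sensor / frequency level.
All outputs are delimited tables plus a JSON manifest that fully
reproduces the run (config, seed, config hash, package version).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import AlignmentError, ConfigurationError
from .neurodynamics import (NITrace, aggregate_ni, ni_trace,
                            randomized_baseline, shared_information,
                            subtract_baseline)
from .peaks import detect_peaks, incidence, peaks_to_frame
from .power_values import (DEFAULT_REGIONS, RegionScheme, correlation_map,
                           eeg_pv, ni_pv_correlation)
from .symbolize import compose_team, read_symbol_table, write_symbol_table
from .synthetic import PlantedEpoch, SimConfig, simulate_symbols
from .windows import WindowSpec

__all__ = ["RunConfig", "run_pipeline", "export_timefreq_map",
           "read_timefreq_map"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str
    symbols_path: str | None = None      # long-format symbol table, or --
    simulate: dict | None = None         # -- SimConfig fields to synthesize
    window_length_s: int = 60
    window_step_s: int = 1
    n_shuffles: int = 6
    seed: int = 0
    min_prominence_bits: float = 0.1
    min_height_bits: float = 0.0
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    aggregation_levels: tuple[str, ...] = ("scalp", "sensor", "frequency")

    def __post_init__(self) -> None:
        if (self.symbols_path is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of symbols_path / simulate must be given")
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")
        if self.min_prominence_bits <= 0:
            raise ConfigurationError("min_prominence_bits must be > 0")
        self.window()  # validates

    def window(self) -> WindowSpec:
        return WindowSpec(length=self.window_length_s, step=self.window_step_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aggregation_levels"] = list(self.aggregation_levels)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sim_config(spec: dict, seed: int) -> SimConfig:
    spec = dict(spec)
    epochs = tuple(PlantedEpoch(**e) for e in spec.pop("epochs", ()))
    for key in ("members", "channels", "bins"):
        if key in spec:
            spec[key] = tuple(spec[key])
    spec.setdefault("seed", seed)
    return SimConfig(epochs=epochs, **spec)


def _trace_frame(traces: list[NITrace]) -> pd.DataFrame:
    frames = []
    for t in traces:
        df = pd.DataFrame({
            "time": t.anchor_times,
            "member": t.coords.get("member", ""),
            "channel": t.coords.get("channel", ""),
            "bin_hz": t.coords.get("bin_hz", ""),
            "ni_bits": t.baseline + t.values if t.corrected else t.values,
            "baseline_bits": t.baseline if t.baseline is not None else np.nan,
            "corrected_bits": t.values if t.corrected else np.nan,
        })
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Returns a dict of the in-memory results (streams, traces, peaks,
    summary tables) keyed by output name. Identical config + seed yields
    byte-identical output tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = config.window()

    # ------------------------------------------------------------------ input
    if config.simulate is not None:
        sim = _sim_config(config.simulate, config.seed)
        streams_by_key, truth = simulate_symbols(sim)
        streams = list(streams_by_key.values())
        truth.to_csv(out / "ground_truth.csv", index=False)
        write_symbol_table(streams, out / "symbols.csv")
    else:
        streams = read_symbol_table(config.symbols_path)
    members = sorted({s.member for s in streams})
    logger.info("loaded %d streams, members: %s", len(streams), members)

    # one deterministic child seed per (stream kind, coordinates)
    def child_seed(tag: str) -> int:
        h = int(hashlib.sha256(
            f"{config.seed}:{tag}".encode()).hexdigest()[:8], 16)
        return h % (2 ** 31)

    # -------------------------------------------------------------- NI traces
    member_traces: list[NITrace] = []
    failed = 0
    for s in streams:
        tag = f"m:{s.member}:{s.channel}:{s.bin_hz}"
        try:
            raw = ni_trace(s, window)
            base = randomized_baseline(s, window, config.n_shuffles,
                                       seed=child_seed(tag))
            member_traces.append(subtract_baseline(raw, base))
        except AlignmentError as exc:   # too short etc.: logged, not dropped
            failed += 1
            logger.warning("stream %s failed: %s", tag, exc)
    if failed:
        logger.warning("%d stream(s) failed and were masked", failed)

    by_coord: dict = {}
    for s in streams:
        by_coord.setdefault((s.channel, s.bin_hz), {})[s.member] = s

    team_traces: list[NITrace] = []
    mi_rows = []
    if len(members) >= 2:
        for (ch, b), d in sorted(by_coord.items()):
            if len(d) != len(members):
                continue
            team = compose_team([d[m] for m in members])
            tag = f"t:{ch}:{b}"
            raw = ni_trace(team, window)
            base = randomized_baseline(team, window, config.n_shuffles,
                                       seed=child_seed(tag))
            team_traces.append(subtract_baseline(raw, base))
            if len(members) == 2:
                mi = shared_information([d[m] for m in members], window)
                mi_rows.append(pd.DataFrame({
                    "time": mi.anchor_times, "channel": ch, "bin_hz": b,
                    "mi_bits": mi.values}))

    # ------------------------------------------------------------------ EEG-PV
    pv_traces = [eeg_pv(s, window) for s in streams]

    corr_rows = []
    pv_by_key = {(p.coords["member"], p.coords["channel"],
                  p.coords["bin_hz"]): p for p in pv_traces}
    for t in member_traces:
        key = (t.coords["member"], t.coords["channel"], t.coords["bin_hz"])
        r = ni_pv_correlation(t, pv_by_key[key], window="whole")
        corr_rows.append({"member": key[0], "channel": key[1],
                          "bin_hz": key[2], "r": r})

    scheme = RegionScheme(mapping=config.regions)
    region_corr = {}
    for m in members:
        m_ni = [t for t in member_traces if t.coords["member"] == m]
        m_pv = [p for p in pv_traces if p.coords["member"] == m]
        if m_ni:
            try:
                region_corr[m] = correlation_map(m_ni, m_pv, scheme,
                                                 granularity="region")
            except Exception as exc:
                logger.warning("region map for %s skipped: %s", m, exc)

    # ------------------------------------------------------------------ peaks
    peak_input = team_traces if team_traces else member_traces
    peaks_by_stream = [detect_peaks(t, config.min_prominence_bits,
                                    config.min_height_bits)
                       for t in peak_input]
    member_peaks = [detect_peaks(t, config.min_prominence_bits,
                                 config.min_height_bits)
                    for t in member_traces]
    inc = incidence(member_peaks, member_traces)

    # ------------------------------------------------------------- aggregates
    agg_rows = []
    for level in config.aggregation_levels:
        try:
            res = aggregate_ni(member_traces, level=level,
                               scheme=config.regions
                               if level == "region" else None)
        except Exception as exc:
            logger.warning("aggregation level %r skipped: %s", level, exc)
            continue
        res = {"scalp": res} if isinstance(res, NITrace) else res
        for stratum, tr in res.items():
            agg_rows.append(pd.DataFrame({
                "time": tr.anchor_times, "level": level, "stratum": stratum,
                "ni_bits": tr.values}))

    # ----------------------------------------------------------------- output
    _trace_frame(member_traces).to_csv(out / "ni_member.csv", index=False)
    if team_traces:
        _trace_frame(team_traces).to_csv(out / "ni_team.csv", index=False)
    if mi_rows:
        pd.concat(mi_rows, ignore_index=True).to_csv(
            out / "shared_information.csv", index=False)
    pv_frame = pd.concat([
        pd.DataFrame({"time": p.anchor_times,
                      "member": p.coords["member"],
                      "channel": p.coords["channel"],
                      "bin_hz": p.coords["bin_hz"],
                      "pv": p.values}) for p in pv_traces],
        ignore_index=True)
    pv_frame.to_csv(out / "pv.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(out / "ni_pv_correlation.csv", index=False)
    all_peaks = [p for plist in peaks_by_stream for p in plist]
    peaks_to_frame(all_peaks).to_csv(out / "peaks.csv", index=False)
    pd.DataFrame([{"total_epochs": inc.total_epochs,
                   "epochs_in_peaks": inc.epochs_in_peaks,
                   "fraction": round(inc.fraction, 2),
                   "percent": round(inc.percent, 2)}]).to_csv(
        out / "incidence.csv", index=False)
    if agg_rows:
        pd.concat(agg_rows, ignore_index=True).to_csv(
            out / "ni_aggregated.csv", index=False)

    manifest = {
        "package": "neurodyn", "version": __version__,
        "seed": config.seed, "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "n_streams": len(streams), "n_members": len(members),
        "n_failed_streams": failed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"streams": streams, "member_traces": member_traces,
            "team_traces": team_traces, "pv_traces": pv_traces,
            "peaks": peaks_by_stream, "incidence": inc,
            "region_correlation": region_corr, "manifest": manifest}


def export_timefreq_map(traces, path=None) -> pd.DataFrame:
    """Stack one member/sensor's per-bin traces into a time x frequency
    matrix (rows = ascending 1-Hz bins, columns = anchor seconds).

    Suitable for heatmap rendering; written as CSV when ``path`` is given.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to export")
    anchors = traces[0].anchor_times
    for t in traces[1:]:
        if not np.array_equal(t.anchor_times, anchors):
            raise AlignmentError("traces must share cadence and anchors")
    rows = sorted(traces, key=lambda t: float(t.coords.get("bin_hz", 0)))
    df = pd.DataFrame(
        np.vstack([t.values for t in rows]),
        index=pd.Index([float(t.coords.get("bin_hz", 0)) for t in rows],
                       name="bin_hz"),
        columns=anchors)
    if path is not None:
        df.to_csv(path)
    return df


def read_timefreq_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="bin_hz")
    df.columns = df.columns.astype(float)
    return df
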