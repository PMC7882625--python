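"""Ternary symbolization of per-second EEG band power and composition of
team symbol streams.

Each second, the band power of one (member, channel, 1-Hz bin) stream is
labelled high (3), average (1), or low (-1) relative to the *whole
performance*: the empirical tertiles of the full power sequence define the
cuts, so each symbol labels one third of the epochs (equal occupancy).
Equal occupancy is what makes Shannon entropy comparable across streams —
every stream has the same maximum-entropy reference distribution.

Member symbols are combined per second into a composite team symbol over
the 3^k-state team space (9 labels for a dyad, 27 for a triad) using a
lexicographic base-3 encoding in declared member order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError

__all__ = [
    "SYMBOLS",
    "SymbolStream",
    "TeamStream",
    "symbolize_stream",
    "compose_team",
    "decode_team",
    "read_symbol_table",
    "write_symbol_table",
]

#: the ternary alphabet: low, average, high power
SYMBOLS = (-1, 1, 3)

_SYMBOL_TO_RANK = {-1: 0, 1: 1, 3: 2}
_RANK_TO_SYMBOL = np.array([-1, 1, 3], dtype=np.int8)


@dataclass
class SymbolStream:
    """Per-second ternary symbols for one (member, channel, bin) stream.

    ``symbols`` take values in {-1, 1, 3}; ``mask`` is True where the epoch
    is valid (False epochs came from masked PSD rows and propagate as
    masked downstream). ``boundaries`` records the two power cut points
    (uV^2/Hz) separating low/average and average/high.
    """

    symbols: np.ndarray
    member: str = ""
    channel: str = ""
    bin_hz: float = 0.0
    mask: np.ndarray | None = None
    boundaries: tuple[float, float] | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.symbols.shape:
                raise AlignmentError("mask and symbols must share shape")
        bad = np.setdiff1d(np.unique(self.symbols[self.valid]), SYMBOLS)
        if bad.size:
            raise ValueError(f"symbols outside {{-1, 1, 3}}: {bad.tolist()}")

    @property
    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.symbols.shape, dtype=bool)
        return self.mask

    @property
    def n_epochs(self) -> int:
        return int(self.symbols.size)

    def codes(self) -> np.ndarray:
        """Symbols mapped to contiguous codes 0, 1, 2 (masked -> -1)."""
        out = np.full(self.symbols.shape, -1, dtype=np.int64)
        v = self.valid
        out[v] = (self.symbols[v] + 1) // 2  # -1->0, 1->1, 3->2
        return out

    def values(self) -> np.ndarray:
        """Numeric reading of the symbols (floats, masked -> NaN)."""
        out = self.symbols.astype(float)
        out[~self.valid] = np.nan
        return out

    def coords(self) -> dict:
        return {"member": self.member, "channel": self.channel,
                "bin_hz": self.bin_hz}


@dataclass
class TeamStream:
    """Composite per-second team symbols over the 3^k team state space.

    Labels run 1..3^k. ``encoding`` documents the tuple -> label bijection:
    label = 1 + sum_i rank(symbol_i) * 3^(k-1-i) with rank -1->0, 1->1,
    3->2, members in declared order (first member most significant).
    """

    symbols: np.ndarray
    member_ids: tuple[str, ...]
    channel: str = ""
    bin_hz: float = 0.0
    mask: np.ndarray | None = None
    start_time: float = 0.0
    encoding: str = field(
        default="label = 1 + sum_i rank(s_i)*3^(k-1-i); rank: -1->0, 1->1, 3->2",
    )

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.member_ids = tuple(self.member_ids)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
        v = self.valid
        if v.any() and (self.symbols[v].min() < 1
                        or self.symbols[v].max() > self.n_states):
            raise ValueError(f"team labels must lie in 1..{self.n_states}")

    @property
    def k(self) -> int:
        return len(self.member_ids)

    @property
    def n_states(self) -> int:
        return 3 ** self.k

    @property
    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.symbols.shape, dtype=bool)
        return self.mask

    @property
    def n_epochs(self) -> int:
        return int(self.symbols.size)

    def codes(self) -> np.ndarray:
        """Labels mapped to 0..3^k-1 (masked -> -1)."""
        out = np.full(self.symbols.shape, -1, dtype=np.int64)
        v = self.valid
        out[v] = self.symbols[v] - 1
        return out

    def coords(self) -> dict:
        return {"member": "+".join(self.member_ids), "channel": self.channel,
                "bin_hz": self.bin_hz}


def symbolize_stream(
    power: Sequence[float] | np.ndarray,
    mask: np.ndarray | None = None,
    member: str = "",
    channel: str = "",
    bin_hz: float = 0.0,
    start_time: float = 0.0,
) -> SymbolStream:
    """Discretize a per-epoch power sequence into equal-occupancy tertiles.

    The cuts are rank-based over the full unmasked sequence: the lowest
    third of epochs (by power, ties broken by time index) receives -1, the
    middle third 1, the top third 3, so the three symbol counts differ
    pairwise by at most one *exactly*, for any input. Symbolization is
    therefore invariant under any strictly increasing transform of power.

    Raises
    ------
    DegenerateInputError
        If all unmasked values are identical: power carries no ordering, so
        three power levels cannot be distinguished.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 1:
        raise ValueError("power must be 1-D")
    valid = np.isfinite(power)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n_valid = int(valid.sum())
    coord_msg = f"member={member!r} channel={channel!r} bin={bin_hz} Hz"
    if n_valid < 3:
        raise DegenerateInputError(
            f"need >= 3 unmasked epochs to form tertiles ({coord_msg})")
    vals = power[valid]
    if np.all(vals == vals[0]):
        raise DegenerateInputError(
            f"all power values identical; cannot separate three levels "
            f"({coord_msg})")

    order = np.argsort(vals, kind="stable")  # stable: ties broken by time
    base, rem = divmod(n_valid, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    ranks = np.empty(n_valid, dtype=np.int8)
    lo, mid = sizes[0], sizes[0] + sizes[1]
    ranks[order[:lo]] = 0
    ranks[order[lo:mid]] = 1
    ranks[order[mid:]] = 2
    boundaries = (float(vals[order[lo - 1]]), float(vals[order[mid - 1]]))

    symbols = np.ones(power.shape, dtype=np.int8)
    symbols[valid] = _RANK_TO_SYMBOL[ranks]
    out_mask = valid if (mask is not None or not valid.all()) else None
    return SymbolStream(symbols=symbols, member=member, channel=channel,
                        bin_hz=bin_hz, mask=out_mask, boundaries=boundaries,
                        start_time=start_time)


def compose_team(members: Sequence[SymbolStream]) -> TeamStream:
    """Combine aligned member streams into a composite team stream.

    Masked epochs in any member mask the composite epoch (intersection
    semantics). Members must share channel, bin, and length.
    """
    k = len(members)
    if not 1 <= k <= 3:
        raise ValueError("team size must be 1..3 members")
    first = members[0]
    for m in members[1:]:
        if (m.channel, m.bin_hz) != (first.channel, first.bin_hz):
            raise AlignmentError(
                f"member streams on different coordinates: "
                f"{m.coords()} vs {first.coords()}")
        if m.n_epochs != first.n_epochs or m.start_time != first.start_time:
            raise AlignmentError("member streams differ in length or origin")

    valid = np.logical_and.reduce([m.valid for m in members])
    labels = np.ones(first.n_epochs, dtype=np.int64)
    acc = np.zeros(first.n_epochs, dtype=np.int64)
    for i, m in enumerate(members):
        rank = (m.symbols.astype(np.int64) + 1) // 2
        acc += rank * 3 ** (k - 1 - i)
    labels = 1 + acc
    labels[~valid] = 1  # placeholder under mask
    mask = None if valid.all() else valid
    return TeamStream(symbols=labels, member_ids=tuple(m.member for m in members),
                      channel=first.channel, bin_hz=first.bin_hz, mask=mask,
                      start_time=first.start_time)


def decode_team(team: TeamStream) -> list[SymbolStream]:
    """Invert :func:`compose_team`: recover each member's ternary stream."""
    k = team.k
    rem = team.symbols - 1
    out: list[SymbolStream] = []
    mask = None if team.mask is None else team.mask.copy()
    for i in range(k):
        rank = (rem // 3 ** (k - 1 - i)) % 3
        syms = _RANK_TO_SYMBOL[rank]
        if mask is not None:
            syms = syms.copy()
            syms[~mask] = 1
        out.append(SymbolStream(symbols=syms, member=team.member_ids[i],
                                channel=team.channel, bin_hz=team.bin_hz,
                                mask=mask, start_time=team.start_time))
    return out


# ---------------------------------------------------------------------------
# delimited I/O: long format with columns time, member, channel, bin_hz, symbol

def write_symbol_table(streams: Sequence[SymbolStream], path) -> None:
    frames = []
    for s in streams:
        t = s.start_time + np.arange(s.n_epochs)
        df = pd.DataFrame({
            "time": t, "member": s.member, "channel": s.channel,
            "bin_hz": s.bin_hz, "symbol": s.symbols.astype(int),
            "valid": s.valid.astype(int),
        })
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_symbol_table(path) -> list[SymbolStream]:
    df = pd.read_csv(path)
    streams = []
    for (member, channel, bin_hz), g in df.groupby(
            ["member", "channel", "bin_hz"], sort=True):
        g = g.sort_values("time")
        valid = g["valid"].to_numpy(dtype=bool) if "valid" in g else None
        if valid is not None and valid.all():
            valid = None
        streams.append(SymbolStream(
            symbols=g["symbol"].to_numpy(), member=str(member),
            channel=str(channel), bin_hz=float(bin_hz), mask=valid,
            start_time=float(g["time"].iloc[0])))
    return streams
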