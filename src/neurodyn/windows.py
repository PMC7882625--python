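"""Sliding-window specification shared by the entropy, power-value and
correlation engines.

The analysis cadence of the method is one emitted value per step (default
1 s) from a window of `length` seconds (default 60 s), anchored at the
window's final second (trailing alignment), so the first value appears once
one full window of data exists.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["WindowSpec"]


@dataclass(frozen=True)
class WindowSpec:
    """A sliding analysis window.

    Parameters
    ----------
    length : int
        Window length in seconds (number of 1-s epochs per window).
    step : int
        Seconds between successive emitted values.
    alignment : {"trailing", "centered"}
        Where the emitted value is anchored relative to the window.
    min_occupancy : float
        Minimum fraction of unmasked epochs a window must contain for a
        value to be emitted; windows below the floor yield NaN.
    """

    length: int = 60
    step: int = 1
    alignment: str = "trailing"
    min_occupancy: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("window length must be >= 1 s")
        if self.step < 1:
            raise ValueError("window step must be >= 1 s")
        if self.alignment not in ("trailing", "centered"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if not 0.0 < self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in (0, 1]")

    def check_alphabet(self, n_symbols: int) -> None:
        """Validate the window against an alphabet size.

        Windowed plug-in entropy needs at least as many observations as
        symbols to be able to reach the uniform distribution; below five
        observations per symbol the estimator bias is severe.
        """
        if self.length < n_symbols:
            raise ValueError(
                f"window length {self.length} < alphabet size {n_symbols}"
            )
        if self.length < 5 * n_symbols:
            warnings.warn(
                f"window length {self.length} < 5x alphabet size {n_symbols}: "
                "plug-in entropy estimates will carry heavy small-sample bias",
                stacklevel=3,
            )

    def anchor_offset(self) -> int:
        """Index offset of the anchor within each window."""
        if self.alignment == "trailing":
            return self.length - 1
        return self.length // 2

    def n_windows(self, n: int) -> int:
        """Number of windows emitted from a stream of ``n`` epochs."""
        if n < self.length:
            return 0
        return (n - self.length) // self.step + 1
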