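"""Stimulus-aligned trial extraction.

For every stimulus onset t_i three 2-ms detection windows are placed on the
upstream and downstream spike trains: Z (pre-stimulus, upstream), X (during
stimulus, upstream) and Y (post-stimulus, downstream).  Each variable is 1
when at least one spike of the designated neuron falls inside its window.
Starred variables (X*, Y*) use the same windows shifted one window width
backward in time, the reference periods of the difference-in-differences
correction.

Windows are half-open ``[t_i + offset, t_i + offset + width)`` so that with
the default offsets (-2, 0, 2) and width 2 the Z/X/Y windows tile the ms
axis without overlap, and X* coincides exactly with Z.  Because a spike 1-2
ms before onset (Z = 1) leaves the neuron absolutely refractory throughout
the X window, Z = 1 forces X = 0: refractoriness acts as the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WindowSpec", "TrialTable", "extract_trials"]


@dataclass(frozen=True)
class WindowSpec:
    """Offsets (ms, relative to onset) and common width of the Z/X/Y windows."""

    z_offset: int = -2
    x_offset: int = 0
    y_offset: int = 2
    width: int = 2

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    def bounds(self, var: str) -> tuple[int, int]:
        """Half-open [start, stop) offsets for Z, X, Y, Xstar or Ystar."""
        base = {"Z": self.z_offset, "X": self.x_offset, "Y": self.y_offset}
        if var in base:
            a = base[var]
        elif var in ("Xstar", "Ystar"):
            a = base[var[0]] - self.width
        else:
            raise KeyError(var)
        return a, a + self.width

    def margins(self) -> tuple[int, int]:
        """(left, right) margin in ms needed inside the raster around an onset."""
        starts, stops = zip(*(self.bounds(v) for v in
                              ("Z", "X", "Y", "Xstar", "Ystar")))
        return -min(starts), max(stops)


@dataclass
class TrialTable:
    """Per-trial binary variables for one upstream/downstream pair."""

    Z: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Xstar: np.ndarray
    Ystar: np.ndarray
    upstream_id: int = 0
    downstream_id: int = 1
    onset_times: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=np.int8)
                for a in (self.Z, self.X, self.Y, self.Xstar, self.Ystar)]
        sizes = {a.size for a in arrs}
        if len(sizes) != 1:
            raise ValueError("all trial variables must have equal length")
        for a in arrs:
            if a.size and not np.isin(a, (0, 1)).all():
                raise ValueError("trial variables must be binary")
        self.Z, self.X, self.Y, self.Xstar, self.Ystar = arrs

    def __len__(self):
        return int(self.Z.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"Z": self.Z, "X": self.X, "Y": self.Y,
             "Xstar": self.Xstar, "Ystar": self.Ystar}
        )


def _window_hits(indicator: np.ndarray, onsets: np.ndarray,
                 start: int, stop: int) -> np.ndarray:
    """1 where the neuron spiked in [onset+start, onset+stop)."""
    cum = np.concatenate([[0], np.cumsum(indicator, dtype=np.int64)])
    return (cum[onsets + stop] - cum[onsets + start] > 0).astype(np.int8)


def extract_trials(
    raster,
    onsets,
    windows: WindowSpec,
    upstream_id: int,
    downstream_id: int,
) -> TrialTable:
    """Build the Z/X/Y/X*/Y* trial table for one neuron pair.

    Onsets whose windows would cross the raster boundary are dropped (not
    clipped); the count is reported on the returned table.
    """
    if upstream_id == downstream_id:
        raise ValueError("upstream and downstream neurons must differ")
    times = np.asarray(
        getattr(onsets, "onset_times", onsets), dtype=np.int64
    ) - raster.t0
    left, right = windows.margins()
    keep = (times >= left) & (times + right <= raster.n_steps)
    n_dropped = int(times.size - keep.sum())
    times = times[keep]

    up = raster.spikes[upstream_id]
    down = raster.spikes[downstream_id]
    cols = {}
    for var, tr in (("Z", up), ("X", up), ("Xstar", up),
                    ("Y", down), ("Ystar", down)):
        a, b = windows.bounds(var)
        cols[var] = _window_hits(tr, times, a, b)
    return TrialTable(
        Z=cols["Z"], X=cols["X"], Y=cols["Y"],
        Xstar=cols["Xstar"], Ystar=cols["Ystar"],
        upstream_id=upstream_id, downstream_id=downstream_id,
        onset_times=times + raster.t0, n_dropped=n_dropped,
    )
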