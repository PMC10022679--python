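"""Intensity projections: collapse each 3D time point to a 2D image.

Lateral drift is estimated on z-projections (shape ``T, Y, X``); axial drift
on y-projections (shape ``T, Z, X``, rows = z so the row component of an
estimated shift is directly dz).  Average projections are computed in
floating point to avoid quantization bias at low signal-to-noise ratio,
where they are the recommended mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VideoStack, as_video_stack

__all__ = ["ProjectionSeries", "project_series", "time_window_average"]

_AXIS_INDEX = {"z": 1, "y": 2}  # within the canonical T,Z,Y,X order
_ROW_COL = {"z": ("y", "x"), "y": ("z", "x")}


@dataclass
class ProjectionSeries:
    """T 2D images obtained by projecting each time point along one axis."""

    frames: np.ndarray  # (T, rows, cols)
    axis: str  # projected axis: 'z' or 'y'
    method: str  # 'max' or 'average'
    row_meaning: str  # original axis the 2D rows correspond to
    col_meaning: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def project_series(stack: VideoStack, axis: str, method: str) -> ProjectionSeries:
    """Reduce every time point over `axis` ('z' or 'y') with `method`
    ('max' or 'average'); no other processing is applied.

    Frames are reduced one at a time, so a memory-mapped stack never needs
    to be resident in full.
    """
    stack = as_video_stack(stack)
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be 'z' or 'y', got {axis!r}")
    if method not in ("max", "average"):
        raise ValueError(f"method must be 'max' or 'average', got {method!r}")
    ax = _AXIS_INDEX[axis] - 1  # within a single (Z, Y, X) frame
    out = None
    for t in range(stack.n_frames):
        frame = np.asarray(stack.data[t])
        proj = frame.max(axis=ax) if method == "max" else frame.mean(
            axis=ax, dtype=np.float64
        )
        if out is None:
            out = np.empty((stack.n_frames,) + proj.shape, dtype=proj.dtype)
        out[t] = proj
    row, col = _ROW_COL[axis]
    return ProjectionSeries(out, axis=axis, method=method, row_meaning=row, col_meaning=col)


def time_window_average(series: ProjectionSeries, window: int) -> ProjectionSeries:
    """Replace each frame by the running mean of `window` frames centered on
    it (window truncated at the sequence boundaries).  ``window=1`` is the
    identity.  Pre-smoothing option for very noisy videos."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return series
    half = window // 2
    frames = series.frames.astype(np.float64, copy=False)
    t = series.n_frames
    out = np.empty_like(frames)
    for i in range(t):
        lo, hi = max(0, i - half), min(t, i + half + 1)
        out[i] = frames[lo:hi].mean(axis=0)
    return ProjectionSeries(
        out,
        axis=series.axis,
        method=series.method,
        row_meaning=series.row_meaning,
        col_meaning=series.col_meaning,
    )
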