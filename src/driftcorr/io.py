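"""Reading and writing of video stacks, drift tables, settings and drift plots.

The on-disk contract used by the rest of the package:

* stacks — multi-page TIFF with axis metadata, canonical in-memory order
  ``T, Z, Y, X`` (channels are never stored inside a :class:`VideoStack`;
  multichannel files must be split into one stack per channel at load),
* drift tables — CSV with header ``frame,dx_px,dy_px,dz_slices``, one row per
  frame, cumulative shifts relative to frame 0,
* settings — JSON,
* drift plots — PNG.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VideoStack",
    "DriftTable",
    "RegistrationSettings",
    "load_stack",
    "save_stack",
    "read_drift_table",
    "write_drift_table",
    "read_settings",
    "write_settings",
    "write_drift_plot",
]

DRIFT_TABLE_COLUMNS = ("frame", "dx_px", "dy_px", "dz_slices")


class DriftTableError(ValueError):
    """Raised for a malformed drift table (file or in-memory)."""


@dataclass
class VideoStack:
    """A single-channel video stack in canonical ``T, Z, Y, X`` order.

    ``Z`` extent may be 1 for plain 2D videos.  Pixel sizes are optional
    provenance metadata (µm per pixel laterally, µm per slice axially) and are
    carried through save/load round trips.
    """

    data: np.ndarray
    pixel_size_xy: float | None = None
    z_step: float | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"VideoStack data must be 4-dimensional (T, Z, Y, X); "
                f"got shape {self.data.shape}"
            )
        if self.height < 2 or self.width < 2:
            raise ValueError("VideoStack frames must be at least 2x2 pixels")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("VideoStack intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def height(self) -> int:
        return self.data.shape[2]

    @property
    def width(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> np.ndarray:
        """The ``(Z, Y, X)`` volume at time point ``t``."""
        return self.data[t]

    def with_data(self, data: np.ndarray) -> "VideoStack":
        return VideoStack(
            data,
            pixel_size_xy=self.pixel_size_xy,
            z_step=self.z_step,
            source_path=self.source_path,
        )


def as_video_stack(x) -> VideoStack:
    """Coerce an array-like into a :class:`VideoStack`.

    3D input is interpreted as a 2D video ``(T, Y, X)`` and gains a singleton
    Z axis; 2D input as a single 2D image.
    """
    if isinstance(x, VideoStack):
        return x
    a = np.asarray(x)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    elif a.ndim != 4:
        raise ValueError(f"cannot interpret array of shape {a.shape} as a video stack")
    return VideoStack(a)


@dataclass
class DriftTable:
    """Per-frame cumulative drift relative to frame 0.

    ``dx``/``dy`` are in pixels, ``dz`` in slices.  Row 0 is always
    ``(0, 0, 0)``: frame 0 is the fixed anchor of the video.
    """

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.dz = np.asarray(self.dz, dtype=float)
        n = len(self.dx)
        if not (len(self.dy) == len(self.dz) == n) or n < 1:
            raise DriftTableError("dx, dy, dz must be equal-length, non-empty")
        for name, v in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not np.all(np.isfinite(v)):
                raise DriftTableError(f"{name} contains non-finite values")
        if not (self.dx[0] == 0 and self.dy[0] == 0 and self.dz[0] == 0):
            raise DriftTableError("drift table row 0 must be (0, 0, 0)")

    @property
    def n_frames(self) -> int:
        return len(self.dx)

    @classmethod
    def zeros(cls, n_frames: int) -> "DriftTable":
        z = np.zeros(n_frames)
        return cls(z.copy(), z.copy(), z.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "dx_px": self.dx,
                "dy_px": self.dy,
                "dz_slices": self.dz,
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DriftTable):
            return NotImplemented
        return (
            np.array_equal(self.dx, other.dx)
            and np.array_equal(self.dy, other.dy)
            and np.array_equal(self.dz, other.dz)
        )

    def max_abs(self) -> tuple[float, float, float]:
        """Largest absolute (dx, dy, dz) over all frames."""
        return (
            float(np.max(np.abs(self.dx))),
            float(np.max(np.abs(self.dy))),
            float(np.max(np.abs(self.dz))),
        )


@dataclass
class RegistrationSettings:
    """Every tunable of a registration run; serializable alongside the table.

    Parameters
    ----------
    projection_method:
        Intensity statistic used for the per-frame projections, ``"max"`` or
        ``"average"``.  Average projections are recommended for noisy data.
    reference_mode:
        ``"first_frame"`` compares every frame against frame 0 (static
        scenes); ``"previous_frame"`` compares consecutive frames and
        cumulates the pairwise shifts (evolving scenes).
    upscale_factor:
        Integer densification of the cross-correlation matrix; nominal shift
        precision is ``1 / upscale_factor`` pixels.
    max_shift:
        Bound (pixels) on the allowed shift magnitude per axis, or ``None``
        for unbounded search.
    time_window:
        Odd number of projection frames averaged (running mean) before
        estimation; 1 disables the smoothing.
    edge_mode:
        ``"zero_fill"`` keeps the frame shape and fills vacated pixels with
        zeros; ``"crop"`` trims every frame to the common valid region.
    axes_corrected:
        Subset of ``{"lateral", "axial"}`` to estimate and correct.
    drift_table_path:
        Path of a previously written drift table, allowing a settings file
        alone to re-apply a correction to another channel.
    """

    projection_method: str = "max"
    reference_mode: str = "first_frame"
    upscale_factor: int = 10
    max_shift: float | None = None
    time_window: int = 1
    edge_mode: str = "zero_fill"
    axes_corrected: tuple[str, ...] = ("lateral", "axial")
    drift_table_path: str | None = None

    _CHOICES = {
        "projection_method": {"max", "average"},
        "reference_mode": {"first_frame", "previous_frame"},
        "edge_mode": {"zero_fill", "crop"},
    }

    def __post_init__(self) -> None:
        self.axes_corrected = tuple(self.axes_corrected)
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                raise ValueError(f"{name} must be one of {sorted(choices)}")
        if int(self.upscale_factor) != self.upscale_factor or self.upscale_factor < 1:
            raise ValueError("upscale_factor must be an integer >= 1")
        self.upscale_factor = int(self.upscale_factor)
        if self.time_window < 1 or self.time_window % 2 == 0:
            raise ValueError("time_window must be a positive odd integer")
        if not set(self.axes_corrected) <= {"lateral", "axial"}:
            raise ValueError("axes_corrected must be a subset of {'lateral','axial'}")
        if self.max_shift is not None and self.max_shift <= 0:
            raise ValueError("max_shift must be positive or None")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axes_corrected"] = list(self.axes_corrected)
        return d


_REQUIRED_SETTINGS_KEYS = {
    "projection_method",
    "reference_mode",
    "upscale_factor",
    "max_shift",
    "time_window",
    "edge_mode",
    "axes_corrected",
}


# ---------------------------------------------------------------------------
# stacks


def save_stack(stack: VideoStack, path) -> None:
    """Write a stack as a multi-page TIFF that :func:`load_stack` inverts
    bit-exactly (ImageJ-hyperstack-compatible axis metadata)."""
    path = Path(path)
    meta = {"axes": "TZYX"}
    if stack.pixel_size_xy is not None:
        meta["pixel_size_xy"] = stack.pixel_size_xy
    if stack.z_step is not None:
        meta["z_step"] = stack.z_step
    tifffile.imwrite(path, stack.data, photometric="minisblack", metadata=meta)


def _canonicalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with named axes into T, Z, Y, X."""
    axes = axes.upper()
    if "C" in axes and data.shape[axes.index("C")] > 1:
        raise ValueError(
            "multichannel requires channel split: load each channel separately "
            "(see load_channel_stacks)"
        )
    if "C" in axes:  # singleton channel axis
        data = np.squeeze(data, axis=axes.index("C"))
        axes = axes.replace("C", "")
    # tifffile labels unidentifiable dimensions 'Q'/'S'; a single leading one
    # is taken to be time
    axes = axes.replace("S", "Q")
    if axes.count("Q") == 1 and "T" not in axes:
        axes = axes.replace("Q", "T")
    unknown = set(axes) - set("TZYX")
    if unknown:
        raise ValueError(f"cannot interpret axes {axes!r}; pass axes_hint")
    if len(axes) != data.ndim or len(set(axes)) != len(axes):
        raise ValueError(f"axes {axes!r} do not match array of shape {data.shape}")
    for missing in set("TZYX") - set(axes):
        data = data[None]
        axes = missing + axes
    order = [axes.index(ax) for ax in "TZYX"]
    return np.transpose(data, order)


def load_stack(path, axes_hint: str | None = None) -> VideoStack:
    """Load a TIFF as a canonical ``T, Z, Y, X`` :class:`VideoStack`.

    ``axes_hint`` (e.g. ``"ZTYX"``) overrides the axis order recorded in the
    file; it is required when the file carries no usable axis metadata and
    has more than two dimensions.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = axes_hint if axes_hint is not None else series.axes
        meta = {}
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
    data = _canonicalize_axes(data, axes)
    return VideoStack(
        data,
        pixel_size_xy=meta.get("pixel_size_xy"),
        z_step=meta.get("z_step"),
        source_path=str(path),
    )


def load_channel_stacks(path, axes_hint: str | None = None) -> list[VideoStack]:
    """Load a multichannel TIFF as one :class:`VideoStack` per channel."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = (axes_hint if axes_hint is not None else series.axes).upper()
    if "C" not in axes:
        raise ValueError(f"{path} has no channel axis (axes {axes!r})")
    c_ax = axes.index("C")
    rest = axes.replace("C", "")
    return [
        VideoStack(
            _canonicalize_axes(np.take(data, c, axis=c_ax), rest),
            source_path=f"{path}[C={c}]",
        )
        for c in range(data.shape[c_ax])
    ]


# ---------------------------------------------------------------------------
# drift tables


def write_drift_table(table: DriftTable, path) -> None:
    """Write a drift table as CSV (full float precision, '.' decimals)."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_drift_table(path) -> DriftTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalise to a parse error
        raise DriftTableError(f"cannot parse drift table {path}: {exc}") from exc
    if list(df.columns) != list(DRIFT_TABLE_COLUMNS):
        raise DriftTableError(
            f"drift table {path} must have columns {DRIFT_TABLE_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    frames = df["frame"].to_numpy()
    if len(frames) == 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise DriftTableError(
            f"drift table {path} must contain consecutive frame indices from 0"
        )
    return DriftTable(
        df["dx_px"].to_numpy(float),
        df["dy_px"].to_numpy(float),
        df["dz_slices"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# settings


def write_settings(settings: RegistrationSettings, path) -> None:
    Path(path).write_text(json.dumps(settings.to_dict(), indent=2) + "\n")


def read_settings(path) -> RegistrationSettings:
    raw = json.loads(Path(path).read_text())
    missing = _REQUIRED_SETTINGS_KEYS - raw.keys()
    if missing:
        raise ValueError(f"settings file {path} is missing keys {sorted(missing)}")
    known = {f.name for f in dataclasses.fields(RegistrationSettings)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(
            f"ignoring unknown settings keys {sorted(unknown)} in {path}",
            stacklevel=2,
        )
    kwargs = {k: v for k, v in raw.items() if k in known}
    kwargs["axes_corrected"] = tuple(kwargs.get("axes_corrected", ()))
    return RegistrationSettings(**kwargs)


# ---------------------------------------------------------------------------
# plots


def write_drift_plot(table: DriftTable, path) -> None:
    """Plot dx, dy, dz versus frame index to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    frames = np.arange(table.n_frames)
    ax.plot(frames, table.dx, marker="o", ms=3, label="dx (px)")
    ax.plot(frames, table.dy, marker="s", ms=3, label="dy (px)")
    ax.plot(frames, table.dz, marker="^", ms=3, label="dz (slices)")
    ax.set_xlabel("frame")
    ax.set_ylabel("cumulative drift")
    ax.legend()
    ax.set_title("Estimated drift relative to frame 0")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
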