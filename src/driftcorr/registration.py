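"""Drift-correction pipeline: estimators and thin functional wrappers.

The pipeline sequentially estimates lateral (x, y) drift on z-projections,
corrects it, then estimates axial (z) drift on y-projections of the
laterally corrected stack and corrects that too.  The per-frame estimates
are accumulated into a drift table (cumulative shifts relative to frame 0)
that can be re-applied to other channels acquired simultaneously.

:class:`DriftCorrector` is a scikit-learn style transformer: ``fit``
estimates the drift table from one channel, ``transform`` applies it to any
stack with the same frame count.  :class:`ChannelAligner` registers
misaligned channels of a 3D multichannel image by treating the channels as
time frames.  The module-level functions (:func:`register_video`,
:func:`estimate_lateral`, ...) are wrappers over these estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from sklearn.base import BaseEstimator, TransformerMixin

from . import io as dio
from .io import DriftTable, RegistrationSettings, VideoStack, as_video_stack
from .projection import project_series, time_window_average
from .transform import apply_drift_table, translate_volume
from .xcorr import ZeroVarianceError, estimate_shift

__all__ = [
    "DriftCorrector",
    "ChannelAligner",
    "RegistrationResult",
    "estimate_lateral",
    "estimate_axial",
    "register_video",
    "register_second_channel",
    "register_channels",
    "register_file",
    "batch_register",
]

logger = logging.getLogger(__name__)

LOW_CORRELATION_WARNING = 0.2


@dataclass
class RegistrationResult:
    """Everything a registration run produces."""

    corrected: VideoStack
    table: DriftTable
    settings: RegistrationSettings
    diagnostics: pd.DataFrame


def _estimate_pairwise(frames: np.ndarray, stage: str, settings: RegistrationSettings):
    """Cumulative per-frame (row, col) shifts of a 2D series, plus
    diagnostics records.

    ``first_frame`` mode estimates every frame against frame 0;
    ``previous_frame`` mode estimates consecutive pairs and cumulates them.
    """
    t = frames.shape[0]
    rows = np.zeros(t)
    cols = np.zeros(t)
    records = []
    for i in range(1, t):
        ref_idx = 0 if settings.reference_mode == "first_frame" else i - 1
        try:
            est = estimate_shift(
                frames[ref_idx],
                frames[i],
                upscale_factor=settings.upscale_factor,
                max_shift=settings.max_shift,
                full_output=True,
            )
        except ZeroVarianceError as exc:
            raise ZeroVarianceError(
                f"{stage} estimation failed: constant projection at frame "
                f"{i if 'mov' in str(exc) else ref_idx} ({exc})"
            ) from exc
        if settings.reference_mode == "first_frame":
            rows[i], cols[i] = est.row_shift, est.col_shift
        else:
            rows[i] = rows[i - 1] + est.row_shift
            cols[i] = cols[i - 1] + est.col_shift
        if est.peak_correlation < LOW_CORRELATION_WARNING:
            warnings.warn(
                f"{stage}: frame {i} peak correlation "
                f"{est.peak_correlation:.3f} < {LOW_CORRELATION_WARNING}; "
                "possible registration failure",
                stacklevel=3,
            )
        logger.info(
            "%s frame %d vs %d: shift (%.3f, %.3f), peak %.3f%s",
            stage, i, ref_idx, est.row_shift, est.col_shift,
            est.peak_correlation, " [bound hit]" if est.bound_hit else "",
        )
        records.append(
            {
                "stage": stage,
                "frame": i,
                "reference_frame": ref_idx,
                "row_shift": est.row_shift,
                "col_shift": est.col_shift,
                "peak_correlation": est.peak_correlation,
                "bound_hit": est.bound_hit,
            }
        )
    return rows, cols, records


def _lateral_projection(stack: VideoStack, settings: RegistrationSettings) -> np.ndarray:
    series = project_series(stack, axis="z", method=settings.projection_method)
    series = time_window_average(series, settings.time_window)
    return series.frames


def _axial_projection(stack: VideoStack, settings: RegistrationSettings) -> np.ndarray:
    series = project_series(stack, axis="y", method=settings.projection_method)
    series = time_window_average(series, settings.time_window)
    return series.frames


class DriftCorrector(TransformerMixin, BaseEstimator):
    """Estimate and correct lateral and axial drift of a video stack.

    ``fit(X)`` runs the sequential pipeline (lateral estimate → lateral
    correct → axial estimate) on one channel and stores the cumulative drift
    table; ``transform(X)`` applies the stored table to any stack with the
    same frame count — the fitted channel or another one.

    Parameters mirror :class:`~driftcorr.io.RegistrationSettings`; see there
    for meanings and defaults.

    Attributes
    ----------
    drift_table_ : DriftTable
        Cumulative per-frame (dx, dy, dz) relative to frame 0.
    diagnostics_ : pandas.DataFrame
        Per estimated pair: stage, frames, shift, peak correlation and
        whether the ``max_shift`` bound was hit.
    n_frames_ : int
        Frame count of the fitted stack.
    """

    def __init__(
        self,
        projection_method: str = "max",
        reference_mode: str = "first_frame",
        upscale_factor: int = 10,
        max_shift: float | None = None,
        time_window: int = 1,
        edge_mode: str = "zero_fill",
        axes_corrected: tuple[str, ...] = ("lateral", "axial"),
    ):
        self.projection_method = projection_method
        self.reference_mode = reference_mode
        self.upscale_factor = upscale_factor
        self.max_shift = max_shift
        self.time_window = time_window
        self.edge_mode = edge_mode
        self.axes_corrected = axes_corrected

    # -- scikit-learn plumbing ------------------------------------------
    def _settings(self) -> RegistrationSettings:
        return RegistrationSettings(
            projection_method=self.projection_method,
            reference_mode=self.reference_mode,
            upscale_factor=self.upscale_factor,
            max_shift=self.max_shift,
            time_window=self.time_window,
            edge_mode=self.edge_mode,
            axes_corrected=tuple(self.axes_corrected),
        )

    # -- estimation ------------------------------------------------------
    def fit(self, X, y=None) -> "DriftCorrector":
        """Estimate the drift table from stack `X` (VideoStack or array of
        shape (T, Z, Y, X) / (T, Y, X))."""
        stack = as_video_stack(X)
        settings = self._settings()  # validates parameters
        n = stack.n_frames
        dx = np.zeros(n)
        dy = np.zeros(n)
        dz = np.zeros(n)
        records: list[dict] = []
        if "lateral" in settings.axes_corrected:
            frames = _lateral_projection(stack, settings)
            rows, cols, recs = _estimate_pairwise(frames, "lateral", settings)
            dy, dx = rows, cols
            records += recs
        if "axial" in settings.axes_corrected and stack.n_slices > 1:
            work = stack
            if dx.any() or dy.any():
                # axial estimation runs on the laterally corrected stack
                work = apply_drift_table(
                    stack, DriftTable(dx, dy, np.zeros(n)), edge_mode="zero_fill"
                )
            frames = _axial_projection(work, settings)
            rows, _cols, recs = _estimate_pairwise(frames, "axial", settings)
            dz = rows  # rows of a y-projection are z; the x component is discarded
            records += recs
        self.drift_table_ = DriftTable(dx, dy, dz)
        self.diagnostics_ = pd.DataFrame(
            records,
            columns=[
                "stage", "frame", "reference_frame",
                "row_shift", "col_shift", "peak_correlation", "bound_hit",
            ],
        )
        self.n_frames_ = n
        return self

    def transform(self, X) -> VideoStack:
        """Apply the fitted drift table to `X` (same frame count)."""
        if not hasattr(self, "drift_table_"):
            raise RuntimeError("DriftCorrector must be fitted before transform")
        return apply_drift_table(as_video_stack(X), self.drift_table_, self.edge_mode)

    def fit_transform(self, X, y=None, **fit_params) -> VideoStack:
        return self.fit(X).transform(X)


class ChannelAligner(TransformerMixin, BaseEstimator):
    """Register misaligned channels of a 3D multichannel image.

    Channels are converted to time frames and sent through the drift
    pipeline with ``reference_mode='first_frame'``, the user-chosen
    reference channel playing the role of frame 0.  ``fit`` stores one
    (dx, dy, dz) offset per channel relative to the reference;
    ``transform`` aligns the channels of any image with the same channel
    count (e.g. an image acquired with the same calibration-slide
    conditions).

    Attributes
    ----------
    channel_shifts_ : ndarray of shape (C, 3)
        Per-channel (dx, dy, dz) relative to the reference channel.
    drift_table_ : DriftTable
        The same offsets re-anchored to channel 0 (row 0 = zero), in
        channels-as-frames form.
    diagnostics_ : pandas.DataFrame
    """

    def __init__(
        self,
        reference_channel: int = 0,
        projection_method: str = "max",
        upscale_factor: int = 10,
        max_shift: float | None = None,
        edge_mode: str = "zero_fill",
        axes_corrected: tuple[str, ...] = ("lateral", "axial"),
    ):
        self.reference_channel = reference_channel
        self.projection_method = projection_method
        self.upscale_factor = upscale_factor
        self.max_shift = max_shift
        self.edge_mode = edge_mode
        self.axes_corrected = axes_corrected

    @staticmethod
    def _check_channels(X) -> np.ndarray:
        a = np.asarray(X)
        if a.ndim == 3:  # C, Y, X
            a = a[:, None]
        if a.ndim != 4:
            raise ValueError(
                f"expected a (C, Z, Y, X) multichannel image, got shape {a.shape}"
            )
        if a.shape[0] < 2:
            raise ValueError("channel registration requires at least 2 channels")
        return a

    def fit(self, X, y=None) -> "ChannelAligner":
        a = self._check_channels(X)
        c = a.shape[0]
        ref = self.reference_channel
        if not 0 <= ref < c:
            raise ValueError(f"reference_channel {ref} out of range for {c} channels")
        if ref == 0:
            logger.info("using channel 0 as the reference channel (default)")
        order = [ref] + [i for i in range(c) if i != ref]
        corrector = DriftCorrector(
            projection_method=self.projection_method,
            reference_mode="first_frame",
            upscale_factor=self.upscale_factor,
            max_shift=self.max_shift,
            edge_mode=self.edge_mode,
            axes_corrected=tuple(self.axes_corrected),
        ).fit(a[order])
        t = corrector.drift_table_
        shifts = np.zeros((c, 3))
        for pos, chan in enumerate(order):
            shifts[chan] = (t.dx[pos], t.dy[pos], t.dz[pos])
        self.channel_shifts_ = shifts
        anchored = shifts - shifts[0]
        self.drift_table_ = DriftTable(anchored[:, 0], anchored[:, 1], anchored[:, 2])
        self.diagnostics_ = corrector.diagnostics_
        self.n_channels_ = c
        return self

    def transform(self, X) -> np.ndarray:
        """Align the channels of `X` using the fitted per-channel offsets."""
        if not hasattr(self, "channel_shifts_"):
            raise RuntimeError("ChannelAligner must be fitted before transform")
        a = self._check_channels(X)
        if a.shape[0] != self.n_channels_:
            raise ValueError(
                f"fitted on {self.n_channels_} channels, got {a.shape[0]}"
            )
        out = []
        for chan in range(a.shape[0]):
            dx, dy, dz = self.channel_shifts_[chan]
            if dx == 0 and dy == 0 and dz == 0:
                out.append(np.asarray(a[chan]).copy())
            else:
                out.append(translate_volume(a[chan], -dz, -dy, -dx))
        return np.stack(out)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# functional wrappers


def estimate_lateral(stack, settings: RegistrationSettings | None = None) -> DriftTable:
    """Per-frame (dx, dy) drift from the z-projection series (dz left 0)."""
    settings = settings or RegistrationSettings()
    c = DriftCorrector(**{**_corrector_kwargs(settings), "axes_corrected": ("lateral",)})
    return c.fit(stack).drift_table_


def estimate_axial(stack, settings: RegistrationSettings | None = None) -> DriftTable:
    """Per-frame dz drift from the y-projection series (dx, dy left 0).

    When lateral correction is wanted first, use :func:`register_video`;
    this wrapper estimates on the stack exactly as given.
    """
    settings = settings or RegistrationSettings()
    c = DriftCorrector(**{**_corrector_kwargs(settings), "axes_corrected": ("axial",)})
    return c.fit(stack).drift_table_


def _corrector_kwargs(settings: RegistrationSettings) -> dict:
    return dict(
        projection_method=settings.projection_method,
        reference_mode=settings.reference_mode,
        upscale_factor=settings.upscale_factor,
        max_shift=settings.max_shift,
        time_window=settings.time_window,
        edge_mode=settings.edge_mode,
        axes_corrected=settings.axes_corrected,
    )


def register_video(stack, settings: RegistrationSettings | None = None) -> RegistrationResult:
    """Full pipeline on one stack: estimate (lateral then axial, per
    ``settings.axes_corrected``), correct, and return corrected stack,
    drift table, settings and diagnostics."""
    settings = settings or RegistrationSettings()
    corrector = DriftCorrector(**_corrector_kwargs(settings)).fit(stack)
    corrected = corrector.transform(stack)
    return RegistrationResult(
        corrected=corrected,
        table=corrector.drift_table_,
        settings=settings,
        diagnostics=corrector.diagnostics_,
    )


def register_second_channel(stack, settings: RegistrationSettings) -> VideoStack:
    """Apply a previously written drift table (named by
    ``settings.drift_table_path``) to another channel — pure application,
    no estimation."""
    if not settings.drift_table_path:
        raise ValueError("settings.drift_table_path must name a drift table")
    table = dio.read_drift_table(settings.drift_table_path)
    return apply_drift_table(as_video_stack(stack), table, settings.edge_mode)


def register_channels(
    stack, settings: RegistrationSettings | None = None, reference_channel: int = 0
):
    """Align the channels of a (C, Z, Y, X) image; returns the corrected
    multichannel array and the per-channel drift table."""
    settings = settings or RegistrationSettings()
    aligner = ChannelAligner(
        reference_channel=reference_channel,
        projection_method=settings.projection_method,
        upscale_factor=settings.upscale_factor,
        max_shift=settings.max_shift,
        edge_mode=settings.edge_mode,
        axes_corrected=settings.axes_corrected,
    )
    corrected = aligner.fit_transform(stack)
    return corrected, aligner.drift_table_


# ---------------------------------------------------------------------------
# file-level runs


def _write_outputs(result: RegistrationResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corrected": out_dir / "corrected.tif",
        "drift_table": out_dir / "drift_table.csv",
        "drift_plot": out_dir / "drift_plot.png",
        "settings": out_dir / "settings.json",
    }
    dio.save_stack(result.corrected, paths["corrected"])
    dio.write_drift_table(result.table, paths["drift_table"])
    dio.write_drift_plot(result.table, paths["drift_plot"])
    settings = result.settings
    settings.drift_table_path = str(paths["drift_table"])
    dio.write_settings(settings, paths["settings"])
    return {k: str(v) for k, v in paths.items()}


def register_file(
    path,
    settings: RegistrationSettings | None = None,
    out_dir=None,
    low_memory: bool = False,
    axes_hint: str | None = None,
) -> RegistrationResult:
    """Register a TIFF on disk; optionally write the four run outputs
    (corrected.tif, drift_table.csv, drift_plot.png, settings.json).

    With ``low_memory=True`` the input is memory-mapped and every pipeline
    stage walks it one frame at a time, so peak memory is bounded by a
    single time point; the resulting drift table is bit-identical to the
    in-memory run.
    """
    settings = settings or RegistrationSettings()
    if low_memory:
        data = tifffile.imread(path, out="memmap")
        with tifffile.TiffFile(path) as tif:
            axes = axes_hint if axes_hint is not None else tif.series[0].axes
        from .io import _canonicalize_axes

        stack = VideoStack(_canonicalize_axes(data, axes), source_path=str(path))
    else:
        stack = dio.load_stack(path, axes_hint=axes_hint)
    result = register_video(stack, settings)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def batch_register(paths, settings: RegistrationSettings | None = None, out_root=None):
    """Register several files independently; per-file failures are collected
    and the remaining files still processed.

    Returns ``(results, failures)``: dicts mapping each input path to its
    :class:`RegistrationResult` or to the raised exception.
    """
    settings = settings or RegistrationSettings()
    results: dict[str, RegistrationResult] = {}
    failures: dict[str, Exception] = {}
    for p in paths:
        try:
            out_dir = None
            if out_root is not None:
                out_dir = Path(out_root) / Path(p).stem
            results[str(p)] = register_file(p, settings, out_dir=out_dir)
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            logger.error("registration of %s failed: %s", p, exc)
            failures[str(p)] = exc
    return results, failures
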