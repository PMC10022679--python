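"""Apply shifts to images and volumes with sub-pixel interpolation.

Lateral (in-plane) shifts use bicubic interpolation; axial shifts use linear
interpolation between adjacent slices, reflecting the coarse z-sampling of
typical confocal stacks.  Integer shifts bypass interpolation entirely and
are exact copies.  Vacated pixels are zero-filled by default; the crop edge
policy trims every frame of a corrected stack to the common region that is
valid for all frames.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import DriftTable, VideoStack, as_video_stack

__all__ = ["translate_2d", "translate_axial", "apply_drift_table", "crop_bounds"]


def _is_integer(x: float) -> bool:
    return float(x) == int(x)


def _integer_translate(a: np.ndarray, shifts: tuple[int, ...]) -> np.ndarray:
    """Exact, roll-free integer translation along each axis; vacated regions
    are zero."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for d, size in zip(shifts, a.shape):
        if abs(d) >= size:
            return out
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    out[tuple(dst)] = a[tuple(src)]
    return out


def translate_2d(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate a 2D image so its content moves by ``(+dy, +dx)``.

    Fractional shifts are resampled with bicubic interpolation (vacated
    pixels zero); integer shifts are exact copies preserving dtype.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("translate_2d expects a 2D image")
    if abs(dy) >= image.shape[0] or abs(dx) >= image.shape[1]:
        raise ValueError(
            f"shift ({dy}, {dx}) exceeds image size {image.shape}"
        )
    if _is_integer(dy) and _is_integer(dx):
        return _integer_translate(image, (int(dy), int(dx)))
    return ndimage.shift(
        image.astype(np.float64, copy=False),
        (dy, dx),
        order=3,
        mode="constant",
        cval=0.0,
    )


def translate_axial(volume: np.ndarray, dz: float) -> np.ndarray:
    """Translate a (Z, Y, X) volume along z by ``+dz`` slices.

    Fractional dz linearly interpolates between adjacent slices; integer dz
    is an exact slice copy.  Vacated slices are zero.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("translate_axial expects a (Z, Y, X) volume")
    if abs(dz) >= volume.shape[0]:
        raise ValueError(f"dz={dz} exceeds the {volume.shape[0]}-slice extent")
    if _is_integer(dz):
        return _integer_translate(volume, (int(dz), 0, 0))
    return ndimage.shift(
        volume.astype(np.float64, copy=False),
        (dz, 0.0, 0.0),
        order=1,
        mode="constant",
        cval=0.0,
    )


def translate_volume(volume: np.ndarray, dz: float, dy: float, dx: float) -> np.ndarray:
    """Lateral (bicubic, per slice) then axial (linear) translation of a
    single (Z, Y, X) volume."""
    if dy != 0 or dx != 0:
        if _is_integer(dy) and _is_integer(dx):
            volume = _integer_translate(np.asarray(volume), (0, int(dy), int(dx)))
        else:
            volume = np.stack([translate_2d(sl, dy, dx) for sl in volume])
    if dz != 0:
        volume = translate_axial(volume, dz)
    return volume


def crop_bounds(table: DriftTable, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """(z, y, x) slices of the region valid in every frame after correcting
    with `table`: the input shape minus the maximal absolute drift per axis."""
    n_z, n_y, n_x = shape
    dx_m, dy_m, dz_m = (int(np.ceil(m)) for m in table.max_abs())
    if 2 * dz_m >= n_z or 2 * dy_m >= n_y or 2 * dx_m >= n_x:
        raise ValueError("drift exceeds half the stack extent; cannot crop")

    def _sl(m: int, n: int) -> slice:
        return slice(m, n - m) if m else slice(0, n)

    return _sl(dz_m, n_z), _sl(dy_m, n_y), _sl(dx_m, n_x)


def apply_drift_table(
    stack: VideoStack | np.ndarray,
    table: DriftTable,
    edge_mode: str = "zero_fill",
) -> VideoStack:
    """Correct a stack with a drift table: frame t is translated by
    ``(-dx_t, -dy_t, -dz_t)``.

    ``edge_mode='zero_fill'`` preserves the frame shape; ``'crop'`` trims
    every frame to the identical region valid for all frames (no vacated
    pixels).  Deterministic given inputs; a zero table is the identity up to
    the crop.
    """
    stack = as_video_stack(stack)
    if edge_mode not in ("zero_fill", "crop"):
        raise ValueError(f"edge_mode must be 'zero_fill' or 'crop', got {edge_mode!r}")
    if table.n_frames != stack.n_frames:
        raise ValueError(
            f"drift table has {table.n_frames} rows but stack has "
            f"{stack.n_frames} frames"
        )
    frames = []
    for t in range(stack.n_frames):
        vol = np.asarray(stack.data[t])
        dz, dy, dx = table.dz[t], table.dy[t], table.dx[t]
        if dz == 0 and dy == 0 and dx == 0:
            frames.append(vol.copy())
        else:
            frames.append(translate_volume(vol, -dz, -dy, -dx))
    dtype = np.result_type(*(f.dtype for f in frames))
    out = np.stack([f.astype(dtype, copy=False) for f in frames])
    if edge_mode == "crop":
        zs, ys, xs = crop_bounds(table, out.shape[1:])
        out = out[:, zs, ys, xs]
    return stack.with_data(out)
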