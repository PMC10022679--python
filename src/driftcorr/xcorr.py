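"""Shift estimation via up-scaled, normalized cross-correlation matrices.

The estimator computes the circular cross-correlation surface of two 2D
images in the Hartley domain (a real-valued Fourier-like transform: each
image is transformed, the spectra are combined as a complex-conjugate
product, and the result inverse-transformed), up-scales the surface with a
bicubic spline to reach sub-pixel precision, rescales it so its extrema equal
the Pearson correlation of the images aligned at the corresponding shifts,
and reads the shift off the global maximum.

Sign convention: the returned ``(row_shift, col_shift)`` is the displacement
of the *moving* image relative to the *reference*; the correction to apply
is its negation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

__all__ = [
    "CCM",
    "ShiftEstimate",
    "cross_correlation_matrix",
    "upscale_ccm",
    "normalize_ccm",
    "peak_shift",
    "estimate_shift",
    "ZeroVarianceError",
]


class ZeroVarianceError(ValueError):
    """Raised when asked to register a constant (zero-variance) image."""


# ---------------------------------------------------------------------------
# discrete Hartley transform


def dht2(a: np.ndarray) -> np.ndarray:
    """2D discrete Hartley transform, cas(2π(ur/N + vc/M)) kernel.

    Equal to the real part minus the imaginary part of the 2D DFT; real in,
    real out, and self-inverse up to division by the number of elements.
    """
    f = np.fft.fft2(a)
    return f.real - f.imag


def idht2(h: np.ndarray) -> np.ndarray:
    return dht2(h) / h.size


def _reverse_spectrum(h: np.ndarray) -> np.ndarray:
    """H(-u, -v) with indices taken modulo the array shape."""
    return np.roll(h[::-1, ::-1], (1, 1), axis=(0, 1))


@dataclass
class CCM:
    """A cross-correlation surface with its index→shift mapping.

    ``values[i, j]`` is the correlation of the reference with the moving
    image displaced by ``shift_of_index((i, j))``; the matrix center maps to
    shift (0, 0).  ``upscale_factor`` counts grid points per original pixel.
    """

    values: np.ndarray
    center: tuple[int, int]
    upscale_factor: int = 1
    normalized: bool = False

    def shift_of_index(self, index: tuple[float, float]) -> tuple[float, float]:
        r, c = index
        return (
            (r - self.center[0]) / self.upscale_factor,
            (c - self.center[1]) / self.upscale_factor,
        )

    def shift_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Row- and column-shift value per matrix row/column."""
        n, m = self.values.shape
        rows = (np.arange(n) - self.center[0]) / self.upscale_factor
        cols = (np.arange(m) - self.center[1]) / self.upscale_factor
        return rows, cols


def _prepare(img: np.ndarray, name: str) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"{name} must be a 2D image, got shape {img.shape}")
    if np.ptp(img) == 0:
        raise ZeroVarianceError(f"cannot register a constant image ({name})")
    return img - img.mean()


def cross_correlation_matrix(ref: np.ndarray, mov: np.ndarray) -> CCM:
    """Circular cross-correlation surface of two mean-subtracted images.

    Both images are Hartley-transformed; the even/odd spectrum parts are
    combined exactly as the complex-conjugate product of their Fourier
    spectra, and the product is inverse-transformed back to real space.
    The result equals brute-force spatial circular cross-correlation and is
    returned center-origin indexed (peak at the center ⇔ zero shift).
    """
    ref = _prepare(ref, "ref")
    mov = _prepare(mov, "mov")
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    ha, hb = dht2(ref), dht2(mov)
    ha_r, hb_r = _reverse_spectrum(ha), _reverse_spectrum(hb)
    ha_even, ha_odd = (ha + ha_r) / 2.0, (ha - ha_r) / 2.0
    hb_even, hb_odd = (hb + hb_r) / 2.0, (hb - hb_r) / 2.0
    # Hartley spectrum of conj(F_ref) * F_mov
    hc = (ha_even * hb_even + ha_odd * hb_odd) - (ha_odd * hb_even - ha_even * hb_odd)
    surface = np.fft.fftshift(idht2(hc))
    n, m = surface.shape
    return CCM(surface, center=(n // 2, m // 2), upscale_factor=1, normalized=False)


def upscale_ccm(ccm: CCM, factor: int) -> CCM:
    """Densify the surface `factor`-fold with bicubic spline interpolation.

    The interpolant passes through the original grid nodes, so coarse values
    are preserved; the index→shift mapping is rescaled accordingly.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("upscale factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return ccm
    n, m = ccm.values.shape
    spline = RectBivariateSpline(np.arange(n), np.arange(m), ccm.values, kx=3, ky=3)
    fine_r = np.arange((n - 1) * factor + 1) / factor
    fine_c = np.arange((m - 1) * factor + 1) / factor
    values = spline(fine_r, fine_c)
    return CCM(
        values,
        center=(ccm.center[0] * factor, ccm.center[1] * factor),
        upscale_factor=ccm.upscale_factor * factor,
        normalized=ccm.normalized,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _pcc_at_shift(ref: np.ndarray, mov: np.ndarray, shift: tuple[float, float]) -> float:
    """Pearson correlation of ref with mov aligned by `shift`, on the
    overlap region that excludes pixels vacated by the alignment."""
    from .transform import translate_2d

    dr, dc = shift
    aligned = translate_2d(np.asarray(mov, dtype=np.float64), -dr, -dc)
    mr, mc = int(np.ceil(abs(dr))), int(np.ceil(abs(dc)))
    n, m = ref.shape
    if n - 2 * mr < 2 or m - 2 * mc < 2:
        return 0.0
    sl = (slice(mr, n - mr) if mr else slice(None), slice(mc, m - mc) if mc else slice(None))
    return _pearson(np.asarray(ref, dtype=np.float64)[sl], aligned[sl])


def normalize_ccm(ref: np.ndarray, mov: np.ndarray, ccm: CCM) -> CCM:
    """Affinely rescale the surface so that its minimum (maximum) equals the
    Pearson correlation coefficient of the two images aligned at the argmin
    (argmax) shift.  Order of values is preserved; output lies in [−1, 1].
    """
    if ccm.normalized:
        raise ValueError("CCM is already normalized")
    vmin, vmax = float(ccm.values.min()), float(ccm.values.max())
    if vmax == vmin:
        raise ValueError("degenerate CCM: constant surface cannot be normalized")
    argmin = np.unravel_index(int(np.argmin(ccm.values)), ccm.values.shape)
    argmax = np.unravel_index(int(np.argmax(ccm.values)), ccm.values.shape)
    p_min = _pcc_at_shift(ref, mov, ccm.shift_of_index(argmin))
    p_max = _pcc_at_shift(ref, mov, ccm.shift_of_index(argmax))
    slope = (p_max - p_min) / (vmax - vmin)
    values = np.clip(p_min + (ccm.values - vmin) * slope, -1.0, 1.0)
    return CCM(values, center=ccm.center, upscale_factor=ccm.upscale_factor, normalized=True)


def peak_shift(
    ccm: CCM, max_shift: float | None = None
) -> tuple[tuple[float, float], float, bool]:
    """Locate the global maximum of the surface and map it to a shift.

    Ties are broken toward the smallest Euclidean shift magnitude, then
    row-major order ("no drift" is preferred under ambiguity).  With
    ``max_shift`` set, the search is restricted to ``|shift| <= max_shift``
    per axis; ``bound_hit`` reports whether the unrestricted maximum lay
    outside the bound.

    Returns ``((row_shift, col_shift), peak_value, bound_hit)``.
    """
    values = ccm.values
    rows, cols = ccm.shift_grids()
    bound_hit = False
    if max_shift is not None:
        allowed = (np.abs(rows)[:, None] <= max_shift) & (np.abs(cols)[None, :] <= max_shift)
        if not allowed.any():
            raise ValueError("max_shift excludes every candidate shift")
        global_arg = np.unravel_index(int(np.argmax(values)), values.shape)
        bound_hit = not allowed[global_arg]
        masked = np.where(allowed, values, -np.inf)
    else:
        masked = values
    vmax = masked.max()
    cand_r, cand_c = np.nonzero(masked == vmax)
    shifts_r = rows[cand_r]
    shifts_c = cols[cand_c]
    order = np.lexsort((cand_c, cand_r, shifts_r**2 + shifts_c**2))
    best = order[0]
    return (float(shifts_r[best]), float(shifts_c[best])), float(vmax), bound_hit


@dataclass
class ShiftEstimate:
    """A shift estimate with diagnostics."""

    row_shift: float
    col_shift: float
    peak_correlation: float
    bound_hit: bool


def estimate_shift(
    ref: np.ndarray,
    mov: np.ndarray,
    upscale_factor: int = 10,
    max_shift: float | None = None,
    normalize: bool = True,
    full_output: bool = False,
):
    """Estimate the displacement of `mov` relative to `ref`.

    Composition of :func:`cross_correlation_matrix`, :func:`upscale_ccm`,
    :func:`normalize_ccm` and :func:`peak_shift`.  Returns the
    ``(row_shift, col_shift)`` displacement, or a :class:`ShiftEstimate`
    when ``full_output`` is set.
    """
    ccm = cross_correlation_matrix(ref, mov)
    ccm = upscale_ccm(ccm, upscale_factor)
    if normalize:
        ccm = normalize_ccm(ref, mov, ccm)
    (dr, dc), peak, bound_hit = peak_shift(ccm, max_shift=max_shift)
    if full_output:
        return ShiftEstimate(dr, dc, peak, bound_hit)
    return dr, dc
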