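"""Image-similarity metrics used to validate registration quality.

Four per-frame-pair metrics: Pearson's correlation coefficient (PCC), mean
structural similarity index (mSSIM), peak signal-to-noise ratio (PSNR, dB)
and normalized root-mean-square error (NRMSE).  Conventions, recorded for
reproducibility:

* PSNR peak = data-type maximum for integer images, observed maximum of the
  reference for float images; identical images give infinite PSNR, returned
  as ``inf`` and flagged in reports.
* NRMSE is normalized by the Euclidean norm (RMS) of the reference, making
  it invariant to a joint intensity rescaling.
* mSSIM uses the standard local-window formulation (window 7, K1=0.01,
  K2=0.03).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .io import VideoStack, as_video_stack

__all__ = [
    "pcc",
    "mssim",
    "psnr",
    "nrmse",
    "similarity_report",
    "summarize_report",
    "sd_time_projection",
]

SSIM_WINDOW = 7
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _peak(reference) -> float:
    """Dynamic-range peak: dtype max for integers, observed max for floats."""
    ref = np.asarray(reference)
    if np.issubdtype(ref.dtype, np.integer):
        return float(np.iinfo(ref.dtype).max)
    return float(ref.max())


def pcc(a, b) -> float:
    """Pearson's correlation coefficient over all pixels; 1 means a perfect
    linear relationship between the two images."""
    af, bf = _check_pair(a, b)
    if np.ptp(af) == 0 or np.ptp(bf) == 0:
        raise ValueError("PCC is undefined for a constant image")
    af -= af.mean()
    bf -= bf.mean()
    return float(np.sum(af * bf) / np.sqrt(np.sum(af**2) * np.sum(bf**2)))


def mssim(a, b) -> float:
    """Mean structural similarity index; 1 means perfectly similar images."""
    af, bf = _check_pair(a, b)
    if min(af.shape) < SSIM_WINDOW:
        raise ValueError(
            f"image smaller than the {SSIM_WINDOW}-pixel SSIM window"
        )
    # joint dynamic range keeps the index symmetric in its arguments
    if np.issubdtype(np.asarray(a).dtype, np.integer) and np.issubdtype(
        np.asarray(b).dtype, np.integer
    ):
        data_range = max(_peak(np.asarray(a)), _peak(np.asarray(b)))
    else:
        data_range = float(max(af.max(), bf.max()) - min(af.min(), bf.min()))
    if data_range == 0:
        raise ValueError("mSSIM is undefined for a zero dynamic range")
    return float(
        structural_similarity(
            af, bf, win_size=SSIM_WINDOW, K1=SSIM_K1, K2=SSIM_K2, data_range=data_range
        )
    )


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB, ``10·log10(peak² / MSE)`` with `a`
    as the reference; identical images give ``inf``."""
    af, bf = _check_pair(a, b)
    mse = float(np.mean((af - bf) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(_peak(np.asarray(a)) ** 2 / mse))


def nrmse(a, b) -> float:
    """Root-mean-square error of `b` against reference `a`, divided by the
    RMS of `a`; 0 means identical images."""
    af, bf = _check_pair(a, b)
    denom = np.sqrt(np.mean(af**2))
    if denom == 0:
        raise ValueError("NRMSE is undefined for a zero-norm reference")
    return float(np.sqrt(np.mean((af - bf) ** 2)) / denom)


def similarity_report(
    stack: VideoStack, z_slice: int, mode: str = "vs_first"
) -> pd.DataFrame:
    """All four metrics for every frame pair of one z-slice.

    ``vs_first`` pairs every later frame with frame 0 (static scenes);
    ``vs_previous`` pairs consecutive frames (evolving scenes).  The frame-0
    self-pair is excluded.  Infinite PSNR values are flagged in the
    ``psnr_infinite`` column.
    """
    stack = as_video_stack(stack)
    if mode not in ("vs_first", "vs_previous"):
        raise ValueError(f"mode must be 'vs_first' or 'vs_previous', got {mode!r}")
    if not 0 <= z_slice < stack.n_slices:
        raise ValueError(f"z_slice {z_slice} out of range [0, {stack.n_slices})")
    rows = []
    for t in range(1, stack.n_frames):
        ref_idx = 0 if mode == "vs_first" else t - 1
        ref = stack.data[ref_idx, z_slice]
        img = stack.data[t, z_slice]
        p = psnr(ref, img)
        rows.append(
            {
                "frame": t,
                "reference_frame": ref_idx,
                "pcc": pcc(ref, img),
                "mssim": mssim(ref, img),
                "psnr": p,
                "psnr_infinite": not np.isfinite(p),
                "nrmse": nrmse(ref, img),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "reference_frame",
            "pcc", "mssim", "psnr", "psnr_infinite", "nrmse",
        ],
    )


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of each metric over frame pairs (infinite PSNRs excluded
    from the PSNR row)."""
    out = []
    for metric in ("pcc", "mssim", "psnr", "nrmse"):
        vals = report[metric].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        out.append(
            {
                "metric": metric,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_pairs": int(len(vals)),
            }
        )
    return pd.DataFrame(out)


def sd_time_projection(stack: VideoStack, z_slice: int) -> np.ndarray:
    """Per-pixel standard deviation across time at one z-slice.

    An all-black result means no variation between frames over time, i.e. a
    perfect drift correction of static content (up to noise).
    """
    stack = as_video_stack(stack)
    if not 0 <= z_slice < stack.n_slices:
        raise ValueError(f"z_slice {z_slice} out of range [0, {stack.n_slices})")
    plane = stack.data[:, z_slice].astype(np.float64)
    ddof = 1 if stack.n_frames > 1 else 0
    return plane.std(axis=0, ddof=ddof)
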