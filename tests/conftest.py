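import numpy as np
import pytest

from driftcorr import synthetic as syn


@pytest.fixture(scope="session")
def small_volume():
    """A compact cell-like volume + mask shared across tests."""
    return syn.generate_cell_volume(shape=(16, 64, 64), seed=3, n_blobs=10)


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth, structured 64x64 test image (periodic-friendly)."""
    rng = np.random.default_rng(42)
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 3.0, mode="wrap")
    return img - img.min()


@pytest.fixture(scope="session")
def integer_drift_video(small_volume):
    """10-frame video with known integer drift, plus its ground truth."""
    volume, _mask = small_volume
    t = np.arange(10, dtype=float)
    traj = np.column_stack([t, -(t // 2), np.minimum(t, 3)])  # dx, dy, dz
    video, truth = syn.generate_drifting_video(
        volume, 10, syn.DriftSpec(kind="explicit", explicit=traj)
    )
    return video, truth


def fourier_shift_image(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sub-pixel circular shift via the Fourier shift theorem (exact for
    band-limited content); the independent way to synthesize fractional
    displacements without touching the package's interpolation code."""
    from scipy.ndimage import fourier_shift

    return np.fft.ifft2(fourier_shift(np.fft.fft2(image), (dy, dx))).real


def brute_force_ccm(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Spatial-domain circular cross-correlation of mean-subtracted images,
    indexed by displacement (row, col) with numpy wrap-around; the oracle
    for the transform-domain implementation."""
    ref = np.asarray(ref, float) - np.mean(ref)
    mov = np.asarray(mov, float) - np.mean(mov)
    n, m = ref.shape
    out = np.empty((n, m))
    for dr in range(n):
        for dc in range(m):
            out[dr, dc] = np.sum(ref * np.roll(mov, (-dr, -dc), axis=(0, 1)))
    return out
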