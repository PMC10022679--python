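# driftcorr

Drift correction for 2D/3D time-lapse fluorescence microscopy, and channel
registration for misaligned 3D multichannel images.

Thermal expansion of microscope parts and sample movement produce an
unwanted rigid translation ("drift") of the imaged volume over time, in the
imaging plane (lateral, *x*/*y*) and along the optical axis (axial, *z*).
`driftcorr` estimates and removes this drift after acquisition, so that
static structures stay put across frames and downstream visualization and
quantification are meaningful.  It is aimed at microscopists and image
analysts who have single- or multi-channel TIFF video stacks and want a
scriptable, reproducible correction with a persistent record of what was
done.

## Method

Rather than registering volumes in 3D, each time point *I(t, z, y, x)* is
collapsed to 2D intensity projections (maximum or average) and the drift is
estimated from 2D cross-correlations — fast, and robust because projection
pools signal over an entire axis:

1. **Lateral stage** — *z*-projections give a 2D video *P(t, y, x)*.  For a
   frame pair (reference, moving) the circular cross-correlation matrix
   (CCM) is computed in the discrete Hartley domain: both images are
   mean-subtracted and Hartley-transformed, the spectra combined as the
   complex-conjugate product of the corresponding Fourier spectra, and the
   product inverse-transformed.  The CCM is up-scaled with a bicubic spline
   (default 10×, i.e. 0.1 px nominal precision), rescaled so its extrema
   equal the Pearson correlation of the two images aligned at the
   corresponding shifts, and the displacement (dx, dy) is read off the
   global maximum.
2. **Lateral correction** — each frame is translated by the negated
   estimate (bicubic interpolation; integer shifts are exact copies).
3. **Axial stage** — *y*-projections *P(t, z, x)* of the laterally
   corrected stack give dz from the row component of the same estimator
   (the *x* component is discarded); correction interpolates linearly
   between slices.

The reference is either frame 0 (static scenes) or the previous frame
(evolving scenes; pairwise shifts are cumulated).  The result is a
**drift table** — cumulative (dx, dy, dz) per frame relative to frame 0 —
written as CSV and re-applicable to any other channel acquired
simultaneously, plus a settings file, a drift plot and the corrected stack.
Misaligned channels of a 3D multichannel image (chromatic aberration,
multi-camera offsets) are registered by treating channels as time frames;
a table measured on a calibration slide can be re-applied to any image
acquired under the same conditions.

Validation utilities include four image-similarity metrics (Pearson
correlation, mean structural similarity, peak signal-to-noise ratio,
normalized RMSE), temporal standard-deviation projections, and a synthetic
data generator that builds drifting videos with known ground truth at
calibrated signal-to-noise ratios (SNR = mean foreground / mean
background).

## Worked example

```python
import numpy as np
from driftcorr import synthetic as syn
from driftcorr import RegistrationSettings, register_video

# a synthetic cell volume duplicated 25 times with known drift injected
volume, mask = syn.generate_cell_volume(seed=0)
drift = syn.DriftSpec(kind="explicit",
                      explicit=np.column_stack([0.5 * np.arange(25),
                                                -0.25 * np.arange(25),
                                                0.1 * np.arange(25)]))
video, truth = syn.generate_drifting_video(volume, n_frames=25, drift=drift)
video = syn.homogenize_background(video, mask, noise_sd=400, seed=1)
print("SNR:", round(syn.compute_snr(video, mask), 1))

result = register_video(video, RegistrationSettings(projection_method="average"))
print(result.table.to_frame().iloc[[1, 12, 24]].to_string(index=False))
```

prints

```
SNR: 29.8
 frame  dx_px  dy_px  dz_slices
     1    0.5   -0.2        0.1
    12    6.0   -3.0        1.2
    24   12.0   -6.0        2.4
```

The estimated table matches the injected drift (0.5, −0.25, 0.1) per frame
to the 0.1-px precision of the default 10× up-scaling: the maximum absolute
error against the ground truth here is 0.05 px in *y* and 0 in *x* and *z*.
`result.corrected` holds the corrected stack and `result.diagnostics` the
per-pair peak correlations.

The same workflow is available as a scikit-learn-style transformer —
`DriftCorrector(...).fit(channel1).transform(channel2)` — and from the
shell:

```sh
driftcorr simulate -o data --seed 0 --frames 25
driftcorr register data/video.tif -o run --projection average
driftcorr apply other_channel.tif --settings-file run/settings.json -o run2
driftcorr channels beads.tif -o aligned
driftcorr metrics run/corrected.tif -o report.csv
```

Every run folder contains `corrected.tif`, `drift_table.csv`,
`drift_plot.png`, `settings.json` and a `run_manifest.json`; a settings
file alone (it names the drift table) suffices to re-apply a correction.
`--low-memory` streams the input one frame at a time and produces
bit-identical drift tables.

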