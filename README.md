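# snapcube

A processing and validation toolkit for **snapshot-mosaic hyperspectral
cameras** (spectrally resolved detector arrays, SRDAs) of the kind used in
hyperspectral laparoscopy. These cameras carry a periodic p×p tile of
micro-optical bandpass filters over the sensor, so one raw frame encodes a
complete — but spatially subsampled and pattern-modulated — hypercube.
`snapcube` implements the full software stack needed to turn raw mosaic
frames into validated reflectance data, plus a forward simulator so the
entire chain can be exercised and tested with no hardware.

It is aimed at researchers building or validating SRDA-based imaging rigs
(endoscopy, microscopy, bench-top spectral imaging) who need reproducible,
scriptable implementations of the standard validation protocol: white/dark
calibration, demosaicing, USAF-1951 resolution metrology and spectral RMSE
against reference tiles.

## What it computes

**Hypercube reconstruction and calibration.** With mosaic period `p`, band
`b` at tile cell `(r_b, c_b)`:

    cube[i, j, b] = frame[i·p + r_b, j·p + c_b]

and flat-field calibration against temporally averaged white (95 %
Spectralon tile) and dark references:

    R = ρ_white · (I − D) / (W − D),   ρ_white = 0.95

with NaN flagging where `W − D` is degenerate, glare clipping at R = 1, and
ROI mean spectra.

**Demosaicing** of the full-resolution raw frame by three methods:
white-reference division (WRC), Fourier notch filtering of the mosaic
harmonics (LPF), and filter convolution (FC) with a p×p per-cell response
kernel `H` and its reciprocal, followed by an unsharp mask.

**Spatial resolution** via USAF-1951 geometry. Element (g, e) has
`2^(g + (e−1)/6)` line pairs/mm, i.e. a bar width of `1/(2·2^(g+(e−1)/6))`
mm. A sinusoid is fitted to the intensity profile across each three-bar
element and its Michelson contrast

    C = (S_max − S_min) / (S_max + S_min)

decides resolution at the 20 % cutoff (inclusive); the finest passing
element per orientation is the resolution limit.

**Spectral validation.** Reference spectra are linearly resampled onto the
camera band centers (out-of-range bands excluded, never extrapolated), an
optional least-squares gain `g = ⟨m, r⟩/⟨r, r⟩` aligns relative-reflectance
scales, and agreement is reported as percent RMSE with mean ± sample SD
across tiles.

**Dual-camera registration** (spectral-mean collapse, binarization,
least-squares affine from control points, per-band bilinear warp) and
**pseudo-RGB rendering** from the bands nearest 700.0 / 546.1 / 435.8 nm.

**Forward simulation.** A linear sensor model — Gaussian filter bank,
halogen-like illuminant, dark offset, shot and read noise, seeded —
generates raw mosaic frames, white/dark references, flat reflectance tiles,
USAF bar targets and sinusoidal test patterns. Camera presets cover a
16-band 4×4 VIS camera (461–597 nm), a 15-band 4×4 red/NIR camera
(614–853 nm) and a 24-band 5×5 NIR camera (669–949 nm).

## Worked example

End-to-end spectral fidelity on the simulator: eight colored reflectance
tiles, 30 noisy frames each, full simulate → average → reconstruct →
calibrate → ROI-spectrum → RMSE chain with the VIS camera preset:

```python
import numpy as np
import snapcube as sc
from snapcube.srda_sim import AcquisitionModel, halogen_illuminant, TILE_NAMES
from snapcube.reconstruction import (reconstruct_hypercube, calibrate,
                                     roi_mean_spectrum, temporal_average)
from snapcube.spectral_validation import resample_reference, spectral_rmse, rmse_table
from snapcube.formats_io import SpectralCurve

grid = np.arange(360.0, 1101.0)
cam = sc.preset("vis")
model = AcquisitionModel(illuminant=halogen_illuminant(grid), seed=42)
cal = sc.make_reference_pair(cam, model, (64, 64), n_frames=30)

rmses = []
for name in TILE_NAMES[:-1]:          # the eight colored tiles
    spectrum = sc.tile_spectrum(name, grid)
    frames = sc.simulate_sequence(sc.make_tile_scene(spectrum, (64, 64)), cam, model, 30)
    cube = reconstruct_hypercube(temporal_average(frames))
    refl, _ = calibrate(cube, cal)
    curve = roi_mean_spectrum(refl, np.ones(refl.spatial_shape, bool), name)
    rr = resample_reference(spectrum, cam.band_centers_nm)
    measured = SpectralCurve(curve.wavelengths_nm[rr.kept], curve.values[rr.kept])
    rmses.append(spectral_rmse(measured, rr.curve))
    print(f"{name:8s} RMSE = {rmses[-1]:.2f}%")

summary = rmse_table(np.array(rmses))
print(f"mean +/- SD = {summary.rounded()[0]:.2f} +/- {summary.rounded()[1]:.2f} %")
```

Output:

```
red      RMSE = 0.13%
green    RMSE = 0.24%
blue     RMSE = 0.25%
yellow   RMSE = 0.14%
violet   RMSE = 0.08%
cyan     RMSE = 0.18%
orange   RMSE = 0.13%
purple   RMSE = 0.09%
mean +/- SD = 0.16 +/- 0.06 %
```

Each line is the percent RMSE between the recovered per-band reflectance
and the generating tile spectrum sampled at the camera's band centers; the
sub-0.3 % values show the calibration chain is limited only by
band-integration effects and residual averaged noise. (A real rig adds
optics, stray light and filter cross-talk on top of this — see
`docs/methods.md` for what the simulator does and does not emulate.)

The same stages are available from the shell:

```sh
snapcube simulate --camera vis --scene scene.json --frames 30 --seed 7 --out seq.tif
snapcube reconstruct --camera vis --frames seq.tif --white w.tif --dark d.tif \
    --clip-glare 1.0 --out cube.tif
snapcube demosaic --method fc --camera vis --in seq.tif --out demosaiced.tif
snapcube resolution --in demosaiced.tif --elements elements.json --report res.json
snapcube validate-spectra --cube cube.tif --masks rois.json --refs refs/red.csv \
    --report rmse.csv
snapcube register --src rnir_cube.tif --dst vis_cube.tif --points pairs.csv --out reg.tif
snapcube render --cube cube.tif --out rgb.png
```

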