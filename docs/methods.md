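# Methods

This note documents the models, numerical choices and limitations behind
`snapcube`, in the order data flows through the toolkit.

## Sensor model

A snapshot-mosaic camera is described statically by a `CameraSpec`: a p×p
`MosaicLayout` mapping tile cells to band indices, strictly ascending band
centers, a bit depth and (for simulation only) per-band filter FWHMs.
Vendors do not publish exact band centers or the cell-to-band assignment,
so the presets place B centers uniformly over each camera's realized
spectral endpoints (VIS 461–597 nm / 16 bands / 4×4; red-NIR 614–853 nm /
15 bands / 4×4; NIR 669–949 nm / 24 bands / 5×5) and assign bands row-major
within the tile in ascending wavelength, overridable via `cell_band` in the
camera JSON. Cameras with fewer bands than tile cells (15 of 16, 24 of 25)
leave the bottom-right cell inactive; its samples are never read during
reconstruction. Filter transmissions are unit-peak Gaussians,
`exp(−4 ln2 (λ−c_b)²/FWHM_b²)`, with preset FWHMs of 12/16/18 nm
(VIS/RNIR/NIR) — roughly λ/Δλ-constant, in the range typical of
Fabry–Pérot mosaic filters.

## Reconstruction and calibration

Raw frames whose dimensions are not divisible by the period are cropped by
dropping trailing rows/columns, keeping the mosaic phase anchored at the
top-left origin. Reconstruction is pure index bookkeeping
(`cube[i,j,b] = frame[i·p+r_b, j·p+c_b]`), so it commutes with temporal
averaging; the toolkit averages raw frames first because it is cheaper and
mathematically identical.

Calibration uses `R = ρ_white (I − D)/(W − D)` with ρ_white = 0.95, the
reflectance of the Spectralon white tile, so output is absolute-referenced
reflectance; passing `white_reflectance=1.0` reproduces the
relative-reflectance convention instead. Pixels with
`W − D ≤ 10⁻⁶ × full scale` become NaN (counted in the returned report) and
are excluded from every downstream mean. Glare handling clips reflectance
above 1.0 rather than discarding pixels, so camera ROIs remain comparable
with spectrometer footprints that cannot be glare-masked.

## Demosaicing

All three methods return both a physical-scale field (`raw_image`) and a
min–max normalized display image (`image`; an exactly constant field maps
to zeros). The distinction matters: min–max display normalization
stretches whatever residual a near-flat field has to the full [0, 1] range,
so quantitative statements about flattening residuals or profile contrast
are made on `raw_image`.

* **WRC** divides by the (averaged) white mosaic wherever it exceeds an
  epsilon guard; the per-cell gains cancel exactly, and the result is
  invariant to any per-cell gain field present in both images.
* **LPF** protects a central Fourier disk of radius `keep_radius_frac` ×
  Nyquist (default `1/(2p)`, halfway to the first mosaic harmonic at 1/p)
  and zeroes outside bins (magnitude and phase together) whose magnitude
  exceeds `notch_threshold` (default 0.1) times the largest non-DC
  magnitude. Both defaults are starting points — the threshold is
  inherently data-dependent — but they remove all dominant mosaic
  harmonics of the simulated flat scenes (residual ≈ 0.2 % of mean) while
  passing low-frequency scene content with < 2 % amplitude error.
* **FC** forms the p×p kernel `H` of per-cell sums normalized to unit mean
  over active cells (inactive cells are set to 1, the neutral value), and
  its reciprocal `H⁻¹`. Both are convolved over the raw frame, each branch
  is normalized to unit mean, and the two are averaged; an unsharp mask
  (σ = 1 px, amount = 0.5 by default) then restores the sharpness lost to
  the period-sized convolution. Unit-mean branch normalization was chosen
  over min–max because the two branch patterns are equal and opposite to
  first order in the cell-gain variation: mean normalization preserves that
  cancellation (flat-scene residual ≈ 0.4 % with a ±40 % gain spread),
  whereas min–max rescaling breaks it (≈ 7 %) by stretching the two
  patterns asymmetrically. Borders are padded by periodically replicating
  the outermost tile strips, which preserves the mosaic phase up to the
  edge; plain reflection reverses the phase and leaves a period-wide border
  band of first-order artifacts.

## Resolution metrology

USAF-1951 geometry is exact: element (g, e) has `2^(g+(e−1)/6)` line
pairs/mm and bar width `1/(2·2^(g+(e−1)/6))` mm. Reports round to three
decimals (round-half-even) while full precision is returned; note two
printed-value conventions in circulation disagree in the third decimal for
some elements (e.g. 0.445 vs 0.446 for g0e2, 0.354 vs 0.353 for g0e4) —
this package always rounds the exact geometry.

Profiles are extracted perpendicular to the bars with bilinear
interpolation and fitted with `offset + A sin(2πfx + φ)` by bounded
nonlinear least squares, initialized at the geometric bar frequency with
`A₀ = (max−min)/2`, offset at the mean and a coarse 8-point phase search;
the frequency is free within a factor of 3 so small scale errors do not
bias the contrast. A constant profile short-circuits to the exact
zero-amplitude fit. Fitting a sinusoid to an ideal square wave recovers
the Fourier fundamental, whose amplitude exceeds the square-wave half-range
by 4/π; the implied Michelson contrast can therefore exceed 1 on sharp
bars, and `resolution_limit` clamps contrast into [0, 1], since intensity
contrast above 1 is unphysical. An element is resolved when the fitted
contrast is ≥ 0.20 (inclusive boundary); the finest passing element per
bar orientation, converted to millimeters, is the reported limit, and an
orientation where no element passes is reported as unresolved.

## Spectral validation

Reference curves are linearly interpolated at the camera band centers;
band centers outside the reference's span are excluded from the comparison
rather than extrapolated, and the exclusion indices are returned so the
measured curve is trimmed identically. Scale alignment is the closed-form
least-squares gain `⟨m, r⟩/⟨r, r⟩`, returned rather than applied so one
gain (fitted on a single tile or tissue) can be reused across curves.
Percent RMSE is computed with reflectance on the 0–1 scale; per-tile values
aggregate to the arithmetic mean and the sample (n−1) standard deviation,
the convention that reproduces the published summary rows exactly. Tile
comparisons apply no scale alignment by default (alignment is a
relative-reflectance correction for tissue measurements). With a single
value the SD is reported as 0 and flagged undefined.

## Registration and rendering

Cubes collapse to grayscale by the per-pixel mean over valid bands;
binarization is a simple `≥ threshold` mask (the threshold is exposed, not
chosen automatically). The affine transform (2×3, source→destination,
0-based row/col pixel centers) is the least-squares solution of
`dst ≈ A·src + t`, exact for three non-collinear pairs; degenerate point
sets raise. Warping pulls each destination pixel through the inverse map
with per-band bilinear interpolation (nearest-neighbor available for
masks); destination pixels mapping outside the source domain are NaN.
Pseudo-RGB picks the bands nearest 700.0 / 546.1 / 435.8 nm (ties to the
lower index), clips to [0, 1], and applies no white balance or gamma; a
1–99 percentile stretch is available behind a flag for display.

## Forward simulator

The sensor model is linear: counts = dark + gain · Σ_λ L(λ) R(λ) T_b(λ) Δλ
on a 1-nm rectangular quadrature grid covering every filter to ±3 FWHM,
clipped to the digital range. Defaults: dark level 64 counts, read noise
2 counts RMS, shot noise as a Gaussian with variance equal to the signal in
counts (adequate above ~100 counts; the simulator is not intended for
photon-starved regimes), 10-bit range, and an auto-gain that puts a
unit-reflectance scene at 90 % of full scale in the brightest band. The
default illuminant is a 3200 K Planck curve — a halogen source, dim at
short visible wavelengths, which reproduces the light-starved blue end of
a real rig. All randomness flows from one seeded generator; a sequence of
frames draws independent noise from it, and the same seed reproduces
byte-identical frames.

Scenes are separable, `R(x, y, λ) = spatial(x, y) · spectrum(λ)`: flat
tiles (eight smooth synthetic color-tile spectra with transition scales
≥ 25 nm, plus white at 0.95 and a NIR-rising tile), wavelength-flat USAF
three-bar charts rendered with exact sub-pixel area coverage (both bar
orientations; probe segments generated alongside), and wavelength-flat
sinusoids. The reference pair generator images the 0.95 tile and a
blocked-light path with the same model and temporal averaging.

**What the simulator does not emulate** — and hence what passing tests do
not show about real hardware: laparoscope optics (PSF, vignetting, the
circular field), specular glare (tests plant saturated pixels by hand),
filter cross-talk and out-of-band leakage, non-Gaussian filter shapes,
wavelength-dependent QE beyond what the illuminant absorbs,
working-distance dependence of the calibration, and chromatic misalignment
between dual cameras beyond a global affine. Simulator-based bounds
(e.g. < 0.5 % noise-free tile RMSE) characterize the software chain, not
an instrument.

## Problem sizes and tolerances

Tests and examples run at desk scale: 64×64–128×128 rasters, 30-frame
sequences, 8 tiles, 5-point blur sweeps — sizes at which every property is
already measurable with comfortable margins while the full suite stays in
the seconds range. The epsilon guard for calibration denominators is 10⁻⁶
of full scale; sine fits bound the amplitude at ≥ 0 and the frequency
within [f₀/3, 3f₀]; min–max normalization treats ranges below 10⁻⁹
(relative) as constant; warping tolerances (round-trip < 10⁻³ away from
borders) reflect bilinear interpolation error, not the transform estimate,
which is exact to machine precision on noiseless points.
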