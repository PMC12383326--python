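# specsave

Spectrum-aided vision enhancement for gastrointestinal endoscopy images:
convert ordinary white-light (WLI) RGB frames into simulated hyperspectral
reflectance cubes and render narrow-band-imaging-like (NBI-like) enhanced
images in software, with no narrow-band hardware.

## Who this is for

Researchers working on endoscopic image enhancement and computer-aided
diagnosis who want NBI-style vessel/mucosa contrast from standard WLI
captures — for example to preprocess large WLI datasets before training
lesion classifiers — plus the calibration and validation tooling needed to
fit the conversion to a particular endoscope.

## The model

The pipeline is calibrated once per camera from a 24-patch ColorChecker
photographed by the endoscope and measured by a spectrometer (reflectance
380–780 nm). Writing V for a fixed polynomial expansion of a tristimulus
value (constant, linear, cross, square, triple-product and square-root
terms; K = 14), the stages are:

1. **Color correction.** Camera sRGB is decoded and converted to CIE 1931
   XYZ; a correction matrix fitted by least squares absorbs dark current,
   channel cross-talk and response nonlinearity:

       C = XYZ_spectrum · pinv(V),        XYZ_correct = C · V

2. **Spectral reconstruction.** The patch reflectance spectra are
   compressed with mean-centered PCA (eigenvectors EV, six components
   capture essentially all variance of a ColorChecker set); a regression
   maps the expansion of the corrected color, V_color, to PCA scores:

       M = Score · pinv(V_color),
       S(λ), 380–780 nm = mean(λ) + EV · M · V_color

   Applied per pixel this turns an 8-bit frame into a reflectance
   hypercube (H × W × 401 bands at 1 nm).

3. **Narrow-band rendering.** Synthetic narrow-band illuminants are built
   from Cauchy–Lorentz profiles

       f(x; x₀, γ) = (1/πγ) · [1 + ((x − x₀)/γ)²]⁻¹

   centered on the hemoglobin bands x₀ = 415 nm and 540 nm. Band images
   (reflectance-weighted means under each band) are routed to display
   channels (415 → G,B; 540 → R) giving the brown-vessel NBI look. Band
   parameters can be tuned by dual annealing to minimize the mean
   CIEDE2000 difference against target patch colors.

4. **Validation.** CIEDE2000 color differences, SSIM, PSNR, Shannon
   entropy and calibration RMSE.

A synthetic-data module generates everything needed offline: smooth
low-rank reflectance sets, a forward camera model with known ground
truth, and a vascular phantom whose vessels carry 415/540 nm absorption
dips.

## Worked example

```sh
specsave --seed 1 simulate --out-dir demo --phantom-size 128
specsave --verbose calibrate --patches demo/patches.csv \
    --spectra demo/spectra.csv --out demo/bundle.json
specsave convert --image demo/phantom_wli.png --bundle demo/bundle.json \
    --out demo/phantom_save.png
specsave evaluate --image-a demo/phantom_save.png --image-b demo/phantom_wli.png
```

which prints (abridged):

```
INFO specsave: calibrated: RMSE=2.8305e-12, k=3, cumulative variance=0.999629
INFO specsave: wrote demo/phantom_save.png
{
  "ssim": 0.9467225708509963,
  "psnr_db": 21.115895329378553,
  "entropy_a": 4.869807209960743,
  "entropy_b": 5.277778528894633,
  "entropy_diff_pct": 7.729981784956302,
  "rmse": 22.425669321811778
}
```

The calibration RMSE (~1e-12 in XYZ units, Y scale 0–100) reflects a
noiseless synthetic capture: the fitted correction inverts the camera
model exactly. Three principal components already explain 99.96% of this
fixture's spectral variance, so the threshold selector stops at k = 3.
The evaluate report compares the enhanced rendering against the original
white-light frame: structurally similar (SSIM 0.95) but deliberately
different in tone and contrast — the enhancement is the point, not
fidelity to the input.

On the vascular phantom the enhanced rendering raises the
vessel/background Michelson contrast from about 0.13 (white light) to
about 0.22 — the software analogue of hardware NBI's vessel enhancement.

## Layout

- `src/specsave/colorimetry.py` — CIE 1931 color science: sRGB, XYZ, Lab,
  CIEDE2000, bundled observer/illuminant tables
- `src/specsave/calibration.py` — polynomial expansion and correction fit
- `src/specsave/spectral.py` — PCA basis, score regression, hypercube
- `src/specsave/nbi.py` — Lorentzian bands, rendering, dual annealing
- `src/specsave/metrics.py` — SSIM, PSNR, entropy, quality reports
- `src/specsave/fixtures.py` — synthetic data generators
- `src/specsave/io.py`, `cli.py` — CSV/JSON/ENVI/image I/O and the CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
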