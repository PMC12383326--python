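# Methods

This note records the modeling choices behind `specsave`: what each stage
assumes, which defaults matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Colorimetry

All color math uses the CIE 1931 2° standard observer on a uniform
380–780 nm grid at 1 nm (401 bands; 5 or 10 nm subsampling is available
through `WavelengthGrid` for speed). Spectral integration normalizes so a
perfect reflector under the working illuminant has Y = 100; CIELAB is
taken against the working illuminant's white point. sRGB uses the
piecewise IEC 61966-2-1 transfer curve (not a pure 2.2 gamma) and the
standard 4-decimal sRGB/D65 primary matrix. CIEDE2000 implements the full
formula including the blue-region rotation term, with parametric factors
kL = kC = kH = 1; it reproduces the published 34-pair verification set to
the printed 1e-4 precision (the set ships with the package as
`data/ciede2000_reference_pairs.csv`).

The bundled observer and illuminant tables are synthetic stand-ins for
the measured CIE data, regenerable with `scripts/make_tables.py`: the
color-matching functions are the Wyman–Sloan–Shirley multi-lobe
piecewise-Gaussian analytic fit (x̄'s small negative lobe clipped to
zero), and the "D65-like" daylight curve is Planck blackbody radiance at
6504 K normalized to 100 at 560 nm. Both have the right shape but not
the reference values — the white point is (96.8, 100, 112.1) rather than
D65's (95.0, 100, 108.9). Every quantitative property of the pipeline is
self-consistent under these tables (calibration targets, reconstruction,
rendering and validation all use the same ones), so no result in this
package depends on exact CIE tabulations; users who need standards-grade
colorimetry can point `load_cmf`/`load_d65` at their own CSVs.

Negative XYZ values arising from out-of-gamut arithmetic are preserved
during fitting (clipping would bend the least-squares geometry) and
clipped only at render time.

## Camera correction

The correction targets three camera defects: dark current (constant
term), incorrect color separation (linear and cross terms), and nonlinear
response (squares, triple product, square roots). The default expansion
is

    [1, X, Y, Z, XY, XZ, YZ, X², Y², Z², XYZ, √X, √Y, √Z]   (K = 14)

evaluated on camera XYZ scaled to 0–100. The recipe is serialized inside
every calibration bundle, so alternative term lists are pluggable without
ambiguity about what a stored correction means. The fit is an ordinary
least-squares pseudoinverse solve; singular values below 1e-10 of the
largest are truncated, and rank deficiency produces a warning plus the
minimum-norm solution rather than an error. With 24 patches and K = 14
the design matrix is comfortably overdetermined; the condition number
(~1e6, driven by the XYZ product term) costs ~7 digits of the 16
available, which the recovery tests confirm is harmless.

The same expansion is reused for V (expansion of camera XYZ, input to
the correction) and V_color (expansion of corrected XYZ, input to the
spectral regression). This ordering makes the correction's output feed
the reconstruction's input with a single stored recipe.

## Spectral reconstruction

PCA is mean-centered with components' signs fixed (largest-magnitude
element positive) for reproducible serialization. Component count is
either explicit or chosen as the smallest k whose cumulative explained
variance reaches a threshold, default 0.9964, capped at 6. The threshold
and cap mirror the regime in which six components capture essentially
all ColorChecker spectral variance; the achieved ratio is a property of
the data, not a constant, so the selector reports what it found rather
than asserting it. Reconstruction is affine in V_color
(mean + EV·M·V_color); reflectance is clipped to [0, 1] only when a
hypercube is finalized, with the unclipped values retained for
diagnostics.

## Narrow-band simulation

Bands are Cauchy–Lorentz profiles. Defaults: centers 415 and 540 nm (the
hemoglobin absorption bands that hardware NBI filters target), HWHM γ of
15 and 10 nm (FWHM 30/20 nm, typical NBI filter widths), unit weights.
The summed illuminant is peak-normalized, which makes the overall weight
scale a gauge freedom — doubling all weights changes nothing, only
weight ratios matter. Band images are reflectance-weighted means
(Σ power·R / Σ power), so a perfect reflector renders as 1 under any
band. The default display routing (415 → G,B; 540 → R) reproduces the
brown vascular tone of commercial NBI processors and is serialized and
overridable.

The ambiguity of where the Lorentzian correction enters the pipeline was
resolved as band-shape modeling of the illuminant itself; the
alternative reading (a per-wavelength response correction applied to a
fixed illuminant) is not modeled.

Band optimization minimizes the mean CIEDE2000 between patches rendered
under the candidate illuminant and target Lab values, with Lab taken
against a fixed reference white (the working daylight white by default)
rather than each candidate's own white — self-referenced whites would
adapt away exactly the spectral cast the optimizer must discriminate.
The optimizer is SciPy's dual annealing (generalized simulated annealing
with a local-search polish) with a recorded seed; default bounds are
center ±20 nm, γ ∈ [5, 40] nm, weight ∈ [0.1, 10], and the evaluation
budget defaults to 2000 objective calls (~1 s at 24 patches × 401
bands). Degenerate single-point bounds short-circuit to a direct
evaluation. On self-generated targets with true bands inside the bounds
the optimizer recovers centers to well under 2 nm.

## Quality metrics

SSIM uses the original constants (11-tap Gaussian window, σ = 1.5,
k1 = 0.01, k2 = 0.03 on the data range, population covariances); it
matches the scikit-image implementation to 1e-6, which the tests use as
an independent oracle, never as the implementation. PSNR returns an
infinity sentinel for identical images; peak defaults to 255. Entropy is
the 256-bin histogram Shannon entropy in bits. Color inputs are reduced
to linear-light luminance (Y of XYZ) before the greyscale metrics. The
entropy difference in a report is the absolute percent difference
relative to the reference image. Michelson contrast between two pixel
populations uses population means, signed so that a darker foreground
(vessels) is positive.

## Synthetic data

`generate_reflectance_set` draws independent latent coefficients on a
basis of Gaussian bumps (default width 70 nm, centers spanning the grid)
around a smooth mid-grey mean — a generic smooth low-rank ensemble for
PCA and rank tests.

`generate_color_consistent_set` addresses a structural fact about
RGB-to-spectrum reconstruction: color is 3-dimensional, so six
independent latent coordinates can never be recovered from color alone
(metamers collapse). Reconstruction is only well-posed when the scene's
spectra are predictable from color, and this generator realizes exactly
that regime: each patch color is drawn as an exact 8-bit sRGB triple
(rejection-sampled so its spectrum fits in [0, 1] with margin); three
latent degrees of freedom are pinned so the spectrum's XYZ equals that
color exactly, and the remaining degrees of freedom are a fixed linear
map of the polynomial expansion of that XYZ (globally shrunk, never
per-patch, if the [0, 1] bound binds — preserving the affine
latent-to-expansion relation). The set has exact latent rank 6, and the
full calibrate → reconstruct loop recovers it to machine precision,
which is what makes end-to-end recovery testable at 1e-4 rather than
limited by metamer ambiguity. Real mucosa only approximately satisfies
color–spectrum predictability, so passing these tests demonstrates that
the pipeline's algebra is exact, not that reconstruction of arbitrary
tissue spectra is accurate.

The synthetic camera applies channel mixing and dark current in linear
RGB, the sRGB curve, Gaussian noise in the encoded domain (σ in 8-bit
code values), and optional quantization. Recovery tests use unquantized
captures: 8-bit quantization alone injects ~0.1 RMSE on the 0–100 XYZ
scale, which would swamp the exactness being tested; noise-robustness
tests use quantized captures. For the image-path round trip the chart
image's pixels are the exact 8-bit patch colors, so quantization costs
nothing there.

The vessel phantom is a red-rich sigmoidal mucosa reflectance under a
smooth ±8% brightness field, with vessels grown as seeded random walks
dilated to ~3 px tubes (walks added until the dilated mask reaches the
requested density; achieved coverage lands within about +10%). Vessel
reflectance is the background times 1 − dip_depth·D(λ), D being
peak-normalized Lorentzian dips at 415 nm (γ = 20) and 540 nm (γ = 25,
relative strength 0.9), a coarse stand-in for oxyhemoglobin's Soret and
Q bands. It emulates none of real tissue optics (no scattering, depth
structure, or specular highlights); it exists to make the directional
contrast claim testable: under the default bands the enhanced rendering
roughly doubles vessel/background Michelson contrast relative to the
white-light rendering.

## Problem sizes and numerical choices

Default test and acceptance sizes: 24 patches, 64×64 chart images,
256×256 phantoms, 2000 annealing evaluations — each chosen as the
smallest size at which the corresponding property is stable across
seeds; the whole suite runs in well under a minute on one core.
Pseudoinverse truncation is 1e-10 relative throughout. Hypercubes from
the phantom generator are float32 (a 256×256×401 cube is ~100 MB);
reconstruction outputs are float64.

## Known limitations

- The bundled observer/illuminant tables are analytic approximations
  (see above); absolute colorimetry against CIE reference data is out of
  scope unless users supply measured tables.
- Calibration is spatially uniform: no vignetting or per-image white
  balance.
- Single frames only; no video, no DICOM.
- The NBI rendering is a display convention, not a physical simulation
  of narrow-band light transport in tissue; no claim of fidelity to any
  commercial NBI processor is made or tested.
- Reconstruction quality on real scenes is bounded by how strongly the
  scene's spectra correlate with color, a premise the synthetic fixtures
  satisfy by construction.
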