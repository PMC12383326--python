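"""Synthetic data generation.

Everything the pipeline consumes can be generated here offline: smooth
ColorChecker-like reflectance sets, a forward camera model (the inverse
problem the calibration solves), and a vascular endoscopy phantom whose
vessels carry hemoglobin-like absorption dips at 415 and 540 nm.

Every generator is a pure function of its parameters and seed.

Two reflectance generators are provided:

* :func:`generate_reflectance_set` draws independent latent coefficients
  on a smooth Gaussian-bump basis — a generic low-rank spectral ensemble
  for PCA and rank tests.
* :func:`generate_color_consistent_set` draws spectra from a latent
  manifold in which the spectral shape is a deterministic smooth function
  of the patch color. Reconstruction of a full spectrum from three color
  coordinates is only well-posed when the scene's spectra are predictable
  from color; this generator realizes exactly that regime, with exact
  latent rank ``n_latent``, so the full calibrate-reconstruct loop can be
  validated against ground truth with no metamer ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import ExpansionRecipe, expand_variables
from .colorimetry import (
    CMFTable,
    DEFAULT_GRID,
    IlluminantSpectrum,
    WavelengthGrid,
    linear_rgb_to_xyz,
    spectrum_to_xyz,
    srgb_decode,
    srgb_encode,
    xyz_to_linear_rgb,
)
from .nbi import lorentz_profile
from .spectral import Hypercube

__all__ = [
    "SyntheticCamera",
    "PatchMeasurement",
    "VesselPhantom",
    "generate_reflectance_set",
    "generate_color_consistent_set",
    "simulate_capture",
    "generate_vessel_phantom",
    "patch_image",
]


def _bump_basis(grid: WavelengthGrid, n_latent: int, smoothness: float) -> np.ndarray:
    """(B, k) matrix of Gaussian bumps spanning the grid, peak 1."""
    w = grid.wavelengths
    centers = np.linspace(w[0] + 20.0, w[-1] - 20.0, n_latent)
    return np.exp(-0.5 * ((w[:, None] - centers[None, :]) / smoothness) ** 2)


def _mean_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Smooth mid-grey reflectance with a gentle long-wavelength rise."""
    w = grid.wavelengths
    return 0.30 + 0.10 / (1.0 + np.exp(-(w - 600.0) / 60.0))


def generate_reflectance_set(
    n: int = 24,
    n_latent: int = 6,
    smoothness: float = 70.0,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
    clip: bool = True,
) -> np.ndarray:
    """Smooth random reflectance spectra of exact latent rank ``n_latent``.

    spectra = mean + basis @ coefficients, with seeded Gaussian
    coefficients on a bump basis of the stated width (nm). With
    ``clip=False`` the centered set has exact rank ``n_latent``; clipping
    to [0, 1] (the default) can only reduce values already out of range.

    Returns an (n, B) array.
    """
    if not 1 <= n_latent <= n:
        raise ValueError(f"need n >= n_latent >= 1, got n={n}, n_latent={n_latent}")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive (nm)")
    rng = np.random.default_rng(seed)
    basis = _bump_basis(grid, n_latent, smoothness)
    coeffs = rng.normal(0.0, 0.12, size=(n_latent, n))
    spectra = _mean_spectrum(grid)[None, :] + (basis @ coeffs).T
    return np.clip(spectra, 0.0, 1.0) if clip else spectra


def generate_color_consistent_set(
    n: int = 24,
    n_latent: int = 6,
    smoothness: float = 70.0,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
    cmf: CMFTable | None = None,
    illuminant: IlluminantSpectrum | None = None,
    recipe: ExpansionRecipe = ExpansionRecipe(),
) -> tuple[np.ndarray, np.ndarray]:
    """Reflectance set whose spectra are a smooth function of their color.

    Each patch color is first drawn as an exact 8-bit sRGB triple; the
    spectrum is then built on an ``n_latent``-dimensional bump basis so
    that (a) its XYZ under ``illuminant``/``cmf`` equals the patch color's
    XYZ exactly, and (b) the remaining latent degrees of freedom are a
    fixed linear map of the polynomial expansion of that XYZ. The set has
    exact latent rank ``n_latent`` and zero metamer ambiguity, which makes
    it the ground truth for end-to-end reconstruction tests.

    Returns ``(spectra (n, B), patch sRGB uint8 (n, 3))``.
    """
    from .colorimetry import load_cmf, load_d65

    if not 3 <= n_latent <= n:
        raise ValueError(f"need n >= n_latent >= 3, got n={n}, n_latent={n_latent}")
    cmf = cmf if cmf is not None else load_cmf(grid=grid)
    illuminant = illuminant if illuminant is not None else load_d65(grid=grid)
    rng = np.random.default_rng(seed)

    mean = _mean_spectrum(grid)
    basis = _bump_basis(grid, n_latent, smoothness)                   # (B, k)
    xyz0 = spectrum_to_xyz(mean, illuminant, cmf)
    A = spectrum_to_xyz(basis.T, illuminant, cmf).T                   # (3, k)
    A_pinv = np.linalg.pinv(A)

    # distinct mid-gamut 8-bit patch colors, each rejection-sampled so the
    # color-pinned spectral component stays comfortably inside [0, 1]
    chosen: list[tuple[int, int, int]] = []
    for _ in range(200_000):
        if len(chosen) == n:
            break
        cand = tuple(int(v) for v in rng.integers(60, 211, size=3))
        if cand in chosen:
            continue
        xyz_c = 100.0 * linear_rgb_to_xyz(srgb_decode(np.asarray(cand, np.uint8)))
        pinned = mean + basis @ (A_pinv @ (xyz_c - xyz0))
        if pinned.min() >= 0.06 and pinned.max() <= 0.94:
            chosen.append(cand)
    if len(chosen) < n:
        raise RuntimeError("could not sample enough in-gamut patch colors")
    rgb = np.asarray(chosen, dtype=np.uint8)
    xyz = 100.0 * linear_rgb_to_xyz(srgb_decode(rgb))                 # (n, 3)

    # 3 latent dof pinned by color, the rest a fixed linear map of the
    # expanded color (constant term included -> affine in the expansion)
    c_color = A_pinv @ (xyz - xyz0).T                                 # (k, n)
    _, _, vt = np.linalg.svd(A)
    null = vt[3:].T                                                   # (k, k-3)
    vexp = expand_variables(xyz, recipe).T                            # (K, n)
    mix = rng.normal(size=(n_latent - 3, len(recipe)))
    z = mix @ vexp
    z = z - z.mean(axis=1, keepdims=True)
    z = 0.25 * z / np.maximum(z.std(axis=1, keepdims=True), 1e-12)
    coeffs = c_color + null @ z                                       # (k, n)

    # shrink the free (null-space) part globally if any spectrum leaves
    # [0, 1]; a single global factor keeps the latent-to-color map affine
    # (and cannot reach zero, because the pinned part has margin 0.06)
    margin = 0.02
    for _ in range(60):
        spectra = mean[None, :] + (basis @ coeffs).T
        if spectra.min() >= margin and spectra.max() <= 1.0 - margin:
            break
        z *= 0.8
        coeffs = c_color + null @ z
    spectra = mean[None, :] + (basis @ coeffs).T
    if spectra.min() < 0.0 or spectra.max() > 1.0:
        raise RuntimeError(
            "could not fit color-consistent spectra inside [0, 1]; "
            "the drawn colors are outside the representable gamut"
        )
    return spectra, rgb


@dataclass(frozen=True)
class SyntheticCamera:
    """Forward model mapping scene XYZ to the camera's 8-bit sRGB output.

    The model applies, in linear-RGB space, a channel-mixing matrix
    (incorrect color separation) and a dark-current offset, then the sRGB
    transfer curve, additive Gaussian noise in the encoded domain
    (``noise_sigma`` in 8-bit code values), and optional quantization.
    The mixing matrix must be invertible, so a noiseless, unquantized
    capture is exactly invertible by the polynomial calibration.
    """

    channel_mixing: np.ndarray = field(default_factory=lambda: np.eye(3))
    dark_current: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.channel_mixing, dtype=float)
        d = np.asarray(self.dark_current, dtype=float)
        if A.shape != (3, 3) or d.shape != (3,):
            raise ValueError("mixing must be 3x3 and dark current length 3")
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("channel mixing matrix must be invertible")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        object.__setattr__(self, "channel_mixing", A)
        object.__setattr__(self, "dark_current", d)

    @classmethod
    def realistic(cls, noise_sigma: float = 0.0, seed: int = 0) -> "SyntheticCamera":
        """A mildly miscalibrated endoscope-like camera."""
        mixing = np.array(
            [
                [0.92, 0.06, 0.02],
                [0.04, 0.90, 0.06],
                [0.02, 0.07, 0.91],
            ]
        )
        return cls(mixing, np.array([0.02, 0.015, 0.025]), noise_sigma, seed)

    def capture(self, xyz_scene: np.ndarray, quantize: bool = True) -> np.ndarray:
        """Scene XYZ (N, 3; Y scale 0-100) -> camera sRGB.

        Returns uint8 when ``quantize`` else float in [0, 1].
        """
        rng = np.random.default_rng(self.seed)
        lin = xyz_to_linear_rgb(np.asarray(xyz_scene, float) / 100.0)
        lin = lin @ self.channel_mixing.T + self.dark_current
        enc = srgb_encode(lin)
        if self.noise_sigma > 0:
            enc = enc + rng.normal(0.0, self.noise_sigma / 255.0, size=enc.shape)
        enc = np.clip(enc, 0.0, 1.0)
        if quantize:
            return np.round(255.0 * enc).astype(np.uint8)
        return enc


@dataclass(frozen=True)
class PatchMeasurement:
    """One ColorChecker patch: camera color plus spectrometer reflectance."""

    patch_id: int
    camera_rgb: np.ndarray
    reflectance: np.ndarray


def simulate_capture(
    spectra: np.ndarray,
    camera: SyntheticCamera,
    illuminant: IlluminantSpectrum,
    cmf: CMFTable,
    quantize: bool = True,
) -> list[PatchMeasurement]:
    """Photograph reflectance patches with a synthetic camera.

    Renders each spectrum to scene XYZ under the illuminant and passes it
    through the camera's forward model. Patch ids are 1-based.
    """
    spectra = np.asarray(spectra, dtype=float)
    xyz = spectrum_to_xyz(spectra, illuminant, cmf)
    rgb = camera.capture(xyz, quantize=quantize)
    return [
        PatchMeasurement(i + 1, rgb[i], spectra[i]) for i in range(spectra.shape[0])
    ]


@dataclass(frozen=True)
class VesselPhantom:
    """Synthetic mucosa scene with hemoglobin-like vessels.

    Vessel pixels share the background's smooth reflectance multiplied by
    ``1 - dip_depth * D(lambda)`` where D is a pair of Lorentzian
    absorption dips at 415 and 540 nm.
    """

    vessel_mask: np.ndarray
    cube: Hypercube
    wli_image: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.vessel_mask.shape != self.wli_image.shape[:2]:
            raise ValueError("mask and image shapes differ")


def _vessel_mask(h: int, w: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk vessel skeletons dilated to tubes, ~``density`` coverage."""
    mask = np.zeros((h, w), dtype=bool)
    target = density * h * w
    structure = np.ones((3, 3), dtype=bool)
    for _ in range(10_000):
        dilated = ndimage.binary_dilation(mask, structure=structure)
        if dilated.sum() >= target:
            break
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, 2 * math.pi)
        for _ in range(int(0.5 * max(h, w))):
            yi, xi = int(y) % h, int(x) % w
            mask[yi, xi] = True
            angle += rng.normal(0.0, 0.25)
            y += math.sin(angle)
            x += math.cos(angle)
    return ndimage.binary_dilation(mask, structure=structure)


def generate_vessel_phantom(
    height: int = 256,
    width: int = 256,
    vessel_density: float = 0.08,
    dip_depth: float = 0.5,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
    cmf: CMFTable | None = None,
    illuminant: IlluminantSpectrum | None = None,
) -> VesselPhantom:
    """Generate the vascular endoscopy phantom.

    The background is a smooth, red-rich mucosa-like reflectance with a
    gentle multiplicative brightness field; vessels are seeded random
    walks dilated to tubes. The white-light image is the cube rendered
    under the working daylight illuminant.
    """
    from .colorimetry import load_cmf, load_d65

    if not 0.0 < vessel_density < 0.5:
        raise ValueError(f"vessel_density must be in (0, 0.5), got {vessel_density}")
    if not 0.0 <= dip_depth < 1.0:
        raise ValueError(f"dip_depth must be in [0, 1), got {dip_depth}")
    cmf = cmf if cmf is not None else load_cmf(grid=grid)
    illuminant = illuminant if illuminant is not None else load_d65(grid=grid)
    rng = np.random.default_rng(seed)
    w_nm = grid.wavelengths

    base = 0.30 + 0.45 / (1.0 + np.exp(-(w_nm - 590.0) / 35.0))
    shading = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=max(height, width) / 8.0
    )
    sd = shading.std()
    if sd > 0:
        shading = 1.0 + 0.08 * shading / sd
    else:
        shading = np.ones((height, width))

    mask = _vessel_mask(height, width, vessel_density, rng)
    dips = lorentz_profile(w_nm, 415.0, 20.0) / lorentz_profile(415.0, 415.0, 20.0)
    dips = dips + 0.9 * lorentz_profile(w_nm, 540.0, 25.0) / lorentz_profile(
        540.0, 540.0, 25.0
    )
    dips = np.clip(dips, 0.0, 1.0)

    values = (shading[:, :, None] * base[None, None, :]).astype(np.float32)
    values[mask] *= (1.0 - dip_depth * dips).astype(np.float32)
    cube = Hypercube(grid=grid, values=np.clip(values, 0.0, 1.0))

    xyz = spectrum_to_xyz(cube.values, illuminant, cmf) / 100.0
    wli = np.round(255.0 * srgb_encode(np.clip(xyz_to_linear_rgb(xyz), 0.0, 1.0)))
    return VesselPhantom(
        vessel_mask=mask,
        cube=cube,
        wli_image=wli.astype(np.uint8),
        params={
            "height": height,
            "width": width,
            "vessel_density": vessel_density,
            "dip_depth": dip_depth,
            "seed": seed,
        },
    )


def patch_image(patch_rgb: np.ndarray, height: int = 64, width: int = 64) -> np.ndarray:
    """Tile patch colors into an H x W chart image (uint8).

    Pixel values are exactly the provided 8-bit triples, so the image path
    and the per-patch path see identical colors.
    """
    rgb = np.asarray(patch_rgb, dtype=np.uint8)
    n = rgb.shape[0]
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    yy, xx = np.mgrid[0:height, 0:width]
    cell = (yy * rows // height) * cols + (xx * cols // width)
    return rgb[cell % n]
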