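"""CIE 1931 color science primitives.

Everything downstream (camera calibration, spectral reconstruction,
narrow-band rendering, color-difference validation) is built on the small
set of operations in this module: sRGB decoding/encoding, spectrum-to-XYZ
integration against the CIE 1931 2-degree observer, the CIELAB transform,
and the CIEDE2000 color-difference formula.

Conventions
-----------
* Wavelength grids are uniform, in nanometres, default 380-780 nm at 1 nm
  (401 samples).
* Tristimulus values from spectral integration are normalized so that a
  perfect reflector under the working illuminant has Y = 100.
* ``linear_rgb_to_xyz`` works on the 0-1 scale (multiply by 100 where the
  spectral convention is needed).
* Negative XYZ from out-of-gamut arithmetic is never clipped here; clipping
  is a rendering-time policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "CMFTable",
    "IlluminantSpectrum",
    "DEFAULT_GRID",
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "srgb_decode",
    "srgb_encode",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "spectrum_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "ciede2000",
    "load_cmf",
    "load_d65",
    "equal_energy_illuminant",
    "load_ciede2000_reference",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid in nanometres."""

    start_nm: float = 380.0
    end_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(f"start_nm must be < end_nm, got {self.start_nm} >= {self.end_nm}")
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"grid span {self.start_nm}-{self.end_nm} nm is not an integer "
                f"multiple of step {self.step_nm} nm"
            )

    def __len__(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self))

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("need a 1-D array of at least two wavelengths")
        steps = np.diff(w)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelength grid is not uniform")
        return cls(float(w[0]), float(w[-1]), float(steps[0]))


DEFAULT_GRID = WavelengthGrid(380.0, 780.0, 1.0)


@dataclass(frozen=True)
class CMFTable:
    """Color-matching functions of the CIE 1931 2-degree standard observer."""

    grid: WavelengthGrid
    values: np.ndarray  # (n_bands, 3) columns xbar, ybar, zbar

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid), 3):
            raise ValueError(f"CMF values shape {v.shape} != ({len(self.grid)}, 3)")
        if np.any(v < 0):
            raise ValueError("CMF weights must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def xbar(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def ybar(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def zbar(self) -> np.ndarray:
        return self.values[:, 2]

    def resample(self, grid: WavelengthGrid) -> "CMFTable":
        w = self.grid.wavelengths
        cols = [np.interp(grid.wavelengths, w, self.values[:, i]) for i in range(3)]
        return CMFTable(grid, np.stack(cols, axis=1))


@dataclass(frozen=True)
class IlluminantSpectrum:
    """Relative spectral power distribution of a light source."""

    grid: WavelengthGrid
    power: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.shape != (len(self.grid),):
            raise ValueError(f"power shape {p.shape} != ({len(self.grid)},)")
        if np.any(p < 0):
            raise ValueError("illuminant power must be nonnegative")
        if not np.any(p > 0):
            raise ValueError("illuminant power is identically zero")
        object.__setattr__(self, "power", p)

    def white_point(self, cmf: CMFTable) -> np.ndarray:
        """XYZ of a perfect reflector under this illuminant (Y = 100)."""
        ones = np.ones(len(self.grid))
        return spectrum_to_xyz(ones, self, cmf)

    def resample(self, grid: WavelengthGrid) -> "IlluminantSpectrum":
        p = np.interp(grid.wavelengths, self.grid.wavelengths, self.power)
        return IlluminantSpectrum(grid, p)


# ---------------------------------------------------------------------------
# sRGB transfer curve and primaries (IEC 61966-2-1, D65 white)
# ---------------------------------------------------------------------------

SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)


def srgb_decode(image: np.ndarray) -> np.ndarray:
    """8-bit (or already 0-1 float) sRGB values -> linear RGB in [0, 1].

    Applies the inverse of the piecewise IEC 61966-2-1 electro-optical
    transfer function per channel. Integer input is scaled by 255.
    """
    img = np.asarray(image)
    if img.ndim >= 1 and img.shape[-1] not in (1, 3) and img.ndim >= 3:
        raise ValueError(f"expected 1- or 3-channel image, got shape {img.shape}")
    v = img.astype(float)
    if np.issubdtype(img.dtype, np.integer):
        v = v / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear RGB in [0, 1] -> nonlinear sRGB in [0, 1] (no quantization)."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear sRGB (..., 3) -> CIE XYZ (..., 3) on the 0-1 Y scale."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError(f"last axis must have length 3, got {rgb.shape}")
    return rgb @ SRGB_TO_XYZ.T


def xyz_to_linear_rgb(xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"last axis must have length 3, got {xyz.shape}")
    return xyz @ XYZ_TO_SRGB.T


# ---------------------------------------------------------------------------
# Spectral integration
# ---------------------------------------------------------------------------


def spectrum_to_xyz(
    reflectance: np.ndarray,
    illuminant: IlluminantSpectrum,
    cmf: CMFTable,
) -> np.ndarray:
    """Integrate reflectance(s) against illuminant and observer -> XYZ.

    ``reflectance`` has the grid on its last axis; any leading shape is
    preserved (so whole hypercubes integrate in one call). Normalization:
    a perfect reflector yields Y = 100.
    """
    if illuminant.grid != cmf.grid:
        raise ValueError("illuminant and CMF are on different wavelength grids")
    r = np.asarray(reflectance, dtype=float)
    if r.shape[-1] != len(cmf.grid):
        raise ValueError(
            f"reflectance has {r.shape[-1]} bands but grid has {len(cmf.grid)}"
        )
    weights = illuminant.power[:, None] * cmf.values  # (B, 3)
    k = 100.0 / float(illuminant.power @ cmf.ybar)
    return k * (r @ weights)


# ---------------------------------------------------------------------------
# CIELAB
# ---------------------------------------------------------------------------

_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    d3 = _LAB_DELTA**3
    return np.where(t > d3, np.cbrt(t), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > _LAB_DELTA, u**3, 3 * _LAB_DELTA**2 * (u - 4.0 / 29.0))


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """XYZ (..., 3) -> CIELAB (..., 3) relative to the given white point."""
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError(f"white point must be strictly positive, got {white}")
    t = np.asarray(xyz, dtype=float) / white
    f = _lab_f(t)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_xyz(lab: np.ndarray, white: np.ndarray) -> np.ndarray:
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError(f"white point must be strictly positive, got {white}")
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _lab_f_inv(f) * white


# ---------------------------------------------------------------------------
# CIEDE2000
# ---------------------------------------------------------------------------


def ciede2000(
    lab1: np.ndarray,
    lab2: np.ndarray,
    kL: float = 1.0,
    kC: float = 1.0,
    kH: float = 1.0,
) -> np.ndarray:
    """CIEDE2000 color difference between Lab pairs (vectorized).

    Full formula including the blue-region hue-rotation term. Symmetric in
    its arguments and zero iff the inputs are identical. The parametric
    weighting factors kL, kC, kH default to 1.
    """
    if kL <= 0 or kC <= 0 or kH <= 0:
        raise ValueError("parametric factors kL, kC, kH must be positive")
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((np.abs(a1p) < 1e-300) & (np.abs(b1) < 1e-300), 0.0, h1p)
    h2p = np.where((np.abs(a2p) < 1e-300) & (np.abs(b2) < 1e-300), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    both_chromatic = (C1p * C2p) != 0.0
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(both_chromatic, dh, 0.0)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(both_chromatic, hbp, hsum)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)


# ---------------------------------------------------------------------------
# Bundled observer / illuminant tables
# ---------------------------------------------------------------------------


def _read_table_csv(path) -> tuple[WavelengthGrid, np.ndarray]:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    grid = WavelengthGrid.from_wavelengths(df["wavelength_nm"].to_numpy())
    return grid, df.iloc[:, 1:].to_numpy(dtype=float)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("specsave").joinpath("data", name)))


def load_cmf(path: str | Path | None = None, grid: WavelengthGrid | None = None) -> CMFTable:
    """Load color-matching functions from CSV (bundled table by default).

    The bundled table is a synthetic stand-in for the measured CIE 1931
    2-degree observer: the multi-lobe piecewise-Gaussian analytic fit of
    Wyman, Sloan & Shirley (2013), tabulated 380-780 nm at 1 nm.
    """
    g, values = _read_table_csv(path or _data_path("cmf_cie1931_2deg_synthetic.csv"))
    if values.shape[1] != 3:
        raise ValueError("CMF CSV must have columns wavelength_nm, xbar, ybar, zbar")
    cmf = CMFTable(g, values)
    return cmf.resample(grid) if grid is not None and grid != g else cmf


def load_d65(path: str | Path | None = None, grid: WavelengthGrid | None = None) -> IlluminantSpectrum:
    """Load a daylight illuminant from CSV (bundled table by default).

    The bundled curve is a synthetic stand-in for CIE D65: Planck blackbody
    radiance at 6504 K normalized to 100 at 560 nm. It has D65's broad
    shape but none of the atmospheric absorption structure.
    """
    g, values = _read_table_csv(path or _data_path("illuminant_d65_synthetic.csv"))
    ill = IlluminantSpectrum(g, values[:, 0])
    return ill.resample(grid) if grid is not None and grid != g else ill


def equal_energy_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> IlluminantSpectrum:
    """Illuminant E: constant spectral power."""
    return IlluminantSpectrum(grid, np.ones(len(grid)))


def load_ciede2000_reference() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The published CIEDE2000 verification pair set (Sharma, Wu & Dalal).

    Returns ``(lab1, lab2, expected)`` where the Lab arrays are (34, 3)
    and ``expected`` holds the reference color differences. Used to
    validate any CIEDE2000 implementation to the printed 1e-4 precision.
    """
    df = pd.read_csv(_data_path("ciede2000_reference_pairs.csv"))
    lab1 = df[["L1", "a1", "b1"]].to_numpy(dtype=float)
    lab2 = df[["L2", "a2", "b2"]].to_numpy(dtype=float)
    return lab1, lab2, df["de00"].to_numpy(dtype=float)
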