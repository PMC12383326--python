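"""Image-quality validation metrics.

The enhancement pipeline is validated by comparing rendered images against
reference captures with the standard trio SSIM / PSNR / Shannon entropy,
plus the per-patch CIEDE2000 report and calibration RMSE. Color images are
reduced to luminance (the Y row of the sRGB-to-XYZ matrix) before the
greyscale metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .colorimetry import ciede2000, linear_rgb_to_xyz, srgb_decode

__all__ = [
    "ssim",
    "psnr",
    "shannon_entropy",
    "luminance",
    "michelson_contrast",
    "QualityReport",
    "compare_pair",
]


def luminance(image: np.ndarray) -> np.ndarray:
    """8-bit image -> linear-light luminance Y in [0, 1] (greyscale passthrough)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return srgb_decode(img)
    return linear_rgb_to_xyz(srgb_decode(img))[..., 1]


def _gaussian_window(a: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    out = correlate1d(a, kernel, axis=0, mode="reflect")
    return correlate1d(out, kernel, axis=1, mode="reflect")


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity index between two equal-size greyscale images.

    Gaussian-windowed luminance/contrast/structure product, averaged over
    all window positions (border crop of half a window). Defaults are the
    original SSIM constants: 11-tap window, sigma 1.5, k1 = 0.01,
    k2 = 0.03 on the data range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("ssim expects 2-D greyscale rasters")
    if window % 2 != 1 or window > min(a.shape):
        raise ValueError("window must be odd and no larger than the image")
    if data_range is None:
        data_range = float(a.max() - a.min()) or 1.0
    radius = (window - 1) // 2
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    ux = _gaussian_window(a, sigma, radius)
    uy = _gaussian_window(b, sigma, radius)
    uxx = _gaussian_window(a * a, sigma, radius)
    uyy = _gaussian_window(b * b, sigma, radius)
    uxy = _gaussian_window(a * b, sigma, radius)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    crop = s[radius:-radius, radius:-radius] if radius else s
    return float(crop.mean())


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give math.inf."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def shannon_entropy(image: np.ndarray) -> float:
    """Histogram entropy of an 8-bit greyscale image, in bits (0-8)."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(img.dtype, np.floating):
        img = np.clip(np.round(img), 0, 255)
    counts = np.bincount(img.astype(np.int64).ravel(), minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p @ np.log2(p)))


def michelson_contrast(foreground: np.ndarray, background: np.ndarray) -> float:
    """Michelson contrast between two intensity populations.

    Uses the mean intensity of each population: (Ibg - Ifg) / (Ibg + Ifg),
    positive when the foreground (e.g. vessels) is darker.
    """
    fg = float(np.mean(foreground))
    bg = float(np.mean(background))
    if fg + bg == 0:
        return 0.0
    return (bg - fg) / (bg + fg)


@dataclass(frozen=True)
class QualityReport:
    """Aggregate image-pair and patch-set quality metrics."""

    ssim: float
    psnr_db: float
    entropy_a: float
    entropy_b: float
    entropy_diff_pct: float
    rmse: float
    mean_de00: float | None = None
    per_patch_de00: np.ndarray | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "ssim": self.ssim,
            "psnr_db": "inf" if math.isinf(self.psnr_db) else self.psnr_db,
            "entropy_a": self.entropy_a,
            "entropy_b": self.entropy_b,
            "entropy_diff_pct": self.entropy_diff_pct,
            "rmse": self.rmse,
        }
        if self.mean_de00 is not None:
            d["mean_de00"] = self.mean_de00
            d["per_patch_de00"] = [float(x) for x in self.per_patch_de00]
        return d


def compare_pair(
    a: np.ndarray,
    b: np.ndarray,
    patches_lab_a: np.ndarray | None = None,
    patches_lab_b: np.ndarray | None = None,
) -> QualityReport:
    """Full quality comparison of image ``a`` against reference ``b``.

    Greyscale metrics run on 8-bit luminance; the entropy difference is
    the absolute percent difference relative to the reference image b.
    Optional patch Lab sets add the per-patch and mean CIEDE2000.
    """
    la = np.round(255.0 * luminance(a))
    lb = np.round(255.0 * luminance(b))
    ha = shannon_entropy(la)
    hb = shannon_entropy(lb)
    ediff = 100.0 * abs(ha - hb) / hb if hb != 0 else (0.0 if ha == 0 else math.inf)
    mean_de = per_de = None
    if (patches_lab_a is None) != (patches_lab_b is None):
        raise ValueError("provide both patch sets or neither")
    if patches_lab_a is not None:
        pa = np.asarray(patches_lab_a, dtype=float)
        pb = np.asarray(patches_lab_b, dtype=float)
        if pa.shape != pb.shape:
            raise ValueError(f"patch sets differ in shape: {pa.shape} vs {pb.shape}")
        per_de = ciede2000(pa, pb)
        mean_de = float(np.mean(per_de))
    return QualityReport(
        ssim=ssim(la, lb, data_range=255.0),
        psnr_db=psnr(la, lb, peak=255.0),
        entropy_a=ha,
        entropy_b=hb,
        entropy_diff_pct=ediff,
        rmse=float(np.sqrt(np.mean((la - lb) ** 2))),
        mean_de00=mean_de,
        per_patch_de00=per_de,
    )
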