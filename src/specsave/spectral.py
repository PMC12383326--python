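"""Spectral reconstruction: from corrected tristimulus values to reflectance.

The reflectance spectra of the 24 calibration patches are compressed with
mean-centered PCA; six components typically capture essentially all
spectral variance of a ColorChecker set. A multiple regression then maps
the polynomial expansion of the *corrected* tristimulus value (Vcolor) to
the PCA scores:

    M = Score . pinv(Vcolor)                       (fit)
    S(380..780) = mean + EV . M . Vcolor           (reconstruct)

Chaining camera correction and reconstruction per pixel turns an ordinary
8-bit endoscopy frame into a simulated hyperspectral reflectance cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .calibration import (
    ExpansionRecipe,
    apply_correction,
    expand_variables,
    fit_correction_matrix,
)
from .colorimetry import WavelengthGrid, linear_rgb_to_xyz, srgb_decode

__all__ = [
    "PCABasis",
    "Hypercube",
    "CalibrationBundle",
    "fit_pca_basis",
    "fit_transformation_matrix",
    "reconstruct_spectrum",
    "image_to_hypercube",
    "fit_pipeline",
]


@dataclass(frozen=True)
class PCABasis:
    """Mean-centered PCA decomposition of a set of reflectance spectra.

    ``components`` holds the orthonormal spectral eigenvectors as columns
    (B x k); ``scores`` holds the training coordinates (k x N). The sign
    of each eigenvector is fixed by making its largest-magnitude element
    positive, so serialization is reproducible.
    """

    mean: np.ndarray                      # (B,)
    components: np.ndarray                # (B, k)
    explained_variance_ratio: np.ndarray  # (k,)
    scores: np.ndarray                    # (k, N)

    def __post_init__(self) -> None:
        ev = np.asarray(self.components, dtype=float)
        gram = ev.T @ ev
        if not np.allclose(gram, np.eye(ev.shape[1]), atol=1e-8):
            raise ValueError("PCA eigenvectors are not orthonormal")
        r = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(r) > 1e-12) or np.any(r < -1e-12) or r.sum() > 1 + 1e-9:
            raise ValueError("explained-variance ratios must be non-increasing fractions")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Project spectra (N, B) onto the basis -> scores (k, N)."""
        return self.components.T @ (np.asarray(spectra, float) - self.mean).T


def fit_pca_basis(
    spectra: np.ndarray,
    n_components: int | None = None,
    variance_threshold: float = 0.9964,
    max_components: int = 6,
) -> PCABasis:
    """Fit a mean-centered PCA basis to reflectance spectra.

    Parameters
    ----------
    spectra : (N, B) array
        One reflectance spectrum per row, all on a common grid.
    n_components : int, optional
        Exact component count. If omitted, the smallest k whose cumulative
        explained-variance ratio reaches ``variance_threshold`` is used,
        capped at ``max_components``.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need at least 2 spectra on a common grid")
    n, b = spectra.shape
    if n_components is not None and n_components > min(n, b):
        raise ValueError(f"cannot extract {n_components} components from {n} spectra")
    if np.allclose(spectra, spectra[0], rtol=0, atol=1e-12):
        raise ValueError("degenerate input: all spectra identical (zero variance)")

    k_max = min(n - 1, b, max(max_components, n_components or 0))
    pca = PCA(n_components=k_max, svd_solver="full")
    pca.fit(spectra)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(k, max_components, k_max)
    else:
        k = n_components

    components = pca.components_[:k].T.copy()  # (B, k)
    flip = np.sign(components[np.argmax(np.abs(components), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    components *= flip
    scores = components.T @ (spectra - pca.mean_).T  # (k, N)
    return PCABasis(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
        scores=scores,
    )


def fit_transformation_matrix(
    scores: np.ndarray, vcolor: np.ndarray, rtol: float = 1e-10
) -> np.ndarray:
    """Regression from expanded corrected XYZ to PCA scores: M = scores . pinv(Vcolor)."""
    scores = np.asarray(scores, dtype=float)
    vcolor = np.asarray(vcolor, dtype=float)
    if scores.ndim != 2 or vcolor.ndim != 2 or scores.shape[1] != vcolor.shape[1]:
        raise ValueError(
            f"column counts must match: scores {scores.shape}, vcolor {vcolor.shape}"
        )
    s = np.linalg.svd(vcolor, compute_uv=False)
    if s[0] > 0 and np.sum(s > rtol * s[0]) < min(vcolor.shape):
        warnings.warn(
            "Vcolor is rank deficient; returning the minimum-norm solution",
            stacklevel=2,
        )
    return scores @ np.linalg.pinv(vcolor, rcond=rtol)


@dataclass(frozen=True)
class Hypercube:
    """Per-pixel reflectance over a wavelength grid (H x W x B).

    ``values`` are clipped to the physical range [0, 1] at construction;
    the unclipped reconstruction is available as ``raw`` for diagnostics.
    """

    grid: WavelengthGrid
    values: np.ndarray
    raw: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != len(self.grid):
            raise ValueError(
                f"values shape {v.shape} incompatible with grid length {len(self.grid)}"
            )
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CalibrationBundle:
    """Everything needed to turn an sRGB frame into a reflectance cube.

    Aggregates the fitted correction matrix, the expansion recipe, the PCA
    basis, the score-regression matrix and the wavelength grid, plus
    free-form provenance metadata (fit RMSE, dates, ...).
    """

    correction: np.ndarray          # (3, K)
    recipe: ExpansionRecipe
    basis: PCABasis
    transform: np.ndarray           # (k, K)
    grid: WavelengthGrid
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        K = len(self.recipe)
        C = np.asarray(self.correction, dtype=float)
        M = np.asarray(self.transform, dtype=float)
        k = self.basis.n_components
        B = self.basis.components.shape[0]
        if C.shape != (3, K):
            raise ValueError(f"correction shape {C.shape} != (3, {K})")
        if M.shape != (k, K):
            raise ValueError(f"transform shape {M.shape} != ({k}, {K})")
        if B != len(self.grid):
            raise ValueError(f"basis length {B} != grid length {len(self.grid)}")


def reconstruct_spectrum(
    bundle: CalibrationBundle, vcolor: np.ndarray, clip: bool = False
) -> np.ndarray:
    """Reconstruct reflectance from expanded corrected XYZ.

    ``vcolor`` is a length-K vector or (K, N) stack; returns (B,) or (N, B).
    Clipping to [0, 1] is off by default — it is applied once, at hypercube
    finalization.
    """
    vcolor = np.asarray(vcolor, dtype=float)
    out = bundle.basis.mean + (bundle.basis.components @ (bundle.transform @ vcolor)).T
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def image_to_hypercube(image: np.ndarray, bundle: CalibrationBundle) -> Hypercube:
    """Convert an 8-bit sRGB image to a simulated hyperspectral cube.

    Per pixel: sRGB decode -> XYZ (x100) -> expand -> color correction ->
    expand again -> spectral reconstruction. Deterministic; vectorized
    over all pixels.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    xyz_cam = 100.0 * linear_rgb_to_xyz(srgb_decode(img).reshape(-1, 3))
    v = expand_variables(xyz_cam, bundle.recipe).T               # (K, N)
    xyz_corr = apply_correction(bundle.correction, v)            # (3, N)
    vcolor = expand_variables(xyz_corr.T, bundle.recipe).T       # (K, N)
    spectra = reconstruct_spectrum(bundle, vcolor)               # (N, B)
    raw = spectra.reshape(h, w, -1)
    return Hypercube(grid=bundle.grid, values=raw, raw=raw)


def fit_pipeline(
    patch_rgb: np.ndarray,
    spectra: np.ndarray,
    grid: WavelengthGrid,
    cmf,
    illuminant,
    recipe: ExpansionRecipe = ExpansionRecipe(),
    n_components: int | None = None,
    variance_threshold: float = 0.9964,
    max_components: int = 6,
) -> CalibrationBundle:
    """Fit the full calibration from ColorChecker data.

    Parameters
    ----------
    patch_rgb : (N, 3) array
        Mean camera sRGB of each patch (8-bit values or 0-1 floats).
    spectra : (N, B) array
        Spectrometer reflectance of each patch on ``grid``.
    cmf, illuminant
        Observer table and working illuminant used to turn the reference
        spectra into XYZ targets.

    Returns
    -------
    CalibrationBundle with fit diagnostics (``rmse_xyz``, ``n_components``,
    ``cumulative_variance``) in its metadata.
    """
    from .colorimetry import spectrum_to_xyz

    patch_rgb = np.asarray(patch_rgb)
    spectra = np.asarray(spectra, dtype=float)
    if patch_rgb.shape[0] != spectra.shape[0]:
        raise ValueError("patch count mismatch between RGB values and spectra")
    targets = spectrum_to_xyz(spectra, illuminant, cmf).T          # (3, N)
    xyz_cam = 100.0 * linear_rgb_to_xyz(srgb_decode(patch_rgb))
    v = expand_variables(xyz_cam, recipe).T                        # (K, N)
    C = fit_correction_matrix(v, targets)
    xyz_corr = apply_correction(C, v)
    basis = fit_pca_basis(
        spectra,
        n_components=n_components,
        variance_threshold=variance_threshold,
        max_components=max_components,
    )
    vcolor = expand_variables(xyz_corr.T, recipe).T
    M = fit_transformation_matrix(basis.scores, vcolor)
    rmse = float(np.sqrt(np.mean((xyz_corr - targets) ** 2)))
    meta = {
        "rmse_xyz": rmse,
        "n_components": basis.n_components,
        "cumulative_variance": float(basis.explained_variance_ratio.sum()),
        "n_patches": int(spectra.shape[0]),
    }
    return CalibrationBundle(
        correction=C, recipe=recipe, basis=basis, transform=M, grid=grid, metadata=meta
    )
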