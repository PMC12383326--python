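"""ColorChecker-based camera color correction.

An endoscope camera distorts scene color through three mechanisms: a
nonlinear channel response, a dark-current offset, and channel cross-talk
(incorrect color separation). All three are corrected in XYZ space by a
single linear regression on a fixed polynomial expansion of the camera's
tristimulus value:

    C = XYZ_spectrum . pinv(V)        (fit, 24 ColorChecker patches)
    XYZ_correct = C . V               (apply, per pixel)

where V stacks the expanded camera XYZ vectors. The constant term of the
expansion absorbs dark current, the linear and cross terms absorb channel
mixing, and the power/root terms absorb response nonlinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpansionRecipe",
    "DEFAULT_RECIPE_TERMS",
    "expand_variables",
    "fit_correction_matrix",
    "apply_correction",
    "calibration_rmse",
]

# Term vocabulary: each term maps (X, Y, Z) -> scalar.
_TERM_FUNCS = {
    "1": lambda x, y, z: np.ones_like(x),
    "X": lambda x, y, z: x,
    "Y": lambda x, y, z: y,
    "Z": lambda x, y, z: z,
    "XY": lambda x, y, z: x * y,
    "XZ": lambda x, y, z: x * z,
    "YZ": lambda x, y, z: y * z,
    "X2": lambda x, y, z: x * x,
    "Y2": lambda x, y, z: y * y,
    "Z2": lambda x, y, z: z * z,
    "X3": lambda x, y, z: x**3,
    "Y3": lambda x, y, z: y**3,
    "Z3": lambda x, y, z: z**3,
    "XYZ": lambda x, y, z: x * y * z,
    "sqrtX": lambda x, y, z: np.sqrt(x),
    "sqrtY": lambda x, y, z: np.sqrt(y),
    "sqrtZ": lambda x, y, z: np.sqrt(z),
}

# Constant + linears + cross products + squares + triple product + roots:
# one term family for each physical defect the correction targets.
DEFAULT_RECIPE_TERMS = (
    "1", "X", "Y", "Z",
    "XY", "XZ", "YZ",
    "X2", "Y2", "Z2",
    "XYZ",
    "sqrtX", "sqrtY", "sqrtZ",
)


@dataclass(frozen=True)
class ExpansionRecipe:
    """Ordered list of expansion terms applied to a tristimulus value.

    The recipe is serialized with any fitted calibration, so a bundle
    always carries the exact expansion it was fitted with.
    """

    terms: tuple[str, ...] = field(default=DEFAULT_RECIPE_TERMS)

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        if not terms or terms[0] != "1":
            raise ValueError("first expansion term must be the constant '1'")
        unknown = [t for t in terms if t not in _TERM_FUNCS]
        if unknown:
            raise ValueError(f"unknown expansion terms: {unknown}")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate expansion terms")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)


def expand_variables(xyz: np.ndarray, recipe: ExpansionRecipe = ExpansionRecipe()) -> np.ndarray:
    """Evaluate the expansion terms for XYZ value(s).

    Parameters
    ----------
    xyz : (..., 3) array
        Tristimulus values. Negative components (out-of-gamut arithmetic)
        are clipped to zero before square-root terms only.

    Returns
    -------
    (..., K) array with the terms in recipe order.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) XYZ array, got shape {xyz.shape}")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("XYZ values must be finite")
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    if np.any(xyz < 0) and any(t.startswith("sqrt") for t in recipe.terms):
        warnings.warn(
            "negative XYZ components clipped to zero for square-root terms",
            stacklevel=2,
        )
    xc, yc, zc = (np.maximum(v, 0.0) for v in (x, y, z))
    out = np.empty(xyz.shape[:-1] + (len(recipe),))
    for i, term in enumerate(recipe.terms):
        args = (xc, yc, zc) if term.startswith("sqrt") else (x, y, z)
        out[..., i] = _TERM_FUNCS[term](*args)
    return out


def fit_correction_matrix(
    V: np.ndarray, xyz_targets: np.ndarray, rtol: float = 1e-10
) -> np.ndarray:
    """Least-squares fit of the 3xK correction matrix C = targets . pinv(V).

    Parameters
    ----------
    V : (K, N) array
        Expanded camera tristimulus values, one column per patch.
    xyz_targets : (3, N) array
        Spectrometer-derived reference XYZ, one column per patch.
    rtol : float
        Relative singular-value cutoff of the pseudoinverse: singular
        values below ``rtol * s_max`` are treated as zero.

    Notes
    -----
    Minimizes the Frobenius norm of ``C V - targets``. A rank-deficient V
    triggers a warning and yields the minimum-norm solution.
    """
    V = np.asarray(V, dtype=float)
    xyz_targets = np.asarray(xyz_targets, dtype=float)
    if V.ndim != 2 or xyz_targets.ndim != 2:
        raise ValueError("V and targets must be 2-D")
    if xyz_targets.shape[0] != 3 or xyz_targets.shape[1] != V.shape[1]:
        raise ValueError(
            f"shape mismatch: V {V.shape} vs targets {xyz_targets.shape}"
        )
    s = np.linalg.svd(V, compute_uv=False)
    if s[0] > 0 and np.sum(s > rtol * s[0]) < min(V.shape):
        warnings.warn(
            "expanded design matrix is rank deficient; returning the "
            "minimum-norm least-squares solution",
            stacklevel=2,
        )
    return xyz_targets @ np.linalg.pinv(V, rcond=rtol)


def apply_correction(C: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Apply a fitted correction: XYZ_correct = C . V (vectorized).

    ``V`` may be a single length-K vector or a (K, N) stack of columns.
    """
    C = np.asarray(C, dtype=float)
    V = np.asarray(V, dtype=float)
    if C.shape[1] != V.shape[0]:
        raise ValueError(f"C has K={C.shape[1]} but V has K={V.shape[0]}")
    return C @ V


def calibration_rmse(predicted: np.ndarray, target: np.ndarray) -> float:
    """Pooled elementwise root-mean-square error between two arrays."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((predicted - target) ** 2)))
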