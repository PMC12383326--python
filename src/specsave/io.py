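"""File formats: images, spectra CSV, calibration bundles, ENVI cubes.

All writes are atomic (temp file + rename in the target directory), so a
crashed run never leaves a partial artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import ExpansionRecipe
from .colorimetry import WavelengthGrid
from .spectral import CalibrationBundle, Hypercube, PCABasis

__all__ = [
    "read_image",
    "write_image",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_patches_csv",
    "write_patches_csv",
    "save_bundle",
    "load_bundle",
    "write_envi_cube",
    "read_envi_cube",
    "load_config",
]

BUNDLE_VERSION = 1


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: Path, text: str) -> None:
    _atomic_write_bytes(path, text.encode("utf-8"))


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(path, convert_16bit: bool = True) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as 8-bit RGB (H, W, 3).

    16-bit input is scaled to 8 bits by ``v // 257`` when
    ``convert_16bit`` is set, otherwise it is rejected.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize backend errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise IOError(f"{path}: expected a 3-channel image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        if not convert_16bit:
            raise IOError(f"{path}: 16-bit image and conversion disabled")
        return (img // 257).astype(np.uint8)
    raise IOError(f"{path}: unsupported dtype {img.dtype}")


def write_image(path, image: np.ndarray) -> None:
    """Write an 8-bit image atomically (format from the extension)."""
    path = Path(path)
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got {img.dtype}")
    _atomic_write_bytes(path, iio.imwrite("<bytes>", img, extension=path.suffix))


# ---------------------------------------------------------------------------
# CSV spectra and patch tables
# ---------------------------------------------------------------------------


def read_spectra_csv(path) -> tuple[WavelengthGrid, np.ndarray, list[str]]:
    """Read a spectra CSV: wavelength_nm column + one column per patch.

    Rows are sorted by wavelength; the grid must be uniform. Returns
    ``(grid, spectra (n_patches, B), column_names)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
    df = df.sort_values("wavelength_nm")
    grid = WavelengthGrid.from_wavelengths(df["wavelength_nm"].to_numpy())
    spectra = df.iloc[:, 1:].to_numpy(dtype=float).T
    return grid, spectra, list(df.columns[1:])


def write_spectra_csv(path, grid: WavelengthGrid, spectra: np.ndarray, names=None) -> None:
    spectra = np.asarray(spectra, dtype=float)
    names = names or [f"patch_{i + 1}" for i in range(spectra.shape[0])]
    df = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for name, row in zip(names, spectra):
        df[name] = row
    _atomic_write_text(Path(path), df.to_csv(index=False, float_format="%.12g"))


def read_patches_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read patch means: columns patch_id, R, G, B -> (ids, rgb uint8)."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"patch_id", "R", "G", "B"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}, got {list(df.columns)}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in patch table")
    df = df.sort_values("patch_id")
    if df["patch_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patch ids")
    rgb = df[["R", "G", "B"]].to_numpy()
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError(f"{path}: RGB values must be 8-bit (0-255)")
    return df["patch_id"].to_numpy(), rgb.astype(np.uint8)


def write_patches_csv(path, rgb: np.ndarray, ids=None) -> None:
    rgb = np.asarray(rgb)
    ids = ids if ids is not None else np.arange(1, rgb.shape[0] + 1)
    df = pd.DataFrame({"patch_id": ids, "R": rgb[:, 0], "G": rgb[:, 1], "B": rgb[:, 2]})
    _atomic_write_text(Path(path), df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Calibration bundle JSON
# ---------------------------------------------------------------------------


def save_bundle(path, bundle: CalibrationBundle, extra: dict | None = None) -> None:
    """Serialize a calibration bundle (plus optional extension blocks) to JSON."""
    doc = {
        "version": BUNDLE_VERSION,
        "grid": {
            "start_nm": bundle.grid.start_nm,
            "end_nm": bundle.grid.end_nm,
            "step_nm": bundle.grid.step_nm,
        },
        "recipe": list(bundle.recipe.terms),
        "correction": bundle.correction.tolist(),
        "basis": {
            "mean": bundle.basis.mean.tolist(),
            "components": bundle.basis.components.tolist(),
            "explained_variance_ratio": bundle.basis.explained_variance_ratio.tolist(),
            "scores": bundle.basis.scores.tolist(),
        },
        "transform": bundle.transform.tolist(),
        "metadata": bundle.metadata,
    }
    if extra:
        doc.update(extra)
    _atomic_write_text(Path(path), json.dumps(doc))


def load_bundle(path) -> CalibrationBundle:
    """Load and validate a calibration bundle JSON document."""
    path = Path(path)
    doc = json.loads(path.read_text())
    version = doc.get("version")
    if version != BUNDLE_VERSION:
        raise ValueError(
            f"{path}: bundle version {version!r} not supported "
            f"(expected {BUNDLE_VERSION}); re-run calibration to migrate"
        )
    for key in ("grid", "recipe", "correction", "basis", "transform"):
        if key not in doc:
            raise ValueError(f"{path}: bundle is missing field {key!r}")
    g = doc["grid"]
    grid = WavelengthGrid(g["start_nm"], g["end_nm"], g["step_nm"])
    basis_doc = doc["basis"]
    try:
        basis = PCABasis(
            mean=np.asarray(basis_doc["mean"], float),
            components=np.asarray(basis_doc["components"], float),
            explained_variance_ratio=np.asarray(
                basis_doc["explained_variance_ratio"], float
            ),
            scores=np.asarray(basis_doc["scores"], float),
        )
        return CalibrationBundle(
            correction=np.asarray(doc["correction"], float),
            recipe=ExpansionRecipe(tuple(doc["recipe"])),
            basis=basis,
            transform=np.asarray(doc["transform"], float),
            grid=grid,
            metadata=doc.get("metadata", {}),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: invalid bundle: {exc}") from exc


# ---------------------------------------------------------------------------
# ENVI hypercube container
# ---------------------------------------------------------------------------


def write_envi_cube(path_prefix, cube: Hypercube) -> tuple[Path, Path]:
    """Write a hypercube as ENVI: text ``.hdr`` plus float32 BSQ ``.raw``.

    Returns (header path, data path). Wavelengths go into the header's
    ``wavelength`` block.
    """
    prefix = Path(path_prefix)
    hdr_path = prefix.with_suffix(".hdr")
    raw_path = prefix.with_suffix(".raw")
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {reflectance hypercube}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {len(cube.grid)}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    bsq = np.ascontiguousarray(np.moveaxis(cube.values.astype("<f4"), 2, 0))
    _atomic_write_bytes(raw_path, bsq.tobytes())
    _atomic_write_text(hdr_path, header)
    return hdr_path, raw_path


def read_envi_cube(path_prefix) -> Hypercube:
    prefix = Path(path_prefix)
    hdr = prefix.with_suffix(".hdr").read_text()
    fields: dict[str, str] = {}
    in_braces = None
    for line in hdr.splitlines():
        if in_braces is not None:
            fields[in_braces] += " " + line.strip()
            if line.strip().endswith("}"):
                in_braces = None
            continue
        if "=" in line:
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            fields[key] = value
            if value.startswith("{") and not value.endswith("}"):
                in_braces = key
    h, w, b = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    if fields.get("data type") != "4" or fields.get("interleave", "bsq") != "bsq":
        raise IOError(f"{prefix}: only float32 BSQ ENVI cubes are supported")
    wl = np.array(
        [float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    data = np.fromfile(prefix.with_suffix(".raw"), dtype="<f4")
    if data.size != h * w * b:
        raise IOError(f"{prefix}: truncated ENVI data file")
    values = np.moveaxis(data.reshape(b, h, w), 0, 2).astype(float)
    return Hypercube(grid=WavelengthGrid.from_wavelengths(wl), values=values)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "bundle_path",
    "cmf_path",
    "illuminant_path",
    "grid",
    "recipe",
    "n_components",
    "variance_threshold",
    "bands",
    "seed",
    "max_evals",
}


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration, rejecting unknown keys."""
    import yaml

    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown configuration keys {sorted(unknown)}; "
            f"allowed keys are {sorted(_CONFIG_KEYS)}"
        )
    return doc
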