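"""MSI datacube and embedding containers with I/O and light preprocessing.

The central object is :class:`MSIDataCube`: a dense ``(n_pixels, n_channels)``
intensity matrix together with its m/z axis, per-pixel integer grid
coordinates, the grid shape, and optional integer region labels
(0 = background / unlabelled). Pixel order is canonical: row-major by
``(y, x)``; every aligned structure (embedding coordinates, label vectors)
shares that order.

Supported formats:

* continuous-mode imzML (via :mod:`pyimzml`) — the interchange format of the
  MSI field; processed-mode files (per-spectrum m/z axes) are rejected.
* a native container: a NumPy ``.npz`` archive of the arrays plus a JSON
  sidecar recording shapes for integrity checking. Lossless round trip.
* embeddings and label vectors as CSV (``x, y, dim1..dimk`` / ``x, y, label``).

Intensities are held as float64 regardless of on-disk precision, because the
downstream cosine/Euclidean distance computations are done in double.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, IntegrityError, UnsupportedFormatError, ValidationError

__all__ = [
    "MSIDataCube",
    "Embedding",
    "read_imzml",
    "write_imzml",
    "read_native",
    "write_native",
    "rebin",
    "apply_roi",
    "region_mean_spectra",
    "write_embedding_csv",
    "read_embedding_csv",
]


@dataclass
class MSIDataCube:
    """A mass spectrometry imaging datacube (the high-dimensional space).

    Parameters
    ----------
    intensities:
        ``(n_pixels, n_channels)`` non-negative float matrix.
    mz_axis:
        Strictly increasing m/z vector (Th), length ``n_channels``.
    coords:
        ``(n_pixels, 2)`` integer ``(x, y)`` pixel coordinates, unique,
        0-based, inside ``mask_shape``.
    mask_shape:
        ``(width, height)`` of the pixel grid.
    region_labels:
        Optional integer label per pixel; 0 means background/unlabelled.
    metadata:
        Free-form provenance (generator spec, pairing of concatenated
        regions, ...).
    """

    intensities: np.ndarray
    mz_axis: np.ndarray
    coords: np.ndarray
    mask_shape: tuple[int, int]
    region_labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.mask_shape = (int(self.mask_shape[0]), int(self.mask_shape[1]))
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, c = self.intensities.shape
        if n < 1:
            raise ValidationError("cube must contain at least one pixel")
        if c < 2:
            raise ValidationError("cube must contain at least two m/z channels")
        if self.mz_axis.shape != (c,):
            raise ValidationError(
                f"mz_axis length {self.mz_axis.shape[0]} != n_channels {c}"
            )
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValidationError("mz_axis must be strictly increasing")
        if self.coords.shape != (n, 2):
            raise ValidationError("coords must be (n_pixels, 2)")
        w, h = self.mask_shape
        x, y = self.coords[:, 0], self.coords[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
            raise ValidationError("pixel coordinates fall outside mask_shape")
        if len(np.unique(y.astype(np.int64) * w + x)) != n:
            raise ValidationError("pixel coordinates must be unique")
        if self.region_labels is not None and self.region_labels.shape != (n,):
            raise ValidationError("region_labels length must equal n_pixels")

    # -- convenience ----------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "MSIDataCube":
        return MSIDataCube(
            intensities=self.intensities.copy(),
            mz_axis=self.mz_axis.copy(),
            coords=self.coords.copy(),
            mask_shape=self.mask_shape,
            region_labels=None if self.region_labels is None else self.region_labels.copy(),
            metadata=dict(self.metadata),
        )

    def equals(self, other: "MSIDataCube") -> bool:
        """Bit-exact equality of arrays (metadata excluded)."""
        if self.mask_shape != other.mask_shape:
            return False
        if (self.region_labels is None) != (other.region_labels is None):
            return False
        same = (
            np.array_equal(self.intensities, other.intensities)
            and np.array_equal(self.mz_axis, other.mz_axis)
            and np.array_equal(self.coords, other.coords)
        )
        if same and self.region_labels is not None:
            same = np.array_equal(self.region_labels, other.region_labels)
        return same


@dataclass
class Embedding:
    """A low-dimensional representation of a cube's pixels.

    Rows are aligned with the source cube's pixel order; ``params`` records
    the generating algorithm and its hyperparameters.
    """

    coordinates: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2:
            raise ValidationError("embedding coordinates must be 2-D")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("embedding contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def _canonical_order(coords: np.ndarray, width: int) -> np.ndarray:
    """Row-major (y, x) sort order for a coordinate table."""
    return np.argsort(coords[:, 1].astype(np.int64) * width + coords[:, 0], kind="stable")


def read_imzml(path: str | Path) -> MSIDataCube:
    """Read a continuous-mode imzML/ibd pair into a cube.

    imzML pixel coordinates are 1-based per the imzML standard; they are
    converted to 0-based internally. Pixels are reordered into the canonical
    row-major (y, x) order. Processed-mode files (one m/z axis per spectrum)
    raise :class:`UnsupportedFormatError`.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.with_suffix(".ibd").exists():
        raise IOError(f"missing binary data file: {path.with_suffix('.ibd')}")
    parser = ImzMLParser(str(path))
    try:
        mode_params = parser.metadata.file_description.param_by_name
        if "processed" in mode_params:
            raise UnsupportedFormatError(
                "processed-mode imzML (per-spectrum m/z axes) is not supported; "
                "only continuous mode is read"
            )
        n = len(parser.coordinates)
        mz0, spec0 = parser.getspectrum(0)
        mz_axis = np.asarray(mz0, dtype=np.float64)
        intensities = np.empty((n, mz_axis.size), dtype=np.float64)
        intensities[0] = spec0
        for i in range(1, n):
            mz_i, spec_i = parser.getspectrum(i)
            if len(mz_i) != mz_axis.size:
                raise UnsupportedFormatError(
                    "spectra have differing m/z axes; file is effectively "
                    "processed-mode"
                )
            intensities[i] = spec_i
        coords = np.asarray([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.int64)
    finally:
        if parser.m is not None:
            parser.m.close()
    width = int(coords[:, 0].max()) + 1
    height = int(coords[:, 1].max()) + 1
    order = _canonical_order(coords, width)
    return MSIDataCube(
        intensities=intensities[order],
        mz_axis=mz_axis,
        coords=coords[order],
        mask_shape=(width, height),
        metadata={"source": str(path), "format": "imzML"},
    )


def write_imzml(cube: MSIDataCube, path: str | Path) -> Path:
    """Write a cube as a continuous-mode imzML/ibd pair (float64 encoding)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path), mode="continuous", mz_dtype=np.float64, intensity_dtype=np.float64) as w:
        for i in range(cube.n_pixels):
            x, y = cube.coords[i]
            # imzML is 1-based
            w.addSpectrum(cube.mz_axis, cube.intensities[i], (int(x) + 1, int(y) + 1, 1))
    return path


# ---------------------------------------------------------------------------
# Native container: .npz + JSON sidecar
# ---------------------------------------------------------------------------

def write_native(cube: MSIDataCube, path: str | Path) -> Path:
    """Write the cube losslessly as ``<path>.npz`` plus ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    arrays: dict[str, np.ndarray] = {
        "intensities": cube.intensities,
        "mz": cube.mz_axis,
        "coords": cube.coords,
    }
    if cube.region_labels is not None:
        arrays["labels"] = cube.region_labels
    np.savez(str(base) + ".npz", **arrays)
    sidecar = {
        "n_pixels": cube.n_pixels,
        "n_channels": cube.n_channels,
        "mask_shape": list(cube.mask_shape),
        "has_labels": cube.region_labels is not None,
        "metadata": cube.metadata,
    }
    Path(str(base) + ".json").write_text(json.dumps(sidecar, indent=1))
    return Path(str(base) + ".npz")


def read_native(path: str | Path) -> MSIDataCube:
    """Read a cube written by :func:`write_native`, verifying integrity."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    npz_path, json_path = Path(str(base) + ".npz"), Path(str(base) + ".json")
    if not npz_path.exists() or not json_path.exists():
        raise IntegrityError(f"native container incomplete: need {npz_path} and {json_path}")
    try:
        sidecar = json.loads(json_path.read_text())
        with np.load(npz_path) as data:
            intensities = data["intensities"]
            mz = data["mz"]
            coords = data["coords"]
            labels = data["labels"] if "labels" in data.files else None
    except (json.JSONDecodeError, KeyError, ValueError, OSError) as exc:
        raise IntegrityError(f"corrupt native container {base}: {exc}") from exc
    if intensities.shape != (sidecar["n_pixels"], sidecar["n_channels"]):
        raise IntegrityError(
            f"shape header {sidecar['n_pixels']}×{sidecar['n_channels']} does not "
            f"match stored array {intensities.shape}"
        )
    if sidecar["has_labels"] != (labels is not None):
        raise IntegrityError("label presence flag disagrees with stored arrays")
    return MSIDataCube(
        intensities=intensities,
        mz_axis=mz,
        coords=coords,
        mask_shape=tuple(sidecar["mask_shape"]),
        region_labels=labels,
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def rebin(cube: MSIDataCube, bin_width: float) -> MSIDataCube:
    """Interpolation re-binning onto a uniform m/z grid.

    The new axis spans ``[min(mz), max(mz)]`` with step ``bin_width``
    (``floor(span / bin_width) + 1`` channels); each spectrum is piecewise-
    linearly interpolated onto it. Points outside the original span would be
    zero, but the new grid never leaves the span.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = float(cube.mz_axis[0]), float(cube.mz_axis[-1])
    span = hi - lo
    if bin_width > span:
        raise ValidationError(
            f"bin_width {bin_width} exceeds the m/z span {span:.6g}"
        )
    # tolerate float representation of an exact multiple (e.g. 1.0 / 0.001)
    n_new = int(math.floor(span / bin_width + 1e-9)) + 1
    new_mz = lo + bin_width * np.arange(n_new)
    out = np.empty((cube.n_pixels, n_new), dtype=np.float64)
    for i in range(cube.n_pixels):
        out[i] = np.interp(new_mz, cube.mz_axis, cube.intensities[i], left=0.0, right=0.0)
    return replace(
        cube.copy(),
        intensities=out,
        mz_axis=new_mz,
        metadata={**cube.metadata, "rebin_width": bin_width},
    )


def apply_roi(cube: MSIDataCube, keep: np.ndarray) -> MSIDataCube:
    """Restrict the cube to the pixels where ``keep`` is True.

    Pixel order and coordinates are preserved; only the selection changes.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (cube.n_pixels,):
        raise ValidationError("keep mask length must equal n_pixels")
    if not keep.any():
        raise DegenerateInputError("ROI would remove every pixel")
    return MSIDataCube(
        intensities=cube.intensities[keep],
        mz_axis=cube.mz_axis.copy(),
        coords=cube.coords[keep],
        mask_shape=cube.mask_shape,
        region_labels=None if cube.region_labels is None else cube.region_labels[keep],
        metadata=dict(cube.metadata),
    )


def region_mean_spectra(cube: MSIDataCube) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Per-region mean spectra μ_r and the global foreground mean μ_w.

    Returns ``(means, mu_w)`` where ``means[r]`` is the arithmetic mean
    spectrum over pixels labelled ``r`` (label 0 = background is excluded)
    and ``mu_w`` is the mean over all foreground pixels. Satisfies the
    weighted-mean identity Σ_r n_r μ_r = n μ_w.
    """
    if cube.region_labels is None:
        raise ValidationError("region_mean_spectra requires region_labels")
    labels = cube.region_labels
    fg = labels > 0
    if not fg.any():
        raise DegenerateInputError("no foreground (label > 0) pixels")
    means: dict[int, np.ndarray] = {}
    for r in np.unique(labels[fg]):
        means[int(r)] = cube.intensities[labels == r].mean(axis=0)
    mu_w = cube.intensities[fg].mean(axis=0)
    return means, mu_w


# ---------------------------------------------------------------------------
# Embedding CSV I/O
# ---------------------------------------------------------------------------

def write_embedding_csv(embedding: Embedding, cube: MSIDataCube, path: str | Path) -> Path:
    """Write an embedding as CSV with header ``x, y, dim1..dimk``."""
    if embedding.n_points != cube.n_pixels:
        raise ValidationError("embedding rows must match cube pixels")
    cols = {"x": cube.coords[:, 0], "y": cube.coords[:, 1]}
    for j in range(embedding.n_dims):
        cols[f"dim{j + 1}"] = embedding.coordinates[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def write_labels_csv(cube: MSIDataCube, path: str | Path) -> Path:
    """Write the region-label vector as CSV with header ``x, y, label``."""
    if cube.region_labels is None:
        raise ValidationError("cube has no region labels to write")
    pd.DataFrame(
        {"x": cube.coords[:, 0], "y": cube.coords[:, 1], "label": cube.region_labels}
    ).to_csv(path, index=False)
    return Path(path)


def read_labels_csv(path: str | Path) -> np.ndarray:
    """Read a ``x, y, label`` CSV; returns the label vector in file order."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise UnsupportedFormatError("label CSV must have columns x, y, label")
    return df["label"].to_numpy(dtype=np.int64)


def read_embedding_csv(path: str | Path) -> tuple[Embedding, np.ndarray]:
    """Read an embedding CSV; returns the embedding and its (x, y) table."""
    df = pd.read_csv(path)
    dim_cols = [c for c in df.columns if c.startswith("dim")]
    if not dim_cols or "x" not in df.columns or "y" not in df.columns:
        raise UnsupportedFormatError("embedding CSV must have columns x, y, dim1..dimk")
    emb = Embedding(df[dim_cols].to_numpy(dtype=np.float64), params={"source": str(path)})
    return emb, df[["x", "y"]].to_numpy(dtype=np.int64)
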