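"""Loading, validation and standardization of binary single-cell masks.

The pipeline's canonical geometry is a 300x300 field at 0.5 um/pixel with
a single 8-connected, hole-free foreground component.  All descriptors
downstream assume this contract, so :func:`standardize` enforces it:
resampling to 0.5 um/px, keeping the largest component, filling interior
holes and centering the bounding box on the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical pixel size after standardization (micrometres per pixel side).
CANONICAL_RESOLUTION_UM = 0.5
#: Canonical square field size after standardization (pixels).
CANONICAL_FIELD = 300

#: Canonical descriptor names, in fixed column order.
FEATURE_NAMES: tuple[str, ...] = (
    "circularity",
    "ramification_index",
    "roundness_factor",
    "perimeter_area_ratio",
    "density",
    "inertia",
    "processes_soma_areas_ratio",
    "processes_cell_areas_ratio",
    "polarization_index",
    "skeleton_processes_ratio",
    "branchpoints_endpoints_ratio",
    "branching_index",
    "fractal_dimension",
    "lacunarity",
    "solidity",
    "convexity",
    "convex_hull_circularity",
    "convex_hull_span_ratio",
    "convex_hull_radii_ratio",
    "linearity",
)


class MaskValidationError(ValueError):
    """The image content violates the single-cell binary-mask contract."""


class SchemaError(ValueError):
    """A feature table does not carry the canonical descriptor columns."""


@dataclass(frozen=True)
class CellImage:
    """A binarized single-cell mask with resolution metadata.

    Attributes
    ----------
    id : str
        Cell identifier (usually the file stem).
    pixels : ndarray of uint8
        2-D grid, 0 = background, 1 = cell. Row-major, origin top-left.
    resolution_um : float
        Physical size of one pixel side in micrometres.
    group_label : str or None
        Optional experimental condition tag.
    """

    id: str
    pixels: np.ndarray
    resolution_um: float
    group_label: str | None = None
    standardized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MaskValidationError(f"mask must be 2-D, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise MaskValidationError("mask values must be 0 or 1")
        if self.resolution_um <= 0:
            raise MaskValidationError("resolution_um must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def area(self) -> int:
        """Foreground pixel count."""
        return int(self.pixels.sum())


# 8-connectivity for foreground, the standard dual of 4-connected background.
_STRUCT8 = np.ones((3, 3), dtype=bool)


def load_mask(path: str | Path, resolution_um: float, id: str | None = None) -> CellImage:
    """Read a single-channel TIFF/PNG mask and binarize it.

    Any image whose distinct values are {0} plus at most one positive value
    is accepted; that positive value maps to foreground.  The result is not
    yet standardized (call :func:`standardize`).

    Raises
    ------
    MaskValidationError
        If the mask is empty or carries more than two distinct values.
    OSError
        If the file cannot be read or decoded.
    """
    path = Path(path)
    try:
        img = np.asarray(iio.imread(path))
    except Exception as exc:  # plugin-specific decode errors vary widely
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if img.ndim == 3 and img.shape[2] in (1, 3, 4):
        channels = img[..., : min(img.shape[2], 3)]
        if not all(
            np.array_equal(channels[..., 0], channels[..., k])
            for k in range(channels.shape[2])
        ):
            raise MaskValidationError(
                f"{path.name}: multi-channel image with differing channels"
            )
        img = channels[..., 0]
    if img.ndim != 2:
        raise MaskValidationError(f"{path.name}: expected 2-D image, got shape {img.shape}")
    values = np.unique(img)
    if values.size == 1 and values[0] == 0:
        raise MaskValidationError(f"{path.name}: empty mask")
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise MaskValidationError(
            f"{path.name}: ambiguous binarization, values {values.tolist()} "
            "(expected 0 and a single foreground value)"
        )
    return CellImage(
        id=id if id is not None else path.stem,
        pixels=(img != 0).astype(np.uint8),
        resolution_um=float(resolution_um),
    )


def _validate_standardized(px: np.ndarray) -> None:
    n_fg, _ = ndimage.label(px, structure=_STRUCT8)[1], None
    if n_fg != 1:
        raise MaskValidationError(f"foreground has {n_fg} components, expected 1")
    filled = ndimage.binary_fill_holes(px)
    if not np.array_equal(filled, px.astype(bool)):
        raise MaskValidationError("foreground contains interior holes")


def standardize(cell: CellImage) -> CellImage:
    """Resample, clean and center a cell on the canonical field.

    Steps: nearest-neighbour rescale by ``resolution_um / 0.5`` (so physical
    extent is preserved at 0.5 um/px), keep the largest 8-connected
    component, fill interior holes (4-connected background), center the
    bounding box on a 300x300 field.  Idempotent.

    Raises
    ------
    MaskValidationError
        If the mask is empty, or the rescaled cell exceeds the 300x300 field.
    """
    px = cell.pixels.astype(bool)
    if not px.any():
        raise MaskValidationError(f"{cell.id}: empty mask")

    factor = cell.resolution_um / CANONICAL_RESOLUTION_UM
    if abs(factor - 1.0) > 1e-9:
        px = ndimage.zoom(px, zoom=factor, order=0, grid_mode=True, mode="grid-constant")
        px = px.astype(bool)
        if not px.any():
            raise MaskValidationError(f"{cell.id}: mask vanished during rescale")

    labels, n = ndimage.label(px, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"{cell.id}: {n} foreground components, keeping largest "
            f"({int(sizes[keep - 1])} px)",
            stacklevel=2,
        )
        px = labels == keep

    px = ndimage.binary_fill_holes(px)

    rows = np.flatnonzero(px.any(axis=1))
    cols = np.flatnonzero(px.any(axis=0))
    crop = px[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = crop.shape
    if h > CANONICAL_FIELD or w > CANONICAL_FIELD:
        raise MaskValidationError(
            f"{cell.id}: cell bounding box {h}x{w} exceeds the "
            f"{CANONICAL_FIELD}x{CANONICAL_FIELD} field; supply a larger field "
            "or re-crop the cell (no silent cropping is performed)"
        )
    out = np.zeros((CANONICAL_FIELD, CANONICAL_FIELD), dtype=np.uint8)
    r0 = (CANONICAL_FIELD - h) // 2
    c0 = (CANONICAL_FIELD - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = crop

    _validate_standardized(out)
    return replace(
        cell,
        pixels=out,
        resolution_um=CANONICAL_RESOLUTION_UM,
        standardized=True,
    )


def write_features(matrix: "pd.DataFrame | object", path: str | Path) -> None:
    """Write a feature matrix to CSV ('.' decimal, UTF-8, 17 significant digits).

    Accepts either a :class:`~morphorank.ranking.FeatureMatrix` or a
    DataFrame indexed by cell id with the 20 canonical columns (plus an
    optional ``group_label`` column).
    """
    df = _as_dataframe(matrix)
    _check_schema(df.columns)
    df.to_csv(path, index_label="cell_id", float_format="%.17g", encoding="utf-8")


def read_features(path: str | Path):
    """Read a feature CSV back into a :class:`~morphorank.ranking.FeatureMatrix`.

    Raises
    ------
    SchemaError
        If columns are missing, unknown, or the id column is absent.
    """
    from morphorank.ranking import FeatureMatrix

    df = pd.read_csv(path, encoding="utf-8")
    if df.columns[0] != "cell_id":
        raise SchemaError(f"first column must be 'cell_id', got {df.columns[0]!r}")
    df = df.set_index("cell_id")
    _check_schema(df.columns)
    groups = df["group_label"].astype(str).tolist() if "group_label" in df.columns else None
    values = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return FeatureMatrix(
        cell_ids=[str(i) for i in df.index],
        values=values,
        group_labels=groups,
    )


def _as_dataframe(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    # duck-typed FeatureMatrix
    df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=list(FEATURE_NAMES))
    if matrix.group_labels is not None:
        df["group_label"] = matrix.group_labels
    return df


def _check_schema(columns) -> None:
    cols = [c for c in columns if c != "group_label"]
    missing = [n for n in FEATURE_NAMES if n not in cols]
    extra = [c for c in cols if c not in FEATURE_NAMES]
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"missing columns: {missing}")
        if extra:
            msg.append(f"unknown columns: {extra}")
        raise SchemaError(
            "; ".join(msg) + f"; expected exactly {list(FEATURE_NAMES)}"
        )
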