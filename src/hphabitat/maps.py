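"""Parameter maps, tumour ROIs, %NG computation and in-plane transforms.

The pipeline works on co-registered 2-D quantitative maps on a common
pixel grid: the pyruvate signal-to-noise ratio ``SNR_Pyr`` (a surrogate
for substrate delivery / perfusion), the apparent pyruvate-to-lactate
conversion rate ``k_PL`` (s^-1), and the percentage nephrographic
enhancement ``PNG`` derived from pre- and post-contrast T1-weighted
images. A :class:`TumourROI` is a hand-drawn (here: generated) boolean
mask of the whole tumour excluding cystic/necrotic areas.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Recognised map kinds.
MAP_KINDS = ("SNR_Pyr", "k_PL", "PNG", "T1w_pre", "T1w_ng")


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically unusable."""


@dataclass
class ParameterMap:
    """One 2-D quantitative image on the common grid.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Pixel values; NaN marks undefined/excluded pixels.
    kind : str
        One of :data:`MAP_KINDS`.
    pixel_spacing_mm : tuple of float
        In-plane pixel spacing (row, col) in millimetres.
    slice_id : str
        Identifier of the imaging slice the map belongs to.
    """

    values: np.ndarray
    kind: str
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_id: str = "0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"map values must be 2-D, got shape {self.values.shape}")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TumourROI:
    """Boolean whole-tumour mask for one slice of one patient."""

    mask: np.ndarray
    slice_id: str = "0"
    patient_id: str = "P0"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_png(pre: ParameterMap, post: ParameterMap, roi: TumourROI) -> ParameterMap:
    """Percentage nephrographic enhancement map.

    %NG = 100 * (post - pre) / pre per pixel inside the ROI, where *pre*
    is the non-enhanced T1-weighted signal and *post* the nephrographic
    contrast-enhanced phase. Pixels with non-positive baseline are
    excluded (NaN) rather than failing the slice; everything outside the
    ROI is NaN. Negative values (de-enhancement) are allowed.
    """
    if pre.kind != "T1w_pre" or post.kind != "T1w_ng":
        raise ValueError("compute_png expects kinds T1w_pre and T1w_ng")
    if pre.shape != post.shape or pre.shape != roi.shape:
        raise ValueError(
            f"shape mismatch: pre {pre.shape}, post {post.shape}, roi {roi.shape}"
        )
    valid = roi.mask & (pre.values > 0)
    if not valid.any():
        raise DegenerateInputError("no ROI pixel has positive pre-contrast signal")
    out = np.full(pre.shape, np.nan)
    out[valid] = 100.0 * (post.values[valid] - pre.values[valid]) / pre.values[valid]
    return ParameterMap(out, "PNG", pre.pixel_spacing_mm, pre.slice_id)


def make_affine(
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    center: tuple[float, float] | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Build a 2x3 pull-back affine (output pixel -> input pixel).

    Rotation is about ``center`` (row, col); ``translation`` shifts the
    image content by (drow, dcol) in output space.
    """
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / scale
    c = np.zeros(2) if center is None else np.asarray(center, dtype=float)
    t = np.asarray(translation, dtype=float)
    # pull-back: input = R @ (output - t - c) + c
    offset = c - rot @ (c + t)
    return np.column_stack([rot, offset])


def apply_transform(
    pmap: ParameterMap, affine_2d: np.ndarray, interpolation: str = "linear"
) -> ParameterMap:
    """Resample a map through a user-supplied in-plane affine.

    ``affine_2d`` is a 2x3 matrix mapping output pixel coordinates
    (row, col) to input pixel coordinates (the pull-back convention used
    by :func:`scipy.ndimage.affine_transform`). The identity transform
    returns the input values bit-exactly. Label-valued images must use
    ``interpolation='nearest'``.
    """
    A = np.asarray(affine_2d, dtype=float)
    if A.shape != (2, 3):
        raise ValueError("affine_2d must be a 2x3 matrix")
    if abs(np.linalg.det(A[:, :2])) < 1e-12:
        raise ValueError("singular affine transform")
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if np.array_equal(A, np.column_stack([np.eye(2), np.zeros(2)])):
        return replace(pmap, values=pmap.values.copy())
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        pmap.values, A[:, :2], offset=A[:, 2], order=order, mode="constant", cval=np.nan
    )
    return replace(pmap, values=out)


def mask_map(pmap: ParameterMap, roi: TumourROI) -> tuple[np.ndarray, np.ndarray]:
    """Extract in-ROI pixel values in row-major order.

    Returns ``(values, indices)`` where ``indices`` are flat row-major
    pixel indices into the grid and ``values[i] == map.flat[indices[i]]``.
    """
    if pmap.shape != roi.shape:
        raise ValueError(f"shape mismatch: map {pmap.shape}, roi {roi.shape}")
    idx = np.flatnonzero(roi.mask.ravel())
    if idx.size == 0:
        raise ValueError("ROI mask is empty")
    return pmap.values.ravel()[idx].copy(), idx


def scatter_back(
    values: np.ndarray, indices: np.ndarray, shape: tuple[int, int], fill: float = np.nan
) -> np.ndarray:
    """Inverse of :func:`mask_map`: place a value vector back onto the grid."""
    out = np.full(shape, fill, dtype=float)
    out.ravel()[indices] = values
    return out


# ---------------------------------------------------------------------------
# I/O


def save_map_nifti(pmap: ParameterMap, path) -> None:
    """Write a map as a single-slice NIfTI-1 image with pixel spacing in mm."""
    affine = np.diag([pmap.pixel_spacing_mm[0], pmap.pixel_spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(pmap.values.astype(np.float64), affine)
    nib.save(img, str(path))


def load_map_nifti(path, kind: str, slice_id: str = "0") -> ParameterMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D slice, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    return ParameterMap(data, kind, (float(zooms[0]), float(zooms[1])), slice_id)


def save_labels_nifti(labels: np.ndarray, path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def load_labels_nifti(path) -> np.ndarray:
    data = np.squeeze(np.asarray(nib.load(str(path)).dataobj))
    return data.astype(int)


def save_roi_nifti(roi: TumourROI, path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    save_labels_nifti(roi.mask.astype(np.int16), path, pixel_spacing_mm)


def load_roi_nifti(path, slice_id: str = "0", patient_id: str = "P0") -> TumourROI:
    return TumourROI(load_labels_nifti(path) > 0, slice_id, patient_id)


def roi_from_rle_csv(path, shape: tuple[int, int], slice_id="0", patient_id="P0") -> TumourROI:
    """Read an ROI from a run-length CSV with columns row,col_start,col_stop.

    Runs are half-open on the right ([col_start, col_stop)), 0-based.
    Intended for small text fixtures.
    """
    mask = np.zeros(shape, dtype=bool)
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            r = int(rec["row"])
            mask[r, int(rec["col_start"]): int(rec["col_stop"])] = True
    return TumourROI(mask, slice_id, patient_id)
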