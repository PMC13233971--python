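"""Volumetric I/O, world coordinates, and rotation preprocessing.

All modules share one voxel-ordering convention: values inside a mask are
listed in C-order raster scan of the 3-D grid (``numpy`` boolean indexing
order), so a value vector and ``world_coordinates`` always line up.

Volumes are NIfTI-1, single file; data stored float32, masks uint8.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ArgumentError, DimensionError, EmptyMaskError

#: Tolerance (mm) for declaring two affines "the same space".
AFFINE_TOL = 1e-4

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclasses.dataclass
class MaskedVolume:
    """One 3-D scalar field restricted to a voxel mask.

    Parameters
    ----------
    values
        Scalar per in-mask voxel, C-order raster scan of the mask grid.
    mask
        Boolean 3-D array.
    affine
        4x4 voxel-to-world matrix in mm.
    name
        Free-text label carried through the pipeline.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise DimensionError(f"mask must be 3-D, got {self.mask.ndim}-D")
        n = int(self.mask.sum())
        if n == 0:
            raise EmptyMaskError(f"mask of {self.name!r} selects no voxels")
        if self.values.size != n:
            raise DimensionError(
                f"{self.values.size} values for {n} mask voxels in {self.name!r}"
            )
        if self.affine.shape != (4, 4):
            raise DimensionError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ArgumentError("affine is singular")
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError(f"non-finite values inside mask of {self.name!r}")

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def to_grid(self, fill: float = 0.0) -> np.ndarray:
        """Scatter the value vector back onto the full 3-D grid."""
        grid = np.full(self.mask.shape, fill, dtype=float)
        grid[self.mask] = self.values
        return grid

    def with_values(self, values: np.ndarray, name: str | None = None) -> "MaskedVolume":
        return MaskedVolume(values, self.mask, self.affine,
                            self.name if name is None else name)


@dataclasses.dataclass
class BoldRun:
    """One subject's 4-D resting-state run plus ROI / grey-matter masks.

    ``data`` holds the time x voxel matrix over the in-brain voxel set
    (the union of ROI and grey-matter masks, C-order raster scan).
    """

    data: np.ndarray
    roi_mask: np.ndarray
    gm_mask: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.roi_mask.shape != self.gm_mask.shape:
            raise DimensionError("ROI and grey-matter masks have different grids")
        if self.data.ndim != 2:
            raise DimensionError("data must be time x voxel")
        if self.data.shape[0] < 2:
            raise DimensionError("need at least 2 timepoints")
        n_inbrain = int(self.inbrain_mask.sum())
        if self.data.shape[1] != n_inbrain:
            raise DimensionError(
                f"data has {self.data.shape[1]} columns for {n_inbrain} in-brain voxels"
            )
        if self.tr_seconds <= 0:
            raise ArgumentError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ArgumentError("non-finite values in BOLD data")

    @property
    def inbrain_mask(self) -> np.ndarray:
        return self.roi_mask | self.gm_mask

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def roi_data(self) -> np.ndarray:
        """Time series of ROI voxels (time x roi-voxel)."""
        return self.data[:, self.roi_mask[self.inbrain_mask]]

    def target_data(self) -> np.ndarray:
        """Time series of out-of-ROI grey-matter target voxels."""
        sel = self.gm_mask & ~self.roi_mask
        return self.data[:, sel[self.inbrain_mask]]


def _check_same_space(shape_a, affine_a, shape_b, affine_b):
    if tuple(shape_a) != tuple(shape_b):
        raise DimensionError(f"grid mismatch: {tuple(shape_a)} vs {tuple(shape_b)}")
    if not np.allclose(affine_a, affine_b, atol=AFFINE_TOL):
        raise DimensionError("affine mismatch beyond tolerance")


def read_volume(path, mask_path, name: str | None = None) -> MaskedVolume:
    """Read a 3-D scalar NIfTI restricted to a mask NIfTI.

    Values outside the mask are discarded. Raises :class:`DimensionError`
    on grid/affine mismatch and :class:`EmptyMaskError` on an all-false mask.
    """
    img = nib.load(str(path))
    mimg = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mimg.dataobj) > 0
    if data.ndim != 3:
        raise DimensionError(f"expected 3-D volume, got {data.ndim}-D")
    _check_same_space(data.shape, img.affine, mask.shape, mimg.affine)
    if not mask.any():
        raise EmptyMaskError(f"mask {mask_path} selects no voxels")
    return MaskedVolume(data[mask], mask, img.affine,
                        name=Path(path).stem if name is None else name)


def write_volume(vol: MaskedVolume, path, mask_path=None) -> None:
    """Write a MaskedVolume as a float32 NIfTI (zero outside the mask).

    If ``mask_path`` is given the mask itself is written as uint8.
    """
    grid = vol.to_grid().astype(np.float32)
    nib.save(nib.Nifti1Image(grid, vol.affine), str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine),
                 str(mask_path))


def read_run(data_path, roi_path, gm_path, subject_id: str = "") -> BoldRun:
    """Read a 4-D NIfTI run with its ROI and grey-matter masks."""
    img = nib.load(str(data_path))
    roi_img = nib.load(str(roi_path))
    gm_img = nib.load(str(gm_path))
    data4 = np.asarray(img.dataobj, dtype=float)
    if data4.ndim != 4:
        raise DimensionError(f"expected 4-D run, got {data4.ndim}-D")
    roi = np.asarray(roi_img.dataobj) > 0
    gm = np.asarray(gm_img.dataobj) > 0
    _check_same_space(data4.shape[:3], img.affine, roi.shape, roi_img.affine)
    _check_same_space(roi.shape, roi_img.affine, gm.shape, gm_img.affine)
    inbrain = roi | gm
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return BoldRun(data4[inbrain].T, roi, gm, img.affine,
                   tr_seconds=tr if tr > 0 else 2.0, subject_id=subject_id)


def write_run(run: BoldRun, data_path, roi_path=None, gm_path=None) -> None:
    shape4 = run.roi_mask.shape + (run.n_timepoints,)
    grid = np.zeros(shape4, dtype=np.float32)
    grid[run.inbrain_mask] = run.data.T
    img = nib.Nifti1Image(grid, run.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (run.tr_seconds,))
    nib.save(img, str(data_path))
    if roi_path is not None:
        nib.save(nib.Nifti1Image(run.roi_mask.astype(np.uint8), run.affine),
                 str(roi_path))
    if gm_path is not None:
        nib.save(nib.Nifti1Image(run.gm_mask.astype(np.uint8), run.affine),
                 str(gm_path))


def _rotation_transform(shape, affine, angle_deg, axis):
    """Voxel-space homogeneous matrix implementing a world-space rotation
    about the given axis through the world centroid of the grid."""
    try:
        ax = _AXIS_INDEX[str(axis).upper()]
    except KeyError:
        raise ArgumentError(f"axis must be one of X, Y, Z, got {axis!r}") from None
    if not np.isfinite(angle_deg):
        raise ArgumentError("angle must be finite")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot3 = np.eye(3)
    i, j = [k for k in range(3) if k != ax]
    rot3[i, i] = c
    rot3[j, j] = c
    rot3[i, j] = -s
    rot3[j, i] = s
    center = affine @ np.append((np.asarray(shape) - 1) / 2.0, 1.0)
    rinv = np.eye(4)
    rinv[:3, :3] = rot3.T  # inverse world rotation, for the pull-back mapping
    shift = np.eye(4)
    shift[:3, 3] = center[:3]
    unshift = np.eye(4)
    unshift[:3, 3] = -center[:3]
    world = shift @ rinv @ unshift
    return np.linalg.inv(affine) @ world @ affine


def _rotate_grid(grid, transform, order):
    out = ndimage.affine_transform(
        np.asarray(grid, dtype=float), transform[:3, :3], transform[:3, 3],
        order=order, mode="constant", cval=0.0, prefilter=False)
    return out


def rotate_volume(obj, angle_deg: float, axis: str = "X"):
    """Rotate a :class:`MaskedVolume` or :class:`BoldRun` about a world axis.

    The rotation axis passes through the world-space centroid of the grid.
    Scalar data are resampled with trilinear interpolation; masks with
    nearest-neighbour so they stay binary. The output lives on the same
    grid and affine as the input.
    """
    if isinstance(obj, MaskedVolume):
        t = _rotation_transform(obj.mask.shape, obj.affine, angle_deg, axis)
        new_mask = _rotate_grid(obj.mask.astype(float), t, order=0) > 0.5
        if not new_mask.any():
            raise EmptyMaskError("rotation moved the mask off the grid")
        new_grid = _rotate_grid(obj.to_grid(), t, order=1)
        return MaskedVolume(new_grid[new_mask], new_mask, obj.affine, obj.name)
    if isinstance(obj, BoldRun):
        t = _rotation_transform(obj.roi_mask.shape, obj.affine, angle_deg, axis)
        roi = _rotate_grid(obj.roi_mask.astype(float), t, order=0) > 0.5
        gm = _rotate_grid(obj.gm_mask.astype(float), t, order=0) > 0.5
        gm &= ~roi  # keep target and ROI voxel sets disjoint after resampling
        if not roi.any():
            raise EmptyMaskError("rotation moved the ROI mask off the grid")
        inbrain_old = obj.inbrain_mask
        inbrain_new = roi | gm
        frames = np.empty((obj.n_timepoints, int(inbrain_new.sum())))
        scratch = np.zeros(inbrain_old.shape, dtype=float)
        for tpt in range(obj.n_timepoints):
            scratch[inbrain_old] = obj.data[tpt]
            frames[tpt] = _rotate_grid(scratch, t, order=1)[inbrain_new]
        return BoldRun(frames, roi, gm, obj.affine, obj.tr_seconds, obj.subject_id)
    raise ArgumentError(f"cannot rotate object of type {type(obj).__name__}")


def world_coordinates(vol: MaskedVolume) -> np.ndarray:
    """World (X, Y, Z) in mm for each in-mask voxel, in value order.

    Order matches the C-order raster scan used by the values vector.
    """
    idx = np.argwhere(vol.mask)  # C-order, matching boolean indexing
    hom = np.column_stack([idx, np.ones(len(idx))])
    return (hom @ vol.affine.T)[:, :3]
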