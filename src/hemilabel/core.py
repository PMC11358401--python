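"""Volume and label-map data model with NIfTI I/O and grid operations.

All world coordinates are in millimetres, RAS+ (x to the subject's Right,
y Anterior, z Superior); voxel indices are 0-based.  The mid-sagittal
mirror plane used elsewhere in the package is the world plane x = 0.

Two containers are provided: :class:`Volume` for scalar intensity images
and :class:`LabelMap` for integer class images.  Label data are always
resampled nearest-neighbour so class ids stay categorical; intensities
are resampled with linear interpolation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "reorient_to_ras",
    "left_right_flip",
    "resample_isotropic",
]

# label-table roles
BACKGROUND = "background"
SUBREGION = "subregion"            # ids 1..5, one hemisphere
MIRRORED_SUBREGION = "mirrored_subregion"  # ids 6..10, mirrored hemisphere
CONTEXT = "context"                # ids >= context offset (default 100)

SUBREGION_IDS = (1, 2, 3, 4, 5)
MIRRORED_IDS = (6, 7, 8, 9, 10)


def default_label_role(label_id: int) -> str:
    if label_id == 0:
        return BACKGROUND
    if label_id in SUBREGION_IDS:
        return SUBREGION
    if label_id in MIRRORED_IDS:
        return MIRRORED_SUBREGION
    return CONTEXT


@dataclasses.dataclass
class Volume:
    """A 3-D scalar image with a voxel-to-world affine (mm, RAS+)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (always positive)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclasses.dataclass
class LabelMap(Volume):
    """A 3-D integer class image sharing :class:`Volume`'s grid model.

    ``label_table`` maps each id present in ``data`` to its role
    (background, subregion 1-5, mirrored subregion 6-10, or context).
    """

    label_table: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data)
            if not np.array_equal(as_int, self.data):
                raise ValueError("label data must be integer-valued")
            self.data = as_int.astype(np.int32)
        if np.any(self.data < 0):
            raise ValueError("label ids must be non-negative")
        ids = self.ids()
        if self.label_table is None:
            self.label_table = {int(i): default_label_role(int(i)) for i in ids}
        else:
            self.label_table = dict(self.label_table)
            for i in ids:
                self.label_table.setdefault(int(i), default_label_role(int(i)))
        if self.label_table.get(0, BACKGROUND) != BACKGROUND:
            raise ValueError("id 0 must be background")

    def ids(self) -> np.ndarray:
        return np.unique(self.data)

    def mask(self, ids=None) -> np.ndarray:
        """Boolean mask of voxels carrying any of ``ids`` (default: nonzero)."""
        if ids is None:
            return self.data > 0
        return np.isin(self.data, np.asarray(list(ids)))

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.affine.copy(), dict(self.label_table))


def _like(v: Volume, data: np.ndarray, affine: np.ndarray) -> Volume:
    if isinstance(v, LabelMap):
        return LabelMap(data, affine, dict(v.label_table))
    return Volume(data, affine)


def read_volume(path, as_labels: bool = False) -> Volume | LabelMap:
    """Read a NIfTI-1/NIfTI-2 file into a :class:`Volume` or :class:`LabelMap`.

    Label reading preserves integer ids exactly (no interpolation is ever
    involved in I/O); float-typed files whose values are not whole numbers
    raise rather than being rounded silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D in {path}")
    # sform if valid, else qform (nibabel's img.affine implements exactly this)
    affine = img.affine
    if as_labels:
        return LabelMap(data, affine)
    return Volume(np.asarray(data, dtype=np.float64), affine)


def write_volume(v: Volume | LabelMap, path) -> None:
    """Write to NIfTI; labels are stored with an integer dtype, intensities as float32.

    Both sform and qform are set consistently; an existing file is overwritten.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMap):
        data = np.asarray(v.data, dtype=np.int32)
    else:
        data = np.asarray(v.data, dtype=np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.set_sform(v.affine, code=1)
    img.set_qform(v.affine, code=1)
    nib.save(img, str(path))


def _axis_orientation(affine: np.ndarray):
    """Dominant world axis and sign per voxel axis; error if oblique/ambiguous."""
    R = affine[:3, :3]
    cols = R / np.linalg.norm(R, axis=0, keepdims=True)
    axes, signs = [], []
    for j in range(3):
        order = np.argsort(np.abs(cols[:, j]))[::-1]
        if np.abs(cols[order[0], j]) - np.abs(cols[order[1], j]) < 1e-6:
            raise ValueError(
                f"oblique affine: voxel axis {j} has no dominant world axis"
            )
        axes.append(int(order[0]))
        signs.append(1.0 if cols[order[0], j] > 0 else -1.0)
    if sorted(axes) != [0, 1, 2]:
        raise ValueError("oblique affine: voxel axes do not map to distinct world axes")
    return axes, signs


def reorient_to_ras(v: Volume | LabelMap) -> Volume | LabelMap:
    """Permute/flip voxel axes so axis 0 increases toward Right, 1 Anterior, 2 Superior.

    Every voxel keeps its world coordinate: only the index<->world mapping
    is rearranged, never the anatomy.
    """
    _axis_orientation(v.affine)  # raise early on oblique input
    orn = nib.orientations.io_orientation(v.affine)
    data = nib.orientations.apply_orientation(v.data, orn)
    transform = nib.orientations.inv_ornt_aff(orn, v.data.shape)
    affine = v.affine @ transform
    return _like(v, data, affine)


def is_ras(affine: np.ndarray, atol: float = 1e-6) -> bool:
    try:
        axes, signs = _axis_orientation(affine)
    except ValueError:
        return False
    return axes == [0, 1, 2] and all(s > 0 for s in signs)


def left_right_flip(v: Volume | LabelMap) -> Volume | LabelMap:
    """Mirror the anatomy in world x (left-right) for an RAS-oriented image.

    The data are reversed along axis 0 and the affine updated so the
    flipped anatomy occupies mirrored world-x positions (x -> -x), while
    the image remains RAS-oriented.
    """
    if not is_ras(v.affine):
        raise ValueError("input must be RAS-oriented; call reorient_to_ras first")
    data = v.data[::-1].copy()
    # world reflection x->-x composed with an index flip on axis 0
    reflect = np.diag([-1.0, 1.0, 1.0, 1.0])
    n0 = v.data.shape[0]
    flip_idx = np.eye(4)
    flip_idx[0, 0] = -1.0
    flip_idx[0, 3] = n0 - 1
    affine = reflect @ v.affine @ flip_idx
    return _like(v, data, affine)


def resample_isotropic(v: Volume | LabelMap, target_spacing: float) -> Volume | LabelMap:
    """Resample an RAS-oriented image to isotropic ``target_spacing`` mm.

    Output shape is ceil(extent / target_spacing) per axis and the grid
    origin is preserved, so the world bounding box never shrinks by more
    than one voxel.  Intensities use linear interpolation, labels
    nearest-neighbour.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if not is_ras(v.affine):
        raise ValueError("input must be RAS-oriented; call reorient_to_ras first")
    spacing = v.spacing
    if np.allclose(spacing, target_spacing, atol=1e-9):
        return _like(v, v.data.copy(), v.affine.copy())
    shape = v.data.shape
    extent = np.asarray(shape) * spacing
    new_shape = np.maximum(1, np.ceil(extent / target_spacing - 1e-9)).astype(int)
    new_affine = v.affine.copy()
    new_affine[:3, :3] = np.diag([target_spacing] * 3)
    # map output indices to input indices through world space (both axis-aligned)
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    src = [
        (g * target_spacing + new_affine[a, 3] - v.affine[a, 3]) / spacing[a]
        for a, g in enumerate(grids)
    ]
    order = 0 if isinstance(v, LabelMap) else 1
    data = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float), src, order=order, mode="nearest"
    )
    if isinstance(v, LabelMap):
        data = np.rint(data).astype(np.int32)
    return _like(v, data, new_affine)
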