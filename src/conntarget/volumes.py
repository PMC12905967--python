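"""Volumetric data model: grids, masks, scalar maps, NIfTI I/O and sphere ROIs.

All user-facing coordinates are MNI millimetres; voxel indices are 0-based
and tied to a grid by its 4x4 affine.  The dorsolateral prefrontal cortex
(DLPFC) search region is the union of four 20-mm spheres centred on
commonly used left-prefrontal stimulation sites (BA9, BA46, the "5-cm rule"
site and the Beam F3 group-average site).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    AffineError,
    EmptyMaskError,
    GridMismatchError,
    InvalidParameterError,
    NiftiFormatError,
)

#: MNI mm centres of the four 20-mm DLPFC spheres: BA9, BA46, "5-cm rule",
#: Beam F3 group-average site.
DLPFC_SPHERE_CENTERS_MM: tuple[tuple[float, float, float], ...] = (
    (-36.0, 39.0, 43.0),
    (-44.0, 40.0, 29.0),
    (-41.0, 16.0, 54.0),
    (-37.0, 26.0, 49.0),
)

DLPFC_SPHERE_RADIUS_MM: float = 20.0

#: Default stand-in for the pregenual cingulate (PGC) seed when no mask file
#: is supplied: a 6-mm sphere in pregenual ACC.  Flagged as synthetic in
#: every report that uses it.
PGC_STANDIN_CENTER_MM: tuple[float, float, float] = (0.0, 40.0, 4.0)
PGC_STANDIN_RADIUS_MM: float = 6.0


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with an affine voxel-index -> MNI-mm mapping."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if any(s < 1 for s in shape) or len(shape) != 3:
            raise InvalidParameterError(f"grid shape must be 3 positive ints, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or not np.all(np.isfinite(aff)):
            raise AffineError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise AffineError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm (column norms of the affine rotation block)."""
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash(self.shape)

    def voxel_coords_mm(self) -> np.ndarray:
        """(V, 3) MNI mm coordinates of every voxel centre, C-order flat."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return apply_affine(np.asarray(self.affine), idx)


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ affine[:3, :3].T + affine[:3, 3]
    return out if np.asarray(points).ndim > 1 else out[0]


@dataclass
class VolumeMask:
    """Boolean membership per voxel on a grid."""

    grid: VoxelGrid
    member: np.ndarray  # bool, grid.shape

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.member.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_members(self) -> int:
        return int(self.member.sum())

    @property
    def flat(self) -> np.ndarray:
        return self.member.ravel()

    def linear_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flat)

    def coords_mm(self) -> np.ndarray:
        """(n_members, 3) MNI mm coordinates of member voxel centres."""
        ijk = np.argwhere(self.member).astype(float)
        return apply_affine(np.asarray(self.grid.affine), ijk).reshape(-1, 3)

    def intersect(self, other: "VolumeMask") -> "VolumeMask":
        _check_same_grid(self.grid, other.grid)
        return VolumeMask(self.grid, self.member & other.member)

    def minus(self, other: "VolumeMask") -> "VolumeMask":
        _check_same_grid(self.grid, other.grid)
        return VolumeMask(self.grid, self.member & ~other.member)


@dataclass
class ScalarVolume:
    """One finite real value per voxel (weight map, FC map, e-field map)."""

    grid: VoxelGrid
    value: np.ndarray
    allow_nan: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.grid.shape:
            raise GridMismatchError(
                f"volume shape {self.value.shape} != grid shape {self.grid.shape}"
            )
        if not self.allow_nan and not np.all(np.isfinite(self.value)):
            raise InvalidParameterError("ScalarVolume values must be finite")

    @property
    def flat(self) -> np.ndarray:
        return self.value.ravel()


@dataclass(frozen=True)
class SpherePrescription:
    """A spherical ROI given by an MNI-mm centre and radius."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise InvalidParameterError(f"sphere radius must be > 0, got {self.radius_mm}")


def _check_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if a != b:
        raise GridMismatchError("volumes are defined on different grids")


# ---------------------------------------------------------------------------
# Grids


def mni_grid(voxel_mm: float = 4.0) -> VoxelGrid:
    """An isotropic grid covering the MNI box x [-90,90], y [-126,90], z [-72,108].

    The default 4-mm lattice is a coarsened desk-scale version of the 2-mm
    space used for real scans; pass ``voxel_mm=2.0`` for the full-resolution
    lattice.
    """
    if voxel_mm <= 0:
        raise InvalidParameterError("voxel size must be positive")
    origin = np.array([-90.0, -126.0, -72.0])
    extent = np.array([180.0, 216.0, 180.0])
    shape = tuple(int(np.floor(e / voxel_mm)) + 1 for e in extent)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin
    return VoxelGrid(shape, affine)


# ---------------------------------------------------------------------------
# Coordinate transforms


def mm_to_voxel(grid: VoxelGrid, point_mm) -> np.ndarray:
    """Continuous 0-based voxel coordinate of an MNI mm point."""
    inv = np.linalg.inv(np.asarray(grid.affine))
    return apply_affine(inv, point_mm)


def voxel_to_mm(grid: VoxelGrid, voxel) -> np.ndarray:
    """MNI mm coordinate of a (possibly fractional) 0-based voxel index."""
    return apply_affine(np.asarray(grid.affine), voxel)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path):
    """Read a NIfTI file: 3D -> ScalarVolume, 4D -> BoldSeries.

    The repetition time of a 4D series is taken from the NIfTI header
    (``pixdim[4]``); affine, shape and voxel sizes are preserved exactly.
    """
    from .signal import BoldSeries  # local import to avoid cycle

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    try:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=float)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise NiftiFormatError(f"{p} is not a readable NIfTI file: {exc}") from exc
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise AffineError(f"{p} carries a singular or non-finite affine")
    if data.ndim == 3:
        return ScalarVolume(VoxelGrid(data.shape, affine), data)
    if data.ndim == 4:
        grid = VoxelGrid(data.shape[:3], affine)
        tr = float(img.header["pixdim"][4]) or 1.0
        series = data.reshape(-1, data.shape[3]).T  # T x V, C-order voxels
        return BoldSeries(grid=grid, data=series, tr=tr)
    raise NiftiFormatError(f"{p}: expected 3D or 4D data, got {data.ndim}D")


def write_volume(path, obj) -> None:
    """Write a ScalarVolume, VolumeMask or BoldSeries as NIfTI-1."""
    from .signal import BoldSeries

    p = Path(path)
    if isinstance(obj, VolumeMask):
        img = nib.Nifti1Image(obj.member.astype(np.uint8), np.asarray(obj.grid.affine))
    elif isinstance(obj, ScalarVolume):
        img = nib.Nifti1Image(obj.value.astype(np.float64), np.asarray(obj.grid.affine))
    elif isinstance(obj, BoldSeries):
        vol = obj.data.T.reshape(*obj.grid.shape, obj.n_frames)
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), np.asarray(obj.grid.affine))
        img.header["pixdim"][4] = obj.tr
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    nib.save(img, str(p))


# ---------------------------------------------------------------------------
# Masks


def make_sphere_mask(grid: VoxelGrid, sphere: SpherePrescription) -> VolumeMask:
    """Voxels whose centre lies within ``radius_mm`` of the sphere centre.

    Boundary is inclusive (distance <= radius).  A centre outside the grid
    simply yields fewer (possibly zero) members.
    """
    coords = grid.voxel_coords_mm()
    d2 = np.sum((coords - np.asarray(sphere.center_mm, dtype=float)) ** 2, axis=1)
    member = (d2 <= sphere.radius_mm**2).reshape(grid.shape)
    return VolumeMask(grid, member)


def union_masks(masks: list[VolumeMask]) -> VolumeMask:
    """Union of masks sharing one grid."""
    if not masks:
        raise EmptyMaskError("union of zero masks is undefined")
    grid = masks[0].grid
    member = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        _check_same_grid(grid, m.grid)
        member |= m.member
    return VolumeMask(grid, member)


def build_dlpfc_mask(grid: VoxelGrid, radius_mm: float = DLPFC_SPHERE_RADIUS_MM) -> VolumeMask:
    """The merged DLPFC search mask: union of the four 20-mm spheres."""
    spheres = [
        make_sphere_mask(grid, SpherePrescription(c, radius_mm)) for c in DLPFC_SPHERE_CENTERS_MM
    ]
    mask = union_masks(spheres)
    if mask.n_members == 0:
        raise EmptyMaskError("grid does not intersect any DLPFC sphere")
    return mask


def pgc_standin_mask(grid: VoxelGrid) -> VolumeMask:
    """Synthetic spherical stand-in for the PGC seed mask."""
    return make_sphere_mask(
        grid, SpherePrescription(PGC_STANDIN_CENTER_MM, PGC_STANDIN_RADIUS_MM, "pgc-standin")
    )


# ---------------------------------------------------------------------------
# ROI prescription files


def read_roi_prescriptions(path) -> list[SpherePrescription]:
    """Read a JSON list of {center_mm, radius_mm, label} sphere prescriptions."""
    with open(path) as fh:
        entries = json.load(fh)
    return [
        SpherePrescription(tuple(e["center_mm"]), float(e["radius_mm"]), e.get("label", ""))
        for e in entries
    ]


def write_roi_prescriptions(path, spheres: list[SpherePrescription]) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"center_mm": list(s.center_mm), "radius_mm": s.radius_mm, "label": s.label}
                for s in spheres
            ],
            fh,
            indent=2,
        )
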