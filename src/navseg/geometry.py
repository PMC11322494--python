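"""Image geometry: voxel-to-world affines, rigid transforms, and resampling.

All spatial metadata is expressed in millimetres in the DICOM patient-based
LPS (Left-Posterior-Superior) world frame. Voxel indices address voxel
*centers* and are 0-based. Image arrays are indexed ``(slice, row, column)``;
a grid's ``direction`` matrix holds, column by column, the world unit vectors
along which each of those array axes advances.

Rigid world-to-world mappings (e.g. exported navigation registrations) are
represented as 4x4 homogeneous matrices with an orthonormal, det(+1) rotation
block. Chains of such transforms are composed into a single source-to-
destination mapping, and binary masks are resampled onto a destination grid
with nearest-neighbour interpolation so that they stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "GridSpec",
    "ImageVolume",
    "RigidTransform",
    "affine_from_dicom_geometry",
    "compose",
    "apply_to_points",
    "resample_mask",
    "resample_image",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
    "load_transform",
    "save_transform",
]

ORTHONORMAL_TOL = 1e-6  # vendor metadata rounding


class GeometryError(ValueError):
    """Raised for invalid or mismatched spatial metadata."""


def _check_direction(direction: np.ndarray, tol: float = ORTHONORMAL_TOL) -> np.ndarray:
    direction = np.asarray(direction, dtype=float)
    if direction.shape != (3, 3):
        raise GeometryError(f"direction must be 3x3, got {direction.shape}")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=tol):
        raise GeometryError("direction matrix is not orthonormal")
    return direction


def _check_spacing(spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise ValueError(f"spacing must have 3 components, got {spacing.shape}")
    if not np.all(spacing > 0):
        raise ValueError(f"spacing components must be strictly positive: {spacing}")
    return spacing


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: voxel counts plus world-frame placement.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts along the (slice, row, column) array axes.
    spacing : array-like of 3 floats
        Voxel size in mm along each array axis.
    origin : array-like of 3 floats
        World position (mm, LPS) of the center of voxel (0, 0, 0).
    direction : 3x3 array
        Orthonormal matrix; column ``k`` is the world unit vector of array
        axis ``k``. Defaults to the identity.
    frame_of_reference : str
        Opaque label naming the world frame this grid lives in.
    """

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_of_reference: str = ""

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"grid shape must be 3 positive extents, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        origin = np.asarray(self.origin, dtype=float)
        if origin.shape != (3,):
            raise ValueError("origin must have 3 components")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", _check_direction(self.direction))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index-to-world affine (indices in array order)."""
        out = np.eye(4)
        out[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        out[:3, 3] = self.origin
        return out

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return indices * self.spacing @ self.direction.T + self.origin

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin) @ self.direction / self.spacing

    def same_geometry(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar image with full spatial metadata."""

    data: np.ndarray
    geometry: GridSpec

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"image data must be 3D, got ndim={data.ndim}")
        if data.shape != self.geometry.shape:
            raise GeometryError(
                f"data shape {data.shape} does not match grid shape {self.geometry.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def spacing(self) -> np.ndarray:
        return self.geometry.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.geometry.origin

    @property
    def direction(self) -> np.ndarray:
        return self.geometry.direction

    @property
    def frame_of_reference(self) -> str:
        return self.geometry.frame_of_reference


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid world-to-world mapping (rotation + translation).

    The rotation block must be orthonormal with determinant +1 and the last
    row exactly (0, 0, 0, 1).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise GeometryError("last row of a rigid transform must be (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=ORTHONORMAL_TOL):
            raise GeometryError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation block has determinant -1 (reflection)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_euler_deg(cls, angles_deg: Sequence[float], translation_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation from extrinsic x-y-z Euler angles in degrees plus a translation."""
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls.from_rotation_translation(r, translation_mm)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        t = -r @ self.translation
        return RigidTransform.from_rotation_translation(r, t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)


def affine_from_dicom_geometry(
    orientation: Sequence[float],
    position: Sequence[float],
    pixel_spacing: Sequence[float],
    slice_spacing: float,
    slice_normal_sign: int = +1,
) -> np.ndarray:
    """Voxel-to-world affine from DICOM geometry attributes.

    Maps the integer voxel index ``(column, row, slice)`` of a regularly
    spaced series to world mm, using the first slice's ImageOrientationPatient
    (6 direction cosines: row direction then column direction), its
    ImagePositionPatient, the in-plane PixelSpacing ``(row, column)`` and the
    inter-slice spacing. The third matrix column is the cross product of the
    two orientation vectors scaled by ``slice_spacing * slice_normal_sign``,
    because DICOM does not store the stacking direction explicitly.

    Returns the 4x4 affine as a plain array (its linear block is scaled by
    the spacings, hence not itself a rigid transform).
    """
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (6,):
        raise GeometryError("orientation must hold 6 direction cosines")
    row_dir, col_dir = orientation[:3], orientation[3:]
    for v in (row_dir, col_dir):
        if abs(np.linalg.norm(v) - 1.0) > ORTHONORMAL_TOL:
            raise GeometryError("orientation vectors must be unit norm")
    if abs(float(row_dir @ col_dir)) > ORTHONORMAL_TOL:
        raise GeometryError("orientation vectors must be orthogonal")
    pixel_spacing = np.asarray(pixel_spacing, dtype=float)
    if pixel_spacing.shape != (2,) or not np.all(pixel_spacing > 0):
        raise ValueError("pixel_spacing must be 2 positive values (row, column)")
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    if slice_normal_sign not in (+1, -1):
        raise ValueError("slice_normal_sign must be +1 or -1")

    normal = np.cross(row_dir, col_dir) * float(slice_spacing) * slice_normal_sign
    affine = np.eye(4)
    # index order (column, row, slice): columns advance along row_dir spaced
    # by the column spacing, rows along col_dir spaced by the row spacing
    affine[:3, 0] = row_dir * pixel_spacing[1]
    affine[:3, 1] = col_dir * pixel_spacing[0]
    affine[:3, 2] = normal
    affine[:3, 3] = np.asarray(position, dtype=float)
    return affine


def grid_from_dicom_geometry(
    shape: tuple[int, int, int],
    orientation: Sequence[float],
    position: Sequence[float],
    pixel_spacing: Sequence[float],
    slice_spacing: float,
    slice_normal_sign: int = +1,
    frame_of_reference: str = "",
) -> GridSpec:
    """GridSpec (array order slice, row, column) from DICOM geometry attributes."""
    affine = affine_from_dicom_geometry(
        orientation, position, pixel_spacing, slice_spacing, slice_normal_sign
    )
    # reorder columns from (column, row, slice) index order to array order
    lin = affine[:3, [2, 1, 0]]
    spacing = np.linalg.norm(lin, axis=0)
    direction = lin / spacing
    return GridSpec(
        shape=shape,
        spacing=spacing,
        origin=affine[:3, 3],
        direction=direction,
        frame_of_reference=frame_of_reference,
    )


def compose(transforms: Iterable[RigidTransform]) -> RigidTransform:
    """Compose an ordered chain of rigid transforms into a single mapping.

    ``compose([T1, T2, ..., Tn])`` applies T1 first: the result equals
    ``Tn @ ... @ T2 @ T1`` so that applying the composite to points matches
    applying the chain element by element.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("cannot compose an empty transform chain")
    matrix = np.eye(4)
    for t in transforms:
        matrix = t.matrix @ matrix
    return RigidTransform(matrix)


def apply_to_points(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an N x 3 array of world points (mm)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[-1] != 3 or not np.all(np.isfinite(points)):
        raise ValueError("points must be a finite N x 3 array")
    return points @ transform.rotation.T + transform.translation


def _index_map(source: GridSpec, transform: RigidTransform, destination: GridSpec) -> np.ndarray:
    """Affine sending destination voxel indices to source voxel indices.

    ``transform`` maps *source* world coordinates to *destination* world
    coordinates, so destination points are pulled back through its inverse.
    """
    src_affine_inv = np.linalg.inv(source.affine)
    return src_affine_inv @ transform.inverse().matrix @ destination.affine


def resample_image(
    image: ImageVolume,
    transform: RigidTransform,
    destination: GridSpec,
    order: int = 1,
    cval: float = 0.0,
) -> ImageVolume:
    """Resample a scalar volume onto a destination grid (spline order ``order``)."""
    m = _index_map(image.geometry, transform, destination)
    out = ndimage.affine_transform(
        np.asarray(image.data, dtype=float),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=destination.shape,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=order > 1,
    )
    return ImageVolume(out, destination)


def resample_mask(mask, transform: RigidTransform, destination: GridSpec):
    """Resample a binary mask onto a destination grid.

    Nearest-neighbour interpolation keeps the mask strictly binary; voxels
    whose pull-back lands outside the source extent become background. The
    output carries the destination geometry.
    """
    from .masks import BinaryMask  # local import: masks builds on geometry

    m = _index_map(mask.geometry, transform, destination)
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=destination.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(out.astype(bool), destination, label=mask.label)


# ---------------------------------------------------------------------------
# File formats: NIfTI volumes/masks, DICOM series geometry, plain-text matrices
# ---------------------------------------------------------------------------

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _grid_from_lps_affine(shape, affine_lps, frame_of_reference="") -> GridSpec:
    lin = affine_lps[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if not np.all(spacing > 0):
        raise GeometryError("degenerate affine: zero-length axis")
    return GridSpec(
        shape=shape,
        spacing=spacing,
        origin=affine_lps[:3, 3],
        direction=lin / spacing,
        frame_of_reference=frame_of_reference,
    )


def read_nifti(path, frame_of_reference: str = "") -> ImageVolume:
    """Read a NIfTI-1 volume; the RAS affine is converted to LPS world mm."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    affine_lps = _RAS_TO_LPS @ img.affine
    geom = _grid_from_lps_affine(data.shape, affine_lps, frame_of_reference)
    return ImageVolume(data, geom)


def write_nifti(image: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 (LPS metadata converted back to RAS)."""
    import nibabel as nib

    affine_ras = _RAS_TO_LPS @ image.geometry.affine
    data = image.data
    if data.dtype == bool:
        data = data.astype(np.uint8)  # masks stored as 0/1 integers
    nib.save(nib.Nifti1Image(data, affine_ras), str(path))


def read_nifti_mask(path, label: str = "", frame_of_reference: str = ""):
    """Read a NIfTI segmentation as a BinaryMask (non-zero voxels foreground)."""
    from .masks import BinaryMask

    vol = read_nifti(path, frame_of_reference)
    return BinaryMask(vol.data > 0, vol.geometry, label=label)


def write_nifti_mask(mask, path) -> None:
    write_nifti(ImageVolume(mask.data.astype(np.uint8), mask.geometry), path)


def read_dicom_series(paths: Sequence, frame_of_reference: str | None = None) -> ImageVolume:
    """Assemble a volume from single-frame DICOM files (geometry attributes only).

    Slices are sorted by the projection of ImagePositionPatient onto the
    plane normal; the inter-slice spacing and the stacking sign are derived
    from successive positions. Requires >= 2 slices with consistent
    orientation and in-plane spacing.
    """
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]
    if len(datasets) < 2:
        raise GeometryError("need at least two slices to derive slice spacing")
    orientation = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    pixel_spacing = np.asarray(datasets[0].PixelSpacing, dtype=float)
    for ds in datasets[1:]:
        if not np.allclose(ds.ImageOrientationPatient, orientation, atol=1e-6):
            raise GeometryError("inconsistent ImageOrientationPatient across slices")
        if not np.allclose(ds.PixelSpacing, pixel_spacing, atol=1e-6):
            raise GeometryError("inconsistent PixelSpacing across slices")
    normal = np.cross(orientation[:3], orientation[3:])
    positions = np.array([ds.ImagePositionPatient for ds in datasets], dtype=float)
    order = np.argsort(positions @ normal)
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    steps = np.diff(positions @ normal)
    if not np.allclose(steps, steps[0], atol=1e-3) or steps[0] <= 0:
        raise GeometryError("slices are not regularly spaced")
    slice_spacing = float(steps[0])

    data = np.stack([ds.pixel_array for ds in datasets], axis=0)  # (slice, row, col)
    if frame_of_reference is None:
        frame_of_reference = str(getattr(datasets[0], "FrameOfReferenceUID", ""))
    geom = grid_from_dicom_geometry(
        shape=data.shape,
        orientation=orientation,
        position=positions[0],
        pixel_spacing=pixel_spacing,
        slice_spacing=slice_spacing,
        slice_normal_sign=+1,  # sorted ascending along the normal
        frame_of_reference=frame_of_reference,
    )
    return ImageVolume(data, geom)


def load_transform(path) -> RigidTransform:
    """Load a 4x4 rigid matrix from a whitespace-separated text file."""
    m = np.loadtxt(str(path), dtype=float)
    if m.shape != (4, 4):
        raise GeometryError(f"transform file must hold a 4x4 matrix, got {m.shape}")
    return RigidTransform(m)


def save_transform(transform: RigidTransform, path) -> None:
    np.savetxt(str(path), transform.matrix, fmt="%.12g")
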