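"""Pairwise spatial agreement between two segmentations on a common grid.

Metrics
-------
Dice similarity coefficient (DSC)
    ``2 |A ∩ B| / (|A| + |B|)`` on voxel counts; overlap in [0, 1].
Hausdorff distances
    Euclidean distance (world mm, anisotropic spacing honored) from every
    foreground voxel center in one mask to the closest foreground voxel
    center in the other. Both directions are pooled into one multiset; the
    maximum of that pool is the Hausdorff distance and its 95th percentile
    (linear interpolation between order statistics) is the outlier-robust
    HD95. A surface-points variant restricts the point sets to boundary
    voxels.
Volume difference
    Signed (a - b) and absolute difference of the two mask volumes in cm^3.

Qualitative interpretation follows common clinical reading: a DSC between
0.7 and 0.9 counts as good similarity, and an HD95 under 10 mm as clinically
relevant (within typical surgical margins).

Metrics are undefined rather than zero when a mask is empty: overlap and
distance statistics are only meaningful where both modalities segmented
something, so those cases raise :class:`UndefinedMetricError`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .geometry import GeometryError
from .masks import BinaryMask, mask_volume

__all__ = [
    "UndefinedMetricError",
    "AgreementResult",
    "dice",
    "hausdorff_distances",
    "volume_difference",
    "classify_agreement",
    "compare_masks",
    "GOOD_DSC_RANGE",
    "CLINICALLY_RELEVANT_HD95_MM",
]

GOOD_DSC_RANGE = (0.7, 0.9)
CLINICALLY_RELEVANT_HD95_MM = 10.0


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. empty mask input)."""


@dataclass(frozen=True)
class AgreementResult:
    """Agreement metrics for one mask pair (a vs b)."""

    dsc: float
    hd95_mm: float
    hd_max_mm: float
    vol_a_cm3: float
    vol_b_cm3: float
    vol_diff_signed_cm3: float
    vol_diff_abs_cm3: float

    def __post_init__(self):
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"dsc out of [0,1]: {self.dsc}")
        if self.hd95_mm < 0 or self.hd95_mm > self.hd_max_mm + 1e-9:
            raise ValueError("need 0 <= hd95 <= hd_max")
        if abs(self.vol_diff_abs_cm3 - abs(self.vol_diff_signed_cm3)) > 1e-9:
            raise ValueError("absolute volume difference must equal |signed|")

    def to_dict(self) -> dict:
        return asdict(self)


def _require_same_geometry(a: BinaryMask, b: BinaryMask) -> None:
    if not a.geometry.same_geometry(b.geometry):
        raise GeometryError("masks must live on the same grid")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a|+|b|) on voxel counts."""
    _require_same_geometry(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise UndefinedMetricError("DSC is undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def _point_array(mask: BinaryMask, surface_only: bool) -> np.ndarray:
    data = mask.data
    if surface_only:
        data = data & ~ndimage.binary_erosion(data)
    return np.argwhere(data)


def _directed_distances_edt(
    from_pts_data: np.ndarray, to_data: np.ndarray, spacing: np.ndarray
) -> np.ndarray:
    # EDT of the complement gives, per voxel, the distance to the nearest
    # foreground voxel center of the target set (anisotropic sampling).
    dist = ndimage.distance_transform_edt(~to_data, sampling=spacing)
    return dist[from_pts_data]


def hausdorff_distances(
    a: BinaryMask,
    b: BinaryMask,
    percentile: float = 95.0,
    surface_only: bool = False,
    method: str = "edt",
) -> tuple[float, float]:
    """Pooled bidirectional Hausdorff distances in world mm.

    Returns ``(hd_percentile_mm, hd_max_mm)``. The pooled multiset holds the
    directed point-to-set distances a->b and b->a; ``hd_max`` is its maximum
    and the percentile uses linear interpolation between order statistics.

    ``method='edt'`` uses a Euclidean distance transform on the complement
    grid (fast for large masks); ``method='brute'`` computes all pairwise
    world distances (exact oracle for small masks). Both give voxel-center
    distances and agree on any input small enough to brute-force.
    """
    _require_same_geometry(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        raise UndefinedMetricError("Hausdorff distance is undefined for an empty mask")
    spacing = a.geometry.spacing

    a_data, b_data = a.data, b.data
    if surface_only:
        a_data = a_data & ~ndimage.binary_erosion(a_data)
        b_data = b_data & ~ndimage.binary_erosion(b_data)

    if method == "edt":
        d_ab = _directed_distances_edt(a_data, b_data, spacing)
        d_ba = _directed_distances_edt(b_data, a_data, spacing)
    elif method == "brute":
        pts_a = np.argwhere(a_data) * spacing
        pts_b = np.argwhere(b_data) * spacing
        dm = cdist(pts_a, pts_b)
        d_ab = dm.min(axis=1)
        d_ba = dm.min(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}; use 'edt' or 'brute'")

    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, percentile)), float(pooled.max())


def volume_difference(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Signed (a - b) and absolute volume difference in cm^3.

    Extents may differ, but the voxel size must match so the volumes are
    commensurable.
    """
    if not np.allclose(a.geometry.spacing, b.geometry.spacing, atol=1e-6):
        raise GeometryError("volume difference requires matching voxel spacing")
    signed = mask_volume(a) - mask_volume(b)
    return signed, abs(signed)


def classify_agreement(result: AgreementResult) -> dict:
    """Qualitative flags: good DSC band (0.7-0.9) and HD95 < 10 mm."""
    lo, hi = GOOD_DSC_RANGE
    return {
        "good_dsc": bool(lo <= result.dsc <= hi),
        "clinically_relevant_hd": bool(result.hd95_mm < CLINICALLY_RELEVANT_HD95_MM),
    }


def compare_masks(
    a: BinaryMask,
    b: BinaryMask,
    percentile: float = 95.0,
    surface_only: bool = False,
    method: str = "edt",
) -> AgreementResult:
    """All agreement metrics for one mask pair on a common grid."""
    hd95, hd_max = hausdorff_distances(
        a, b, percentile=percentile, surface_only=surface_only, method=method
    )
    signed, absolute = volume_difference(a, b)
    return AgreementResult(
        dsc=dice(a, b),
        hd95_mm=hd95,
        hd_max_mm=hd_max,
        vol_a_cm3=mask_volume(a),
        vol_b_cm3=mask_volume(b),
        vol_diff_signed_cm3=signed,
        vol_diff_abs_cm3=absolute,
    )
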