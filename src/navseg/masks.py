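"""Binary segmentation masks: volumes, connected components, cyst exclusion.

A :class:`BinaryMask` is a boolean 3D array tied to the :class:`~navseg.geometry.GridSpec`
it lives on. Volumes are reported in cm^3 (voxel count x voxel volume in mm^3,
divided by 1000). Before agreement metrics are computed, large solitary cystic
components (connected components that are majority cystic and strictly larger
than 2 cm^3) are removed from the segmentation, mirroring how fluid-filled
cavities are excluded from solid-tumor delineations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import GeometryError, GridSpec

__all__ = [
    "BinaryMask",
    "ComponentReport",
    "mask_volume",
    "connected_components",
    "exclude_cystic_components",
    "component_reports_to_csv",
]

CYST_VOLUME_THRESHOLD_CM3 = 2.0  # strict: components must exceed this to be dropped
CYST_MAJORITY_FRACTION = 0.5

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class BinaryMask:
    """Boolean 3D grid sharing an image's geometry."""

    data: np.ndarray
    geometry: GridSpec
    label: str = ""

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != bool:
            uniques = np.unique(data)
            if not np.all(np.isin(uniques, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            data = data.astype(bool)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got ndim={data.ndim}")
        if data.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {data.shape} does not match grid shape {self.geometry.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data, self.geometry, self.label)


@dataclass(frozen=True)
class ComponentReport:
    """One connected component: id, size, and cystic flag."""

    component_id: int
    voxel_count: int
    volume_cm3: float
    flagged_cystic: bool = False

    def __post_init__(self):
        if self.volume_cm3 < 0 or self.voxel_count < 0:
            raise ValueError("component sizes must be non-negative")


def mask_volume(mask: BinaryMask) -> float:
    """Foreground volume in cm^3 (voxel count x voxel volume, mm^3 -> cm^3)."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3 / 1000.0


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def connected_components(
    mask: BinaryMask,
    connectivity: int = 26,
    cyst_labels: BinaryMask | None = None,
) -> tuple[list[ComponentReport], np.ndarray]:
    """Label connected foreground components.

    Returns per-component reports (ids 1..n, voxel counts, volumes; cystic
    flag set when a ``cyst_labels`` mask is supplied and the component is
    majority cystic) plus the labeled integer array.
    """
    if cyst_labels is not None and not cyst_labels.geometry.same_geometry(mask.geometry):
        raise GeometryError("cyst labels must share the mask's geometry")
    labeled, n = ndimage.label(mask.data, structure=_structure(connectivity))
    voxel_vol = mask.geometry.voxel_volume_mm3 / 1000.0
    reports = []
    for cid in range(1, n + 1):
        inside = labeled == cid
        count = int(inside.sum())
        cystic = False
        if cyst_labels is not None:
            cystic = float((inside & cyst_labels.data).sum()) / count > CYST_MAJORITY_FRACTION
        reports.append(
            ComponentReport(
                component_id=cid,
                voxel_count=count,
                volume_cm3=count * voxel_vol,
                flagged_cystic=cystic,
            )
        )
    return reports, labeled


def exclude_cystic_components(
    mask: BinaryMask,
    cyst_labels: BinaryMask,
    threshold_cm3: float = CYST_VOLUME_THRESHOLD_CM3,
    connectivity: int = 26,
) -> BinaryMask:
    """Drop large solitary cystic components from a segmentation.

    A connected component is removed when it is majority-cystic (> 50% of its
    voxels carry the cyst label) *and* strictly larger than ``threshold_cm3``.
    All other voxels are unchanged. Idempotent, never increases volume.
    """
    if not cyst_labels.geometry.same_geometry(mask.geometry):
        raise GeometryError("cyst labels must share the mask's geometry")
    reports, labeled = connected_components(mask, connectivity, cyst_labels)
    drop = [r.component_id for r in reports if r.flagged_cystic and r.volume_cm3 > threshold_cm3]
    if not drop:
        return mask
    keep = mask.data & ~np.isin(labeled, drop)
    return mask.with_data(keep)


def component_reports_to_csv(reports: list[ComponentReport], path) -> None:
    """Write component reports as CSV (id, voxels, cm3, cystic flag)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "component_id": r.component_id,
                "voxel_count": r.voxel_count,
                "volume_cm3": r.volume_cm3,
                "flagged_cystic": r.flagged_cystic,
            }
            for r in reports
        ]
    ).to_csv(path, index=False)
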