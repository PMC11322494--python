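"""Synthetic paired MRI/ultrasound tumor phantoms and cohorts.

Patient images behind intraoperative residual-tumor studies are rarely
shareable, so this module generates stand-ins with the statistical structure
the analysis pipeline assumes:

* connected, organ-like tumor masks built from chains of overlapping random
  ellipsoids, with the achieved volume driven to a target by bisection on a
  global scale factor;
* an "observed" ultrasound segmentation derived from the ground truth by
  smooth boundary noise plus a global volume bias (threshold shifts on the
  signed distance field), resampled onto an anisotropic ultrasound-like grid
  (0.24 x 0.24 mm in-plane, 1 mm slices) and displaced by a known small rigid
  misregistration (<= 5 deg, <= 5 mm);
* optional cystic components and false-positive artifact blobs;
* whole cohorts with configurable residual-disease prevalence, emitted as
  patient-record tables, either volumes-only (fast, statistical) or with the
  full 3D cases rendered.

Everything is deterministic under a fixed master seed; per-case seeds are
derived from it and recorded in the truth table.

Default condition parameters: tumor volumes are drawn log-uniformly over
0.35-107 cm^3 and residual volumes over 0.90-7.95 cm^3 (the pre-resection and
residual ranges typical of pediatric brain-tumor cohorts), residual-disease
prevalence 10/23, and boundary noise 4 mm, which places cohort median DSC
in the ~0.7 regime reported for navigated-ultrasound vs MRI tumor overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, ImageVolume, RigidTransform, resample_mask
from .masks import BinaryMask, mask_volume
from .agreement import compare_masks

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "PhantomTruth",
    "generate_tumor_mask",
    "perturb_mask",
    "dilate_mask",
    "generate_case",
    "generate_cohort",
    "simulate_volume_pairs",
    "case_seed",
]

MAX_FIELD_OF_VIEW_MM = 256.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative conditions for one phantom case or a cohort of them.

    Volumes in cm^3, lengths in mm, angles in degrees. ``seed`` is mandatory:
    every phantom is a pure function of its spec and seed.
    """

    seed: int
    tumor_volume_range_cm3: tuple[float, float] = (0.35, 107.0)
    residual_volume_range_cm3: tuple[float, float] = (0.90, 7.95)
    residual_prevalence: float = 10.0 / 23.0
    mri_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    us_spacing_mm: tuple[float, float, float] = (1.0, 0.24, 0.24)
    max_rotation_deg: float = 5.0
    max_translation_mm: float = 5.0
    boundary_noise_mm: float = 4.0
    noise_correlation_mm: float = 5.0
    volume_bias_fraction: float = 0.0
    cyst_probability: float = 0.2
    cyst_volume_range_cm3: tuple[float, float] = (0.5, 6.0)
    artifact_probability: float = 2.0 / 13.0
    artifact_volume_cm3: float = 0.3

    def __post_init__(self):
        for name in ("tumor_volume_range_cm3", "residual_volume_range_cm3", "cyst_volume_range_cm3"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive increasing range")
        for name in ("residual_prevalence", "cyst_probability", "artifact_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass(frozen=True)
class PhantomTruth:
    """Generative parameters recorded for one case."""

    case_id: str
    seed: int
    residual_on_truth: bool
    true_tumor_volume_cm3: float
    true_residual_volume_cm3: float | None
    observed_volume_cm3: float | None
    cyst_volume_cm3: float
    rotation_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    true_dsc: float | None
    true_hd95_mm: float | None


@dataclass(frozen=True)
class PhantomCase:
    """One rendered phantom: truth on the MRI grid, observation on the US grid."""

    truth: PhantomTruth
    mri_mask: BinaryMask
    us_mask: BinaryMask
    cyst_labels: BinaryMask
    transform: RigidTransform  # maps US world -> MRI world
    mri_image: ImageVolume | None = None
    us_image: ImageVolume | None = None


def case_seed(master_seed: int, index: int) -> int:
    """Deterministic per-case seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def _grid_for_volume(target_volume_cm3: float, spacing_mm, margin_mm: float = 12.0) -> GridSpec:
    """Cubic (in mm) field of view sized to hold the tumor with margin."""
    r_mm = (3.0 * target_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    fov = 2.0 * (2.0 * r_mm + margin_mm)
    if fov > MAX_FIELD_OF_VIEW_MM:
        raise ValueError(
            f"target volume {target_volume_cm3} cm^3 needs a field of view of "
            f"{fov:.0f} mm, beyond the {MAX_FIELD_OF_VIEW_MM:.0f} mm limit"
        )
    spacing = np.asarray(spacing_mm, dtype=float)
    shape = tuple(int(np.ceil(fov / s)) for s in spacing)
    # center the FOV on the world origin
    origin = -(np.array(shape) - 1) * spacing / 2.0
    return GridSpec(shape=shape, spacing=spacing, origin=origin, frame_of_reference="phantom")


def _ellipsoid_field(grid: GridSpec, centers, radii, rotations) -> np.ndarray:
    """Min over ellipsoids of the normalized quadratic form (<=1 means inside)."""
    idx = np.indices(grid.shape, dtype=float)
    world = np.stack(
        [idx[k] * grid.spacing[k] for k in range(3)], axis=-1
    ) @ grid.direction.T + grid.origin
    q = np.full(grid.shape, np.inf)
    for c, r, rot in zip(centers, radii, rotations):
        local = (world - c) @ rot / r
        q = np.minimum(q, np.einsum("...k,...k->...", local, local))
    return q


def _random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def generate_tumor_mask(
    target_volume_cm3: float,
    grid: GridSpec,
    rng: np.random.Generator,
    n_lobes_range: tuple[int, int] = (3, 7),
    center_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[BinaryMask, float]:
    """Connected, lobulated tumor blob at a target volume.

    The blob is a union of 3-7 overlapping random ellipsoids chained so each
    center lies inside the previous ellipsoid (hence connected). All radii are
    scaled by a common factor found by bisection so the achieved volume is
    within 2% of the target. Deterministic given the generator state.
    """
    if target_volume_cm3 <= 0:
        raise ValueError("target volume must be positive")
    n = int(rng.integers(n_lobes_range[0], n_lobes_range[1] + 1))
    base_r = (3.0 * target_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    centers = [np.asarray(center_mm, dtype=float)]
    radii = [base_r * rng.uniform(0.7, 1.1, size=3)]
    rotations = [_random_rotation(rng)]
    for _ in range(n - 1):
        parent = len(centers) - 1
        offset = rng.uniform(-0.6, 0.6, size=3) * radii[parent]
        centers.append(centers[parent] + rotations[parent] @ offset)
        radii.append(base_r * rng.uniform(0.3, 0.8, size=3))
        rotations.append(_random_rotation(rng))

    q = _ellipsoid_field(grid, centers, radii, rotations)
    target_mm3 = target_volume_cm3 * 1000.0
    voxel_mm3 = grid.voxel_volume_mm3

    def volume_at(scale: float) -> float:
        return float((q <= scale * scale).sum()) * voxel_mm3

    lo, hi = 0.05, 1.0
    while volume_at(hi) < target_mm3:
        hi *= 1.3
        if hi > 8.0:
            raise ValueError("target volume infeasible for this grid extent")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if volume_at(mid) < target_mm3:
            lo = mid
        else:
            hi = mid
    mask_data = q <= hi * hi
    achieved = float(mask_data.sum()) * voxel_mm3 / 1000.0
    if abs(achieved - target_volume_cm3) > 0.02 * target_volume_cm3:
        raise ValueError(
            f"could not reach target volume {target_volume_cm3} cm^3 on this grid "
            f"(achieved {achieved:.3f}); the grid may be too coarse or too small"
        )
    return BinaryMask(mask_data, grid, label="tumor"), achieved


def _signed_distance(data: np.ndarray, spacing) -> np.ndarray:
    """Positive inside the mask, negative outside, in mm."""
    inside = ndimage.distance_transform_edt(data, sampling=spacing)
    outside = ndimage.distance_transform_edt(~data, sampling=spacing)
    return inside - outside


def dilate_mask(mask: BinaryMask, mm: float) -> BinaryMask:
    """Grow (mm > 0) or shrink (mm < 0) a mask by a metric margin."""
    d = _signed_distance(mask.data, mask.geometry.spacing)
    return mask.with_data(d >= -mm)


def _smooth_noise_field(shape, spacing, correlation_mm, rng) -> np.ndarray:
    sigma_vox = np.asarray(correlation_mm, dtype=float) / np.asarray(spacing, dtype=float)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = g.std()
    if sd == 0:
        return np.zeros(shape)
    return g / sd


def perturb_mask(
    mask: BinaryMask,
    boundary_noise_mm: float,
    volume_bias_fraction: float,
    rng: np.random.Generator,
    noise_correlation_mm: float = 5.0,
) -> BinaryMask:
    """Emulate an observed segmentation of a known truth mask.

    A spatially smooth Gaussian field (unit variance, correlation length
    ``noise_correlation_mm``) scaled by ``boundary_noise_mm`` is added to the
    signed distance of the truth, displacing the boundary locally; the
    threshold is then shifted by bisection so the perturbed volume equals
    ``(1 + volume_bias_fraction)`` times the truth volume. Zero noise and zero
    bias return the mask unchanged. The expected overlap with the truth
    decreases monotonically as the boundary noise grows.
    """
    if boundary_noise_mm < 0:
        raise ValueError("boundary noise must be non-negative")
    if boundary_noise_mm == 0 and volume_bias_fraction == 0:
        return mask
    spacing = mask.geometry.spacing
    d = _signed_distance(mask.data, spacing)
    if boundary_noise_mm > 0:
        d = d + boundary_noise_mm * _smooth_noise_field(
            mask.data.shape, spacing, noise_correlation_mm, rng
        )
    target = mask.voxel_count * (1.0 + volume_bias_fraction)
    k = min(int(round(target)), d.size)
    if k < 1:
        raise ValueError("volume bias would shrink the mask to empty")
    # take the k voxels with the largest perturbed signed distance; ties on
    # plateaus of the distance field are broken deterministically by index
    order = np.argsort(d, axis=None, kind="stable")[::-1]
    out = np.zeros(d.size, dtype=bool)
    out[order[:k]] = True
    return mask.with_data(out.reshape(d.shape))


def _random_rigid(
    rng, max_rotation_deg: float, max_translation_mm: float
) -> tuple[RigidTransform, np.ndarray, np.ndarray]:
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    trans = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_euler_deg(angles, trans), angles, trans


def _render_intensities(mask: BinaryMask, rng, tumor_level=2.0, noise_sd=0.2) -> ImageVolume:
    # visual QC only: hyperintense tumor on noisy background; metrics never read this
    data = 1.0 + (tumor_level - 1.0) * mask.data + noise_sd * rng.standard_normal(mask.data.shape)
    return ImageVolume(data, mask.geometry)


def generate_case(
    spec: PhantomSpec,
    seed: int | None = None,
    case_id: str = "case",
    stage: str = "pre",
    render_intensities: bool = False,
) -> PhantomCase:
    """Render one paired phantom case.

    ``stage='pre'`` draws a tumor from the pre-resection volume range;
    ``stage='post'`` draws a residual-positive or residual-negative case per
    the spec's prevalence, with residual volumes from the residual range.

    The truth mask lives on the MRI grid. The observed mask is the perturbed
    truth resampled onto the ultrasound grid and displaced by a random small
    rigid misregistration; ``case.transform`` is the true mapping from the
    ultrasound frame back to the MRI frame. The recorded true DSC/HD95 are
    computed post-hoc on the MRI grid from the truth and the correctly
    re-registered observation.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    residual_positive = True
    if stage == "post":
        residual_positive = bool(rng.random() < spec.residual_prevalence)
        lo, hi = spec.residual_volume_range_cm3
    elif stage == "pre":
        lo, hi = spec.tumor_volume_range_cm3
    else:
        raise ValueError("stage must be 'pre' or 'post'")
    target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    transform, angles, trans = _random_rigid(rng, spec.max_rotation_deg, spec.max_translation_mm)

    if stage == "post" and not residual_positive:
        # empty truth; optionally a false-positive artifact blob on the US side
        grid = _grid_for_volume(hi, spec.mri_spacing_mm)
        truth = BinaryMask(np.zeros(grid.shape, dtype=bool), grid, label="residual")
        cysts = truth.with_data(np.zeros(grid.shape, dtype=bool))
        us_grid = _grid_for_volume(hi, spec.us_spacing_mm)
        us_data = np.zeros(us_grid.shape, dtype=bool)
        observed = BinaryMask(us_data, us_grid, label="residual")
        observed_vol = 0.0
        if rng.random() < spec.artifact_probability:
            blob, _ = generate_tumor_mask(spec.artifact_volume_cm3, us_grid, rng)
            observed = observed.with_data(blob.data)
            observed_vol = mask_volume(observed)
        record = PhantomTruth(
            case_id=case_id,
            seed=seed,
            residual_on_truth=False,
            true_tumor_volume_cm3=0.0,
            true_residual_volume_cm3=0.0,
            observed_volume_cm3=observed_vol,
            cyst_volume_cm3=0.0,
            rotation_deg=tuple(angles),
            translation_mm=tuple(trans),
            true_dsc=None,
            true_hd95_mm=None,
        )
        return PhantomCase(record, truth, observed, cysts, transform)

    grid = _grid_for_volume(target, spec.mri_spacing_mm)
    truth, achieved = generate_tumor_mask(target, grid, rng)
    if stage == "post":
        truth = truth.with_data(truth.data)  # residual blob, same construction
        truth = BinaryMask(truth.data, grid, label="residual")

    cyst_data = np.zeros(grid.shape, dtype=bool)
    cyst_volume = 0.0
    if rng.random() < spec.cyst_probability:
        clo, chi = spec.cyst_volume_range_cm3
        cyst_target = float(np.exp(rng.uniform(np.log(clo), np.log(chi))))
        # place the cyst just outside the tumor so it forms its own component
        r_mm = (3.0 * achieved * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        c_r = (3.0 * cyst_target * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        # keep the cyst solitary: the gap must survive the boundary noise
        gap = 3.0 + 2.0 * spec.boundary_noise_mm
        center = direction * (r_mm + c_r + gap)
        try:
            cyst_mask, _ = generate_tumor_mask(
                cyst_target, grid, rng, n_lobes_range=(1, 2), center_mm=center
            )
            cyst_data = cyst_mask.data & ~truth.data
            cyst_volume = float(cyst_data.sum()) * grid.voxel_volume_mm3 / 1000.0
        except ValueError:
            pass  # cyst did not fit the FOV; skip it
    cysts = BinaryMask(cyst_data, grid, label="cyst")

    observed_mri = perturb_mask(
        truth.with_data(truth.data | cyst_data),
        spec.boundary_noise_mm,
        spec.volume_bias_fraction,
        rng,
        spec.noise_correlation_mm,
    )
    us_grid = GridSpec(
        shape=tuple(
            int(np.ceil(grid.shape[k] * grid.spacing[k] / spec.us_spacing_mm[k]))
            for k in range(3)
        ),
        spacing=spec.us_spacing_mm,
        origin=grid.origin,
        direction=grid.direction,
        frame_of_reference="us",
    )
    # the transform maps US world -> MRI world, so the US rendering pulls the
    # observation through its inverse
    observed_us = resample_mask(observed_mri, transform.inverse(), us_grid)
    observed_us = BinaryMask(observed_us.data, us_grid, label=truth.label)

    # post-hoc truth metrics on the common (MRI) grid, correctly re-registered
    # and with large solitary cysts excluded, mirroring the analysis pipeline
    from .masks import exclude_cystic_components

    back = resample_mask(observed_us, transform, grid)
    back = exclude_cystic_components(back, cysts)
    res = compare_masks(truth, back)

    record = PhantomTruth(
        case_id=case_id,
        seed=seed,
        residual_on_truth=residual_positive,
        true_tumor_volume_cm3=achieved if stage == "pre" else 0.0,
        true_residual_volume_cm3=achieved if stage == "post" else None,
        observed_volume_cm3=mask_volume(observed_us),
        cyst_volume_cm3=cyst_volume,
        rotation_deg=tuple(angles),
        translation_mm=tuple(trans),
        true_dsc=res.dsc,
        true_hd95_mm=res.hd95_mm,
    )
    mri_img = _render_intensities(truth, rng) if render_intensities else None
    us_img = _render_intensities(observed_us, rng) if render_intensities else None
    return PhantomCase(record, truth, observed_us, cysts, transform, mri_img, us_img)


def simulate_volume_pairs(
    n: int,
    rho: float,
    bias_cm3: float,
    seed: int,
    volume_range_cm3: tuple[float, float] = (0.35, 107.0),
) -> np.ndarray:
    """Paired (ultrasound, MRI) volumes with a known correlation and bias.

    MRI volumes are drawn log-uniformly over ``volume_range_cm3``; ultrasound
    volumes add ``bias_cm3`` plus Gaussian noise whose variance is set from
    the sample variance so the generative Pearson correlation equals ``rho``.
    Ultrasound volumes are floored at zero. Returns an (n, 2) array of
    (ius, mri) pairs.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = volume_range_cm3
    mri = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if rho == 1.0:
        noise = np.zeros(n)
    else:
        sigma = np.sqrt(mri.var() * (1.0 / rho**2 - 1.0))
        noise = rng.normal(0.0, sigma, size=n)
    ius = np.maximum(mri + bias_cm3 + noise, 0.0)
    return np.column_stack([ius, mri])


def generate_cohort(
    n: int,
    spec: PhantomSpec,
    render: bool = False,
) -> tuple["pd.DataFrame", list[PhantomCase]]:
    """Simulate a cohort of patients with the pipeline's record schema.

    Per-case seeds derive from ``spec.seed``. Residual-disease prevalence and
    volume ranges follow the spec. In volumes-only mode (default) the
    ultrasound measurements come from the statistical volume-noise model; with
    ``render=True`` every case is rendered in 3D (slow for large cohorts) and
    measured volumes are read off the generated masks.

    Returns the patient-record table (pandas DataFrame, cohort CSV schema)
    and the list of rendered cases (empty unless ``render``).
    """
    import pandas as pd

    if n < 1:
        raise ValueError("cohort size must be >= 1")
    master = np.random.default_rng(spec.seed)
    tumor_types = [
        "Pilocytic astrocytoma",
        "Medulloblastoma",
        "Ependymoma",
        "Craniopharyngioma",
        "Low grade glioma",
        "DNET",
        "Other",
    ]
    type_p = np.array([9, 3, 2, 3, 2, 2, 3], dtype=float)
    type_p /= type_p.sum()
    locations = ["Hemispheric", "Infratentorial", "Intraventricular", "Suprasellar"]
    loc_p = np.array([8, 10, 2, 4], dtype=float)
    loc_p /= loc_p.sum()

    rows = []
    cases: list[PhantomCase] = []
    for i in range(n):
        cseed = case_seed(spec.seed, i)
        rng = np.random.default_rng(cseed)
        age = float(np.clip(rng.normal(7.6, 3.9), 0.5, 18.0))
        sex = "Male" if rng.random() < 0.625 else "Female"
        ttype = str(rng.choice(tumor_types, p=type_p))
        tloc = str(rng.choice(locations, p=loc_p))

        lo, hi = spec.tumor_volume_range_cm3
        preop = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        residual = bool(rng.random() < spec.residual_prevalence)
        rlo, rhi = spec.residual_volume_range_cm3
        resid_vol = float(np.exp(rng.uniform(np.log(rlo), np.log(rhi)))) if residual else 0.0

        rel_noise = spec.boundary_noise_mm * 0.02  # relative volume scatter per mm of noise
        ius1 = max(preop * (1.0 + spec.volume_bias_fraction + rng.normal(0, rel_noise)), 0.0)
        if residual:
            ius2_call = True
            ius2_vol = max(resid_vol * (1.0 + spec.volume_bias_fraction + rng.normal(0, rel_noise)), 0.0)
        else:
            ius2_call = bool(rng.random() < spec.artifact_probability)
            ius2_vol = spec.artifact_volume_cm3 if ius2_call else 0.0

        rows.append(
            {
                "id": f"S{i + 1:03d}",
                "sex": sex,
                "age_years": round(age, 1),
                "tumor_type": ttype,
                "tumor_location": tloc,
                "preop_volume_cm3": preop,
                "residual_on_imri": "y" if residual else "n",
                "residual_on_ius2": "y" if ius2_call else "n",
                "evaluable_ius": True,
                "evaluable_quantitative": True,
                "ius1_volume_cm3": ius1,
                "imri_residual_volume_cm3": resid_vol if residual else 0.0,
                "ius2_residual_volume_cm3": ius2_vol,
                "case_seed": cseed,
            }
        )
        if render:
            case_spec = replace(spec, seed=cseed)
            cases.append(generate_case(case_spec, seed=cseed, case_id=f"S{i + 1:03d}"))
    return pd.DataFrame(rows), cases
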