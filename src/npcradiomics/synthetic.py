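"""Synthetic cohort generator.

Builds the stand-in for a recurrent-NPC imaging study: textured ellipsoidal
"tumors" of two phenotype classes on a SPAIR-T2W-like anisotropic grid,
perturbed second-observer contours for reproducibility analysis, and radial
dose cases with a controllable fraction of the recurrence volume inside the
95% isodose.

The texture model is a stationary Gaussian random field: white noise
convolved with an isotropic Gaussian kernel whose physical correlation
length differs between the two classes (in-field-recurrence-like, IFR,
coarse texture vs non-progressing-disease-like, NPD, fine texture). This is
the simplest process with a single controllable heterogeneity scale and is
sufficient to exercise every downstream texture operator; it makes no claim
about NPC biology. Intensities live on an arbitrary positive scale because
downstream [m - 3s, m + 3s] normalization removes scale and offset.

Every case is a pure function of ``(spec.seed, class_label, index)`` via an
independent ``SeedSequence`` stream, so changing the cohort size never
reshuffles existing cases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ImageVolume, RoiMask

__all__ = [
    "IFR",
    "NPD",
    "CohortSpec",
    "DoseCaseSpec",
    "generate_tumor_case",
    "perturb_contour",
    "generate_dose_case",
    "build_cohort",
    "write_cohort",
]

IFR = "IFR"  # in-field recurrence phenotype
NPD = "NPD"  # non-progressing disease phenotype

_CLASS_CODE = {IFR: 1, NPD: 2}


@dataclass
class CohortSpec:
    """Conditions of the synthetic cohort.

    Defaults mirror the study conditions: 11 IFR vs 16 NPD cases on a
    0.65 x 0.65 x 4 mm acquisition grid. The two correlation lengths
    (4 mm vs 1 mm) give a coarsely vs finely textured phenotype pair;
    ``noise_sd`` adds uncorrelated acquisition-like noise a quarter the
    texture amplitude.
    """

    n_ifr: int = 11
    n_npd: int = 16
    grid_shape: tuple[int, int, int] = (48, 48, 12)
    spacing_mm: tuple[float, float, float] = (0.65, 0.65, 4.0)
    texture_scale_ifr: float = 4.0  # Gaussian correlation length, mm
    texture_scale_npd: float = 1.0
    intensity_offset: float = 300.0  # arbitrary SPAIR-T2W-like scale
    texture_amplitude: float = 60.0
    noise_sd: float = 15.0
    roi_radius_mm: tuple[float, float, float] = (9.0, 9.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.roi_radius_mm = tuple(float(r) for r in self.roi_radius_mm)
        if self.n_ifr < 0 or self.n_npd < 0:
            raise ValueError("class counts must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if any(r <= 0 for r in self.roi_radius_mm):
            raise ValueError("roi_radius_mm must be strictly positive")

    def texture_scale(self, class_label: str) -> float:
        return self.texture_scale_ifr if class_label == IFR else self.texture_scale_npd


@dataclass
class DoseCaseSpec:
    """Ground-truth-controlled dosimetric recurrence case."""

    prescription_gy: float = 70.0
    target_fraction_in: float = 1.0
    recur_radius_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction_in <= 1.0:
            raise ValueError("target_fraction_in must be in [0, 1]")
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be positive")


def _case_rng(seed: int, class_label: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, _CLASS_CODE[class_label], index))
    )


def _grf(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    scale_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-marginal-variance Gaussian random field with correlation length scale_mm.

    White noise is smoothed with a wrapped Gaussian kernel; the output is
    rescaled by the analytic post-smoothing standard deviation (sqrt of the
    kernel's sum of squares) rather than the empirical one, so the marginal
    variance is 1 by construction and the within-ROI variance of a single
    realization still vanishes in the kernel-width -> infinity limit.
    """
    white = rng.standard_normal(shape)
    sigma_vox = [scale_mm / s for s in spacing]
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(n // 2 for n in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    norm = float(np.sqrt((kernel**2).sum()))
    return smoothed / norm


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius_mm: tuple[float, float, float],
) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    a, b, c = radius_mm
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def generate_tumor_case(
    spec: CohortSpec, class_label: str, index: int
) -> tuple[ImageVolume, RoiMask]:
    """Generate one textured tumor volume and its ellipsoidal contour.

    Deterministic given ``(spec.seed, class_label, index)``.
    """
    if class_label not in _CLASS_CODE:
        raise ValueError(f"unknown class label {class_label!r}")
    n_class = spec.n_ifr if class_label == IFR else spec.n_npd
    if index < 0 or index >= n_class:
        raise ValueError(f"index {index} out of range for class {class_label} (n={n_class})")

    rng = _case_rng(spec.seed, class_label, index)
    field_ = _grf(spec.grid_shape, spec.spacing_mm, spec.texture_scale(class_label), rng)
    values = (
        spec.intensity_offset
        + spec.texture_amplitude * field_
        + spec.noise_sd * rng.standard_normal(spec.grid_shape)
    )

    mask_values = _ellipsoid_mask(spec.grid_shape, spec.spacing_mm, spec.roi_radius_mm)
    for axis in range(3):
        first = np.take(mask_values, 0, axis=axis)
        last = np.take(mask_values, -1, axis=axis)
        if first.any() or last.any():
            raise ValueError(
                f"ROI touches the grid boundary along axis {axis}; "
                "enlarge grid_shape or shrink roi_radius_mm"
            )

    vol = ImageVolume(values, spec.spacing_mm)
    mask = RoiMask(mask_values, spec.spacing_mm, label="GTV")
    return vol, mask


def perturb_contour(mask: RoiMask, magnitude_mm: float, seed: int) -> RoiMask:
    """Second-observer contour: smooth random radial boundary displacement.

    The boundary is moved along its normal by a smooth zero-mean random
    field clipped to ``magnitude_mm``: a voxel is kept when its signed
    Euclidean distance to the original boundary (positive inside) exceeds
    the local displacement. ``magnitude_mm = 0`` returns the identical
    mask. The largest 6-connected component is kept so observer masks stay
    single objects.
    """
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be non-negative")
    if magnitude_mm == 0:
        return mask.with_values(mask.values.copy(), label="observer2")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0A7)))
    spacing = mask.spacing_mm
    # signed distance to boundary, mm (positive inside the mask)
    inside = ndimage.distance_transform_edt(mask.values, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask.values, sampling=spacing)
    sdist = inside - outside

    sigma_vox = [4.0 / s for s in spacing]  # 4 mm displacement smoothness
    disp = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=sigma_vox)
    sd_field = float(disp.std())
    if sd_field == 0:
        return mask.with_values(mask.values.copy(), label="observer2")
    # typical displacement magnitude_mm / 2, hard-bounded at magnitude_mm
    disp = np.clip(disp / sd_field * (magnitude_mm / 2.0), -magnitude_mm, magnitude_mm)

    new_values = sdist > -disp
    if not new_values.any():
        raise ValueError("contour perturbation emptied the mask")
    labeled, n = ndimage.label(new_values, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
        new_values = labeled == (int(np.argmax(sizes)) + 1)
    return mask.with_values(new_values, label="observer2")


def generate_dose_case(spec: DoseCaseSpec, geometry: ImageVolume):
    """Radially decreasing dose grid hitting a target isodose coverage.

    The recurrence mask is a sphere of ``recur_radius_mm`` at the grid
    center; the dose falls off smoothly with distance from a point offset
    from the mask center, scaled so that the achieved fraction of mask
    voxels receiving >= 95% of the prescription matches
    ``target_fraction_in`` to within the voxel-count resolution (< 0.02 for
    the default geometry). Returns a :class:`~npcradiomics.dosimetry.RecurrenceCase`
    whose ``achieved_fraction_in`` is the stored ground truth.
    """
    from .dosimetry import RecurrenceCase  # local import avoids a cycle

    shape = geometry.shape
    spacing = geometry.spacing_mm
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*coords, indexing="ij")

    r_mask = np.sqrt(
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    )
    mask_values = r_mask <= spec.recur_radius_mm
    n_mask = int(mask_values.sum())
    if n_mask == 0:
        raise ValueError("recurrence sphere contains no voxels on this grid")
    if n_mask > 1 and 0 < spec.target_fraction_in < 1:
        resolution = 1.0 / n_mask
        if resolution > 0.04:
            raise ValueError(
                "recurrence sphere too small to hit the target fraction within 0.02"
            )

    # dose focus offset along axis 0 so mask voxels have distinct positive radii
    focus = [center[0] - spec.recur_radius_mm, center[1], center[2]]
    r = np.sqrt((x - focus[0]) ** 2 + (y - focus[1]) ** 2 + (z - focus[2]) ** 2)

    radii = np.sort(r[mask_values])
    # candidate isodose radii sit between distinct sorted radii (plus the two
    # extremes); pick the boundary whose voxel-count fraction is closest to
    # the target
    uniq, counts = np.unique(radii, return_counts=True)
    cum = np.cumsum(counts)
    cand_k = np.concatenate(([0], cum))
    best = int(np.argmin(np.abs(cand_k / n_mask - spec.target_fraction_in)))
    k = int(cand_k[best])
    if k <= 0:
        r95 = uniq[0] * 0.5
        if r95 <= 0:
            raise ValueError("cannot exclude a recurrence voxel at the dose focus")
    elif k >= n_mask:
        r95 = uniq[-1] + max(spacing)
    else:
        r95 = 0.5 * (uniq[best - 1] + uniq[best])

    # smooth monotone decrease; equals 0.95 * prescription exactly at r95
    dose = spec.prescription_gy * 1.05 * (0.95 / 1.05) ** ((r / r95) ** 2)
    achieved = float((dose[mask_values] >= 0.95 * spec.prescription_gy).sum() / n_mask)
    if abs(achieved - spec.target_fraction_in) > 0.02:
        raise ValueError(
            f"achieved fraction {achieved:.3f} misses target "
            f"{spec.target_fraction_in:.3f} by more than 0.02"
        )

    return RecurrenceCase(
        dose=ImageVolume(dose, spacing, geometry.origin_mm),
        prescription_gy=spec.prescription_gy,
        recur_mask=RoiMask(mask_values, spacing, geometry.origin_mm, label="V_recur"),
        achieved_fraction_in=achieved,
    )


def build_cohort(spec: CohortSpec):
    """All cases of the cohort as ``(case_id, class_label, volume, mask)``."""
    cases = []
    for label, n in ((IFR, spec.n_ifr), (NPD, spec.n_npd)):
        for i in range(n):
            vol, mask = generate_tumor_case(spec, label, i)
            cases.append((f"{label}_{i:03d}", label, vol, mask))
    return cases


def write_cohort(spec: CohortSpec, outdir: str | Path) -> pd.DataFrame:
    """Write the cohort as NIfTI pairs plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case_id, label, vol, mask in build_cohort(spec):
        vol.save(outdir / f"{case_id}_image.nii.gz")
        mask.save(outdir / f"{case_id}_mask.nii.gz")
        rows.append(
            {
                "case_id": case_id,
                "class_label": label,
                "seed": spec.seed,
                "texture_scale_mm": spec.texture_scale(label),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "cohort_manifest.csv", index=False)
    return manifest


def write_dose_case(spec: DoseCaseSpec, geometry: ImageVolume, outdir: str | Path) -> None:
    """Write a dose case as NIfTI dose + mask + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    case = generate_dose_case(spec, geometry)
    case.dose.save(outdir / "dose.nii.gz")
    case.recur_mask.save(outdir / "recur_mask.nii.gz")
    sidecar = {
        "prescription_gy": spec.prescription_gy,
        "target_fraction_in": spec.target_fraction_in,
        "achieved_fraction_in": case.achieved_fraction_in,
    }
    (outdir / "dose_case.json").write_text(json.dumps(sidecar, indent=2))
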