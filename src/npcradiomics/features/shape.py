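"""Morphological (shape and size) features of a binary ROI.

All lengths are physical (mm). Volume is voxel-counted; the surface is a
marching-cubes mesh, so sphericity of a digital ball comes out slightly
below 1. Principal axis lengths follow the 4*sqrt(eigenvalue) convention on
the physical-coordinate covariance of the mask voxels.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..grids import RoiMask

__all__ = ["SHAPE_KEYS", "shape_features"]

SHAPE_KEYS = (
    "shape_Volume",
    "shape_SurfaceArea",
    "shape_SVRatio",
    "shape_Sphericity",
    "shape_Max3DDiameter",
    "shape_Max2DDiameterSlice",
    "shape_Max2DDiameterColumn",
    "shape_Max2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def shape_features(mask: RoiMask) -> dict[str, float]:
    if mask.is_empty():
        raise ValueError("cannot compute shape features of an empty mask")
    spacing = np.asarray(mask.spacing_mm, dtype=np.float64)
    m = mask.values
    n = int(m.sum())
    volume = n * float(np.prod(spacing))

    # raw marching cubes on a 0/1 volume overestimates area by ~9% through
    # faceting; Taubin smoothing (volume-preserving, shrink-free) of the
    # mesh recovers the smooth surface to ~1% on digital balls
    padded = np.pad(m, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(mesh, iterations=10)
    surface = float(mesh.area)

    # sphericity <= 1 analytically; discretization noise may push it over
    sphericity = min(
        1.0, float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface)
    )

    # surface voxels only: interior points never realize the diameter
    eroded = ndimage.binary_erosion(m)
    boundary = m & ~eroded
    coords = np.argwhere(boundary if boundary.any() else m) * spacing
    max3d = _max_pairwise(coords)

    # max 2-D diameters in the planes orthogonal to each axis
    max2d = []
    idx = np.argwhere(m)
    for axis in range(3):
        inplane_axes = [a for a in range(3) if a != axis]
        best = 0.0
        for slice_idx in np.unique(idx[:, axis]):
            pts = idx[idx[:, axis] == slice_idx][:, inplane_axes] * spacing[inplane_axes]
            best = max(best, _max_pairwise(pts))
        max2d.append(best)

    phys = np.argwhere(m) * spacing
    if n < 2:
        warnings.warn("single-voxel mask: principal axes degenerate, reported as 0")
        eigvals = np.zeros(3)
    else:
        cov = np.cov(phys, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    if eigvals[0] > 0:
        elongation = float(np.sqrt(eigvals[1] / eigvals[0]))
        flatness = float(np.sqrt(eigvals[2] / eigvals[0]))
    else:
        warnings.warn("degenerate mask: elongation/flatness reported as 0")
        elongation = flatness = 0.0

    values = (
        volume,
        surface,
        surface / volume,
        sphericity,
        max3d,
        max2d[0],  # slice plane (orthogonal to axis 0)
        max2d[1],
        max2d[2],
        major,
        minor,
        least,
        elongation,
        flatness,
    )
    return dict(zip(SHAPE_KEYS, (float(v) for v in values)))
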