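"""3-D shape features of a binary tumor mask.

Volume is voxel counting.  Surface area uses a Crofton-style (integral
geometry) estimator: the exposed voxel-face area summed over the three axis
orientations, scaled by 2/3.  For isotropically oriented smooth surfaces
the axis-projected face area integrates to 3/2 of the true area, so the
2/3 factor makes the estimator asymptotically exact for digitized balls
(error well under 1 % at clinical voxel sizes), unlike a raw marching-cubes
mesh whose staircase overestimates curved surfaces by ~10 %.  A
single-voxel ROI reports its voxel-cuboid area.

The sphere-referenced descriptors follow the usual conventions:

    sphericity              = pi^(1/3) (6V)^(2/3) / A        (1 for a ball)
    compactness1            = V / (sqrt(pi) A^(3/2))
    compactness2            = 36 pi V^2 / A^3                (= sphericity^3)
    spherical disproportion = A / (4 pi r^2), r = (3V/4pi)^(1/3)

with V in mm^3 and A in mm^2; the reported volume feature is in mL.
Maximum 3-D diameter is the largest pairwise distance between ROI voxel
centers (computed on the convex hull for speed).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from ..errors import NoLesionError
from .roster import GEOMETRY_NAMES


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    if mask.sum() == 1:
        a, b, c = spacing
        return 2.0 * (a * b + b * c + c * a)
    face = {
        0: spacing[1] * spacing[2],
        1: spacing[0] * spacing[2],
        2: spacing[0] * spacing[1],
    }
    total = 0.0
    m = mask.astype(np.int8)
    for ax in range(3):
        crossings = np.abs(np.diff(m, axis=ax)).sum()
        border = np.take(mask, 0, axis=ax).sum() + np.take(mask, -1, axis=ax).sum()
        total += float(crossings + border) * face[ax]
    return (2.0 / 3.0) * total


def _max_diameter_mm(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # coplanar/collinear voxel sets
            pass
    return float(pdist(pts).max())


def geometry_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Compute the 8 shape features of a binary mask with voxel spacing in mm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoLesionError("geometry features require a non-empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_mm3 = float(np.prod(spacing))
    v_mm3 = float(mask.sum()) * voxel_mm3
    area = _surface_area_mm2(mask, spacing)
    coords = np.argwhere(mask) * np.asarray(spacing)
    r_eq = (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    out = {
        "volume_ml": v_mm3 / 1000.0,
        "surface_area_mm2": area,
        "surface_to_volume_ratio": area / v_mm3,
        "sphericity": np.pi ** (1.0 / 3.0) * (6.0 * v_mm3) ** (2.0 / 3.0) / area,
        "compactness1": v_mm3 / (np.sqrt(np.pi) * area**1.5),
        "compactness2": 36.0 * np.pi * v_mm3**2 / area**3,
        "spherical_disproportion": area / (4.0 * np.pi * r_eq**2),
        "max_3d_diameter_mm": _max_diameter_mm(coords),
    }
    assert tuple(out) == GEOMETRY_NAMES
    return out
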