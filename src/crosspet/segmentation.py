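"""Threshold-based tumor segmentation and conventional uptake features.

The ROI rule is the clinical standard for PET lesions: find the hottest
voxel (SUVmax), keep every voxel with SUV at or above a fraction of it
(50 % by default), and retain the 26-connected component containing that
seed so disconnected supra-threshold structures elsewhere in the volume are
excluded.  The "semi-automatic" part is an optional user-supplied search
region that restricts where the seed may lie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MaskConflictError, NoLesionError, ParameterError
from .pet_preprocess import SuvVolume

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TumorRoi:
    """Binary tumor mask plus the seed voxel and threshold that produced it."""

    mask: np.ndarray
    seed: tuple[int, int, int]
    threshold_fraction: float
    suv_max_used: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise NoLesionError("tumor mask is empty")
        if not self.mask[self.seed]:
            raise MaskConflictError("seed voxel is not inside the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConventionalFeatures:
    """T/N ratio and SUV max/median/min over the tumor ROI."""

    tn_ratio: float
    suv_max: float
    suv_median: float
    suv_min: float

    def as_dict(self) -> dict[str, float]:
        return {
            "conventional_tn_ratio": self.tn_ratio,
            "conventional_suv_max": self.suv_max,
            "conventional_suv_median": self.suv_median,
            "conventional_suv_min": self.suv_min,
        }


def segment_tumor(
    suv: SuvVolume,
    threshold_fraction: float = 0.5,
    search_region: np.ndarray | None = None,
    *,
    strict: bool = False,
    confine_to_region: bool = False,
) -> TumorRoi:
    """Delineate the tumor ROI at a fraction of SUVmax.

    Parameters
    ----------
    threshold_fraction
        Fraction of the seed's SUV below which voxels are excluded; the
        comparison is inclusive (``>=``) unless ``strict`` is set.  The
        inclusive rule avoids empty masks on plateau lesions.
    search_region
        Optional boolean mask restricting where the SUVmax seed is sought.
        By default the connected component may extend beyond it; set
        ``confine_to_region`` to intersect the ROI with the region.

    Ties at the maximum resolve to the lowest linear voxel index, which is
    deterministic across platforms.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ParameterError("threshold_fraction must be in (0, 1]")
    vox = suv.voxels
    if search_region is not None:
        search_region = np.asarray(search_region, dtype=bool)
        if search_region.shape != vox.shape:
            raise MaskConflictError("search_region shape does not match volume")
        if not search_region.any():
            raise MaskConflictError("search_region is empty")
        candidates = np.where(search_region, vox, -np.inf)
    else:
        candidates = vox
    flat_seed = int(np.argmax(candidates))
    seed = np.unravel_index(flat_seed, vox.shape)
    suv_max = float(vox[seed])
    if suv_max <= 0:
        raise NoLesionError("no positive uptake found to seed the segmentation")

    thr = threshold_fraction * suv_max
    supra = vox > thr if strict else vox >= thr
    if confine_to_region and search_region is not None:
        supra &= search_region
    labels, _ = ndimage.label(supra, structure=_STRUCT_26)
    mask = labels == labels[seed]
    return TumorRoi(
        mask=mask,
        seed=tuple(int(i) for i in seed),
        threshold_fraction=threshold_fraction,
        suv_max_used=suv_max,
    )


def conventional_features(
    suv: SuvVolume, tumor: TumorRoi, normal: np.ndarray
) -> ConventionalFeatures:
    """SUV max/median/min over the tumor and the tumor-to-normal mean ratio.

    The normal-tissue reference mask is caller-supplied: T/N ratios depend
    on the choice of normal tissue and no single reference is canonical.
    """
    normal = np.asarray(normal, dtype=bool)
    if normal.shape != tumor.mask.shape:
        raise MaskConflictError("normal mask shape does not match tumor mask")
    if not normal.any():
        raise MaskConflictError("normal mask is empty")
    if (tumor.mask & normal).any():
        raise MaskConflictError("tumor and normal masks overlap")
    tvals = suv.voxels[tumor.mask]
    nmean = float(suv.voxels[normal].mean())
    if nmean == 0:
        raise ZeroDivisionError("normal-tissue mean SUV is zero; T/N undefined")
    return ConventionalFeatures(
        tn_ratio=float(tvals.mean()) / nmean,
        suv_max=float(tvals.max()),
        suv_median=float(np.median(tvals)),
        suv_min=float(tvals.min()),
    )
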