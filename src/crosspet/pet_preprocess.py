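"""SUV computation and isotropic resampling of PET volumes.

A raw PET image stores an activity concentration (Bq/mL) per voxel.  For
quantitative comparison across patients and scan sessions the field works
with the standardized uptake value

    SUV(v) = C(v) * body_weight / dose_at_scan,

where ``dose_at_scan`` is the injected dose decay-corrected from injection
time to the scan reference time, ``dose * 2**(-dt / half_life)``.  With
weight in grams and dose in Bq this yields the common g/mL convention in
which a uniform distribution of the tracer over the whole body gives
SUV = 1.

Radiomic texture features are sensitive to voxel size, so volumes are
additionally resampled to an isotropic grid (1.5 mm by default) with
trilinear interpolation before feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ChronologyError, InvalidMetadataError, ResolutionError

#: Physical half-life of fluorine-18 in seconds.
F18_HALF_LIFE_S = 6586.2

TimeLike = datetime | float | int


def _seconds_between(later: TimeLike, earlier: TimeLike) -> float:
    """Elapsed seconds from `earlier` to `later`; accepts datetimes or numbers."""
    if isinstance(later, datetime) and isinstance(earlier, datetime):
        return (later - earlier).total_seconds()
    if isinstance(later, datetime) or isinstance(earlier, datetime):
        raise InvalidMetadataError(
            "scan_time and injection_time must both be datetimes or both numeric seconds"
        )
    return float(later) - float(earlier)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise InvalidMetadataError(f"spacing must be 3 positive reals, got {spacing!r}")
    return spacing


@dataclass
class ActivityVolume:
    """A 3-D activity-concentration image (Bq/mL) with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    scan_time: TimeLike = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidMetadataError("activity volume must be a rank-3 array")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidMetadataError("activity volume contains non-finite voxels")
        self.spacing = _check_spacing(self.spacing)


@dataclass
class AcquisitionMeta:
    """Injection metadata needed to convert activity to SUV.

    body_weight_g : patient body weight in grams.
    injected_dose_bq : injected activity at injection time, in Bq.
    injection_time : datetime or seconds; same convention as the scan time.
    half_life_s : isotope half-life in seconds (default fluorine-18).
    """

    body_weight_g: float
    injected_dose_bq: float
    injection_time: TimeLike = 0.0
    half_life_s: float = F18_HALF_LIFE_S

    def __post_init__(self):
        if self.body_weight_g <= 0:
            raise InvalidMetadataError("body_weight_g must be positive")
        if self.injected_dose_bq <= 0:
            raise InvalidMetadataError("injected_dose_bq must be positive")
        if self.half_life_s <= 0:
            raise InvalidMetadataError("half_life_s must be positive")


@dataclass
class SuvVolume:
    """A 3-D SUV image (dimensionless, g/mL convention)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "unknown"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidMetadataError("SUV volume must be a rank-3 array")
        self.spacing = _check_spacing(self.spacing)

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1


def compute_suv_map(
    act: ActivityVolume,
    meta: AcquisitionMeta,
    *,
    reference_time: TimeLike | None = None,
    modality: str = "unknown",
) -> SuvVolume:
    """Convert an activity volume to SUV, decay-correcting the dose.

    The injected dose is decayed from injection time to ``reference_time``
    (the scan start by default).  Exposing the reference time lets a second
    acquisition be corrected to the first scanner's time point when two
    sessions of the same injection are compared.
    """
    ref = act.scan_time if reference_time is None else reference_time
    dt = _seconds_between(ref, meta.injection_time)
    if dt < 0:
        raise ChronologyError(f"scan reference time precedes injection by {-dt:.1f} s")
    dose_at_scan = meta.injected_dose_bq * 2.0 ** (-dt / meta.half_life_s)
    suv = act.voxels * (meta.body_weight_g / dose_at_scan)
    return SuvVolume(voxels=suv, spacing=act.spacing, modality=modality)


def resample_isotropic(vol, target_spacing_mm: float = 1.5):
    """Resample a volume to an isotropic grid with trilinear interpolation.

    Returns the same type as the input (`SuvVolume` or `ActivityVolume`)
    with ``spacing = (t, t, t)``.  The endpoint-preserving grid convention
    of :func:`scipy.ndimage.zoom` is used, so a linear intensity ramp keeps
    its endpoint values exactly and a constant volume stays constant.  SUV
    outputs are clamped at zero because linear interpolation of noisy
    non-negative data cannot meaningfully go negative.
    """
    if target_spacing_mm <= 0:
        raise ResolutionError("target spacing must be positive")
    t = float(target_spacing_mm)
    if all(abs(s - t) < 1e-12 for s in vol.spacing):
        out = replace(vol)
        out.voxels = vol.voxels.copy()
        return out

    factors = [s / t for s in vol.spacing]
    new_shape = [int(round(n * f)) for n, f in zip(vol.voxels.shape, factors)]
    if any(n < 2 for n in new_shape):
        raise ResolutionError(
            f"resampling to {t} mm leaves shape {tuple(new_shape)}; need >= 2 voxels per axis"
        )
    exact = [n_out / n_in for n_out, n_in in zip(new_shape, vol.voxels.shape)]
    data = ndimage.zoom(vol.voxels, exact, order=1, mode="nearest", grid_mode=False)
    if isinstance(vol, SuvVolume):
        data = np.clip(data, 0.0, None)
        return SuvVolume(voxels=data, spacing=(t, t, t), modality=vol.modality)
    return ActivityVolume(
        voxels=data, spacing=(t, t, t), scan_time=vol.scan_time, meta=dict(vol.meta)
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, voxel spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise InvalidMetadataError(f"{path}: expected a 3-D volume, got rank {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_suv_nifti(path: str | Path, modality: str = "unknown") -> SuvVolume:
    data, spacing = read_nifti(path)
    return SuvVolume(voxels=data, spacing=spacing, modality=modality)


def write_nifti(path: str | Path, voxels: np.ndarray, spacing, sidecar: dict | None = None):
    """Write a volume as NIfTI with a diagonal affine; optional JSON sidecar."""
    spacing = _check_spacing(spacing)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), affine), str(path))
    if sidecar is not None:
        Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str)
        )


def write_suv_nifti(path: str | Path, suv: SuvVolume, provenance: dict | None = None):
    sidecar = {"modality": suv.modality, "spacing_mm": suv.spacing}
    if provenance:
        sidecar.update(provenance)
    write_nifti(path, suv.voxels, suv.spacing, sidecar=sidecar)
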