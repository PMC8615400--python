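"""Synthetic paired-device PET phantoms and paired feature tables.

Two generators make the whole pipeline testable without patient data:

* :func:`generate_phantom_pair` builds a 3-D SUV phantom — an ellipsoidal
  hot lesion with Gaussian-random-field intra-lesion texture on a
  low-uptake background — and a second "device B" rendition of it obtained
  by Gaussian smoothing, an affine gain/offset, and additive noise.  That
  transform is a minimal model of how CT-based and MR-based attenuation
  correction (and reconstruction smoothing) perturb the same underlying
  activity distribution; it is not a physical PET simulation.

* :func:`generate_feature_pairs` draws per-feature paired measurements
  (x_i, y_i = s*x_i + c + eps_i) with the noise SD back-solved so that the
  population r^2 hits a requested target, giving exact ground truth for
  regression/ICC recovery tests.

Default phantom conditions: 64^3 grid at 1.5 mm, lesion mean SUV 5 on a
background of 2 (a tumor-to-normal ratio of 2.5, the usual eligibility
level for boron neutron capture therapy), lesion semi-axes ~12x10x9 mm.
Cohort generation jitters lesion size, uptake and texture per subject so
that between-subject variance — which the ICC needs — is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SpecError
from .pet_preprocess import SuvVolume
from .comparability import PairedFeatureTable


@dataclass
class ModalityTransform:
    """Device-B rendering of a device-A volume: smooth, rescale, add noise."""

    gain: float = 1.03
    offset: float = 0.05  # SUV
    smoothing_mm: float = 0.5  # sigma of the Gaussian PSF mismatch
    noise_sd: float = 0.1  # white (voxel-independent) noise, SUV
    corr_noise_sd: float = 0.15  # spatially correlated reconstruction noise, SUV
    noise_corr_mm: float = 2.5  # correlation length of the correlated component

    def __post_init__(self):
        if self.gain <= 0:
            raise SpecError("gain must be positive")
        if min(self.smoothing_mm, self.noise_sd, self.corr_noise_sd, self.noise_corr_mm) < 0:
            raise SpecError("smoothing and noise parameters must be >= 0")


@dataclass
class PhantomSpec:
    """Parameters of one paired-phantom subject (all lengths in mm)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.5
    lesion_center_mm: tuple[float, float, float] | None = None  # None = grid center
    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 9.0)
    lesion_mean_suv: float = 5.0
    background_mean_suv: float = 2.0
    texture_corr_mm: float = 3.0  # GRF correlation length inside the lesion
    texture_sd_suv: float = 0.75
    uptake_gradient: float = 0.3  # radial profile: >0 hot core, <0 hot rim
    psf_mm: float = 1.2  # shared scanner resolution blur (Gaussian sigma)
    background_noise_sd: float = 0.05
    transform: ModalityTransform = field(default_factory=ModalityTransform)
    seed: int = 0  # mandatory for reproducibility; part of the spec

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes_mm) or self.spacing <= 0:
            raise SpecError("semi-axes and spacing must be positive")
        center = self.center_mm
        extent = tuple(n * self.spacing for n in self.shape)
        for c, a, e in zip(center, self.semi_axes_mm, extent):
            if c - a < 0 or c + a > e:
                raise SpecError(f"lesion (center {center}, semi-axes {self.semi_axes_mm}) exceeds grid extent {extent}")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.lesion_center_mm is not None:
            return self.lesion_center_mm
        return tuple(n * self.spacing / 2.0 for n in self.shape)


def _grf(shape, corr_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian random field with roughly the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_vox <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, corr_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_phantom_pair(
    spec: PhantomSpec,
) -> tuple[SuvVolume, SuvVolume, np.ndarray, np.ndarray]:
    """Build (device A volume, device B volume, lesion mask, normal mask).

    The normal-tissue reference mask is pure background at least ~6 mm away
    from the lesion surface and away from the grid border, mimicking a
    physician-drawn contralateral reference region.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.indices(spec.shape, dtype=float)
    center_vox = [c / spec.spacing for c in spec.center_mm]
    axes_vox = [a / spec.spacing for a in spec.semi_axes_mm]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center_vox, axes_vox))
    lesion = r2 <= 1.0
    if not lesion.any():
        raise SpecError("lesion resolves to zero voxels on this grid")

    a = np.full(spec.shape, spec.background_mean_suv, dtype=float)
    texture = _grf(spec.shape, spec.texture_corr_mm / spec.spacing, rng)
    # radial uptake profile: g > 0 concentrates uptake in the core, g < 0 in the rim
    g = spec.uptake_gradient
    profile = 1.0 + g * (0.5 - r2[lesion])  # zero-mean over the unit ball-ish radius
    a[lesion] = (
        spec.lesion_mean_suv * profile
        + spec.texture_sd_suv * texture[lesion]
    )
    # shared scanner resolution: both devices image the same blurred activity,
    # which also puts the half-maximum segmentation contour on a slope as in
    # real PET, so small device perturbations shift the ROI boundary
    if spec.psf_mm > 0:
        a = ndimage.gaussian_filter(a, spec.psf_mm / spec.spacing)
    a += spec.background_noise_sd * rng.standard_normal(spec.shape)
    a = np.clip(a, 0.0, None)

    tr = spec.transform
    if tr.smoothing_mm > 0:
        b = ndimage.gaussian_filter(a, tr.smoothing_mm / spec.spacing)
    else:
        b = a.copy()
    b = b * tr.gain + tr.offset
    if tr.noise_sd > 0:
        b = b + tr.noise_sd * rng.standard_normal(spec.shape)
    if tr.corr_noise_sd > 0:
        # reconstruction noise is spatially correlated; unlike white noise it
        # survives low-pass filtering, degrading all subbands alike
        b = b + tr.corr_noise_sd * _grf(spec.shape, tr.noise_corr_mm / spec.spacing, rng)
    b = np.clip(b, 0.0, None)

    # normal reference: background >= ~6 mm from the lesion, off the border
    margin_vox = max(1, int(round(6.0 / spec.spacing)))
    dilated = ndimage.binary_dilation(lesion, iterations=margin_vox)
    border = np.zeros(spec.shape, dtype=bool)
    edge = 4
    border[:edge], border[-edge:] = True, True
    border[:, :edge], border[:, -edge:] = True, True
    border[:, :, :edge], border[:, :, -edge:] = True, True
    normal = ~dilated & ~border

    sp = (spec.spacing,) * 3
    return (
        SuvVolume(voxels=a, spacing=sp, modality="synthetic-A"),
        SuvVolume(voxels=b, spacing=sp, modality="synthetic-B"),
        lesion,
        normal,
    )


def sample_cohort_specs(
    n_subjects: int, base: PhantomSpec | None = None, seed: int = 0
) -> list[PhantomSpec]:
    """Per-subject phantom specs with biological-looking heterogeneity.

    Lesion size (roughly 3x in linear scale), mean uptake, texture
    amplitude and grain, and the radial uptake profile (hot-core vs
    hot-rim) all vary across subjects, mimicking the large between-patient
    heterogeneity of real tumor cohorts that paired-device statistics (and
    in particular the ICC) rely on; each subject gets its own derived seed.
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        scale = rng.uniform(0.55, 1.5)
        # per-subject device calibration scatter: attenuation-correction bias
        # differs with each patient's anatomy, so the gain/offset between the
        # two devices is not a fixed instrument constant
        transform = replace(
            base.transform,
            gain=float(base.transform.gain * np.exp(rng.normal(0.0, 0.06))),
            offset=float(base.transform.offset + rng.normal(0.0, 0.12)),
        )
        specs.append(
            replace(
                base,
                semi_axes_mm=tuple(a * scale for a in base.semi_axes_mm),
                lesion_mean_suv=float(rng.uniform(3.5, 7.5)),
                texture_sd_suv=float(rng.uniform(0.3, 1.4)),
                texture_corr_mm=float(rng.uniform(1.5, 5.5)),
                uptake_gradient=float(rng.uniform(-0.4, 0.8)),
                transform=transform,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Paired feature tables with analytic ground truth


@dataclass
class FeaturePairSpec:
    """Ground-truth model of paired feature measurements.

    Each feature f has y = slope_f * x + intercept_f + eps, with eps chosen
    so the squared correlation between x and y equals ``target_r2``:
    sd(eps) = |slope| * sd(x) * sqrt(1/r2 - 1), using the realized sample SD
    of x.  x is log-normal (exp(N(mu, sigma))), a right-skewed positive
    distribution typical of radiomic feature scales.
    """

    n_subjects: int = 15  # the study-scale default
    feature_names: tuple[str, ...] = ()
    slopes: tuple[float, ...] = ()
    intercepts: tuple[float, ...] = ()
    target_r2: tuple[float, ...] = ()
    x_log_mu: float = 1.0
    x_log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        n = len(self.feature_names)
        if not n:
            raise SpecError("at least one feature required")
        if not (len(self.slopes) == len(self.intercepts) == len(self.target_r2) == n):
            raise SpecError("slopes/intercepts/target_r2 must align with feature_names")
        if self.n_subjects < 3:
            raise SpecError("n_subjects must be >= 3")
        for r in self.target_r2:
            if not (0.0 < r <= 1.0):
                raise SpecError(f"target r2 must be in (0, 1], got {r}")


def make_feature_pair_spec(
    n_features: int,
    n_subjects: int = 15,
    r2_levels=(0.95, 0.7, 0.3),
    *,
    seed: int = 0,
) -> FeaturePairSpec:
    """Random spec: slopes ~ U(0.5, 1.5), intercepts ~ U(-1, 1), r2 cycled."""
    rng = np.random.default_rng(seed)
    names = tuple(f"f{i:03d}" for i in range(n_features))
    return FeaturePairSpec(
        n_subjects=n_subjects,
        feature_names=names,
        slopes=tuple(float(s) for s in rng.uniform(0.5, 1.5, n_features)),
        intercepts=tuple(float(c) for c in rng.uniform(-1.0, 1.0, n_features)),
        target_r2=tuple(float(r2_levels[i % len(r2_levels)]) for i in range(n_features)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_feature_pairs(spec: FeaturePairSpec) -> tuple[PairedFeatureTable, pd.DataFrame]:
    """Draw the paired table; returns (table, truth frame with s, c, target r2)."""
    rng = np.random.default_rng(spec.seed)
    n, names = spec.n_subjects, list(spec.feature_names)
    xs, ys, rows = {}, {}, []
    for name, s, c, r2t in zip(names, spec.slopes, spec.intercepts, spec.target_r2):
        x = np.exp(rng.normal(spec.x_log_mu, spec.x_log_sigma, n))
        sd_sx = abs(s) * x.std()
        eps_sd = sd_sx * np.sqrt(1.0 / r2t - 1.0)
        y = s * x + c + (eps_sd * rng.standard_normal(n) if eps_sd > 0 else 0.0)
        xs[name], ys[name] = x, y
        rows.append({"feature": name, "slope": s, "intercept": c, "target_r2": r2t})
    subjects = [f"s{i:03d}" for i in range(n)]
    a = pd.DataFrame(xs, index=subjects)
    b = pd.DataFrame(ys, index=subjects)
    a.index.name = b.index.name = "subject"
    roster = pd.DataFrame(
        {"name": names, "family": "synthetic", "image_set": "n/a", "base_name": names}
    )
    return PairedFeatureTable(a=a, b=b, roster=roster), pd.DataFrame(rows)
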