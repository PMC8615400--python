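"""The fixed feature roster: names, families and image sets.

The panel comprises 4 conventional features, 8 geometric (shape) features,
and — for the original SUV image and each of the eight single-level wavelet
subbands (LLL..HHH) — 16 histogram, 22 GLCM and 11 GLRLM features:

    8 + 9 * (16 + 22 + 11) = 8 + 9 * 49 = 449 radiomic features,

453 entries in total.  The roster is versioned data: it is shipped as a
manifest CSV alongside the code and reconstructed programmatically here;
batch outputs carry the manifest version so tables from mismatched rosters
are never merged silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

MANIFEST_VERSION = "1"

IMAGE_SETS = ("original", "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
"""Order of image sets; subband letters read axis 0 (slowest-varying) first."""

CONVENTIONAL_NAMES = ("tn_ratio", "suv_max", "suv_median", "suv_min")

GEOMETRY_NAMES = (
    "volume_ml",
    "surface_area_mm2",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "max_3d_diameter_mm",
)

HISTOGRAM_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "mean_absolute_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "root_mean_square",
    "percentile_10",
    "percentile_90",
)

GLCM_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference_moment",
    "imc1",
    "imc2",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
    "mean",
)

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)


@dataclass(frozen=True)
class RosterEntry:
    name: str
    family: str  # conventional | geometry | histogram | glcm | glrlm
    image_set: str  # n/a for conventional/geometry, else original/LLL/../HHH
    base_name: str  # family-local short name, shared across image sets


def build_roster(include_conventional: bool = True) -> list[RosterEntry]:
    """Construct the ordered roster (453 entries, or 449 radiomic-only)."""
    entries: list[RosterEntry] = []
    if include_conventional:
        for n in CONVENTIONAL_NAMES:
            entries.append(RosterEntry(f"conventional_{n}", "conventional", "n/a", n))
    for n in GEOMETRY_NAMES:
        entries.append(RosterEntry(f"geometry_{n}", "geometry", "n/a", n))
    for image_set in IMAGE_SETS:
        for n in HISTOGRAM_NAMES:
            entries.append(RosterEntry(f"{image_set}_histogram_{n}", "histogram", image_set, n))
        for n in GLCM_NAMES:
            entries.append(RosterEntry(f"{image_set}_glcm_{n}", "glcm", image_set, n))
        for n in GLRLM_NAMES:
            entries.append(RosterEntry(f"{image_set}_glrlm_{n}", "glrlm", image_set, n))
    return entries


def roster_frame(include_conventional: bool = True) -> pd.DataFrame:
    """The roster as a DataFrame (name, family, image_set, base_name)."""
    return pd.DataFrame([e.__dict__ for e in build_roster(include_conventional)])


def load_manifest() -> pd.DataFrame:
    """Load the shipped manifest CSV (the versioned on-disk form of the roster)."""
    with resources.files("crosspet.data").joinpath(
        f"feature_manifest_v{MANIFEST_VERSION}.csv"
    ).open() as fh:
        return pd.read_csv(fh, keep_default_na=False)  # 'n/a' is a literal tag


def feature_names(include_conventional: bool = True) -> list[str]:
    return [e.name for e in build_roster(include_conventional)]
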