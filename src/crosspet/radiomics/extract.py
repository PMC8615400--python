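"""Full-panel feature extraction: 4 conventional + 449 radiomic features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..segmentation import TumorRoi, conventional_features
from ..pet_preprocess import SuvVolume
from .geometry import geometry_features
from .histogram import histogram_features
from .quantize import discretize
from .roster import IMAGE_SETS, MANIFEST_VERSION, feature_names
from .texture import glcm_features, glrlm_features
from .wavelet import wavelet_decompose


@dataclass
class ExtractionConfig:
    """Tunable parameters of the feature extraction.

    n_bins : gray levels for texture discretization and histogram entropy.
    wavelet : PyWavelets family for the subband decomposition.
    texture_aggregation : 'merged' (one matrix over 13 directions) or
        'average' (per-direction features averaged).
    """

    n_bins: int = 64
    wavelet: str = "coif1"
    texture_aggregation: str = "merged"


@dataclass
class FeatureVector:
    """One subject/modality row of the 453-entry panel."""

    values: dict[str, float]
    subject_id: str
    modality: str
    degenerate: set[str] = field(default_factory=set)
    manifest_version: str = MANIFEST_VERSION

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, name=self.subject_id)
        s.index.name = "feature"
        return s


def _bbox_crop(mask: np.ndarray, *arrays, margin: int = 1):
    """Crop arrays to the mask bounding box (+margin) to speed texture up."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return (mask[sl], *[a[sl] for a in arrays])


def extract_all(
    suv: SuvVolume,
    tumor: TumorRoi,
    normal: np.ndarray,
    config: ExtractionConfig | None = None,
    *,
    subject_id: str = "subject",
) -> FeatureVector:
    """Extract the full ordered panel from one SUV volume and its masks.

    Histogram and texture features are computed on the original SUV image
    and on each of the eight wavelet subbands; subband histogram statistics
    are taken on the raw (signed) coefficients.  Degenerate texture entries
    (single gray level in the ROI) are NaN and recorded in ``degenerate``
    rather than dropped, so the roster length is always 453.
    """
    config = config or ExtractionConfig()
    values: dict[str, float] = {}
    degenerate: set[str] = set()

    conv = conventional_features(suv, tumor, normal)
    values.update(conv.as_dict())
    values.update({f"geometry_{k}": v for k, v in geometry_features(tumor.mask, suv.spacing).items()})

    subbands = wavelet_decompose(suv.voxels, wavelet=config.wavelet)
    image_volumes = {"original": suv.voxels, **subbands}
    for image_set in IMAGE_SETS:
        vol = image_volumes[image_set]
        mask_c, vol_c = _bbox_crop(tumor.mask, vol)
        hist = histogram_features(vol_c[mask_c], n_bins=config.n_bins)
        q = discretize(vol_c, mask_c, n_bins=config.n_bins)
        glcm = glcm_features(q, aggregation=config.texture_aggregation)
        glrlm = glrlm_features(q, aggregation=config.texture_aggregation)
        for fam, feats in (("histogram", hist), ("glcm", glcm), ("glrlm", glrlm)):
            for k, v in feats.items():
                name = f"{image_set}_{fam}_{k}"
                values[name] = v
                if not np.isfinite(v):
                    degenerate.add(name)

    ordered = feature_names(include_conventional=True)
    assert list(values) == ordered and len(values) == 453
    return FeatureVector(
        values=values, subject_id=subject_id, modality=suv.modality, degenerate=degenerate
    )


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack FeatureVectors into a subjects x 453 table (one modality)."""
    if not vectors:
        raise ValueError("no feature vectors given")
    versions = {v.manifest_version for v in vectors}
    if len(versions) > 1:
        raise ValueError(f"refusing to merge tables from mixed manifests: {versions}")
    df = pd.DataFrame([v.values for v in vectors], index=[v.subject_id for v in vectors])
    df.index.name = "subject"
    return df
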