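"""End-to-end convenience wrappers: segment -> extract -> paired tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparability import PairedFeatureTable
from .pet_preprocess import SuvVolume
from .radiomics import ExtractionConfig, extract_all, feature_table
from .segmentation import segment_tumor
from .synthetic import PhantomSpec, generate_phantom_pair, sample_cohort_specs


def extract_subject(
    suv: SuvVolume,
    normal_mask: np.ndarray,
    *,
    subject_id: str = "subject",
    threshold_fraction: float = 0.5,
    config: ExtractionConfig | None = None,
    search_region: np.ndarray | None = None,
):
    """Segment the hottest lesion and extract the full 453-feature panel."""
    roi = segment_tumor(suv, threshold_fraction=threshold_fraction, search_region=search_region)
    normal = np.asarray(normal_mask, dtype=bool) & ~roi.mask  # keep masks disjoint
    return extract_all(suv, roi, normal, config, subject_id=subject_id)


def paired_tables_from_specs(
    specs: list[PhantomSpec],
    *,
    threshold_fraction: float = 0.5,
    config: ExtractionConfig | None = None,
) -> PairedFeatureTable:
    """Generate each subject's phantom pair and extract both devices' panels."""
    vecs_a, vecs_b = [], []
    for i, spec in enumerate(specs):
        vol_a, vol_b, _, normal = generate_phantom_pair(spec)
        sid = f"s{i:03d}"
        vecs_a.append(
            extract_subject(
                vol_a, normal, subject_id=sid,
                threshold_fraction=threshold_fraction, config=config,
            )
        )
        vecs_b.append(
            extract_subject(
                vol_b, normal, subject_id=sid,
                threshold_fraction=threshold_fraction, config=config,
            )
        )
    return PairedFeatureTable(a=feature_table(vecs_a), b=feature_table(vecs_b))


def paired_tables_from_cohort(
    n_subjects: int = 15,
    base_spec: PhantomSpec | None = None,
    *,
    seed: int = 0,
    threshold_fraction: float = 0.5,
    config: ExtractionConfig | None = None,
) -> PairedFeatureTable:
    """Simulate a cohort of paired phantoms and build the paired table."""
    specs = sample_cohort_specs(n_subjects, base_spec, seed=seed)
    return paired_tables_from_specs(
        specs, threshold_fraction=threshold_fraction, config=config
    )


def load_feature_csv(path) -> pd.DataFrame:
    """Read a subjects x features CSV written by the CLI or feature_table."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = "subject"
    return df
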