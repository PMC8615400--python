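"""Gray-level discretization of ROI intensities for texture matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import NoLesionError, ParameterError


@dataclass
class QuantizedRoi:
    """ROI voxels binned to integer gray levels 1..n_bins.

    ``levels`` is a full-grid integer array, 0 outside the ROI so spatial
    structure is preserved for co-occurrence and run-length accumulation.
    A constant ROI cannot support texture: it maps to level 1 everywhere
    with ``degenerate`` set.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    degenerate: bool

    @property
    def n_levels_present(self) -> int:
        return int(np.unique(self.levels[self.mask]).size)


def discretize(values_volume: np.ndarray, mask: np.ndarray, n_bins: int = 64) -> QuantizedRoi:
    """Equal-width binning of ROI intensities into ``n_bins`` gray levels.

    Bins span [min, max] of the intensities inside the ROI; the maximum maps
    to level ``n_bins`` (not a one-voxel overflow bin).
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoLesionError("cannot discretize an empty ROI")
    vals = np.asarray(values_volume, dtype=float)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return QuantizedRoi(levels, mask, n_bins, edges, degenerate=True)
    lvl = np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(lvl, 1, n_bins, out=lvl)
    levels[mask] = lvl
    return QuantizedRoi(levels, mask, n_bins, edges, degenerate=False)
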