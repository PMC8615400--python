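"""First-order (histogram) intensity statistics within an ROI.

Sixteen statistics of the raw intensity values: moments and order
statistics are computed on the values themselves; entropy and uniformity
are computed on an equal-width histogram (64 bins by default, matching the
texture discretization).  Variance and standard deviation are population
(ddof=0) quantities; kurtosis is excess kurtosis (0 for a Gaussian).
Skewness and kurtosis of a constant ROI are undefined and returned as NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..errors import NoLesionError
from .roster import HISTOGRAM_NAMES


def histogram_features(values: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """Compute the 16 first-order features of a 1-D array of ROI intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise NoLesionError("histogram features require a non-empty ROI")
    lo, hi = float(x.min()), float(x.max())
    var = float(np.var(x))
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = counts / counts.sum()
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        uniformity = float((p**2).sum())
        skewness = float(stats.skew(x))
        kurtosis = float(stats.kurtosis(x))  # excess
    else:
        entropy, uniformity = 0.0, 1.0
        skewness = kurtosis = float("nan")
    out = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "minimum": lo,
        "maximum": hi,
        "range": hi - lo,
        "variance": var,
        "standard_deviation": float(np.sqrt(var)),
        "mean_absolute_deviation": float(np.abs(x - x.mean()).mean()),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "percentile_10": float(np.percentile(x, 10)),
        "percentile_90": float(np.percentile(x, 90)),
    }
    assert tuple(out) == HISTOGRAM_NAMES
    return out
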