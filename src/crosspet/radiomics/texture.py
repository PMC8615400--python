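"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Both matrices are accumulated in 3-D over the 13 unique voxel directions at
distance 1.  The default is a single merged matrix (all direction counts
pooled before normalization); per-direction computation with feature
averaging is available behind ``aggregation="average"``.  The GLCM is
symmetric (each pair counted in both orders).  Voxels outside the ROI never
contribute and break runs.

All entropies use log base 2 with 0*log(0) = 0.  A degenerate quantization
(a single gray level in the ROI) cannot support texture; every feature is
returned as NaN and the caller flags the entries rather than dropping them.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedRoi
from .roster import GLCM_NAMES, GLRLM_NAMES

def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    # one representative per +/- pair: keep the vector whose first non-zero is +1
    dirs = []
    for d0 in (-1, 0, 1):
        for d1 in (-1, 0, 1):
            for d2 in (-1, 0, 1):
                d = (d0, d1, d2)
                nz = next((x for x in d if x != 0), 0)
                if nz > 0:
                    dirs.append(d)
    return tuple(dirs)


#: The 13 unique 3-D directions at distance 1 (antipodes merged).
DIRECTIONS_13 = _unique_directions()
assert len(DIRECTIONS_13) == 13


def _shift_slices(shape, d):
    """Slice pair (src, dst) such that arr[src] and arr[dst] are offset by d."""
    src, dst = [], []
    for n, di in zip(shape, d):
        if di == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif di > 0:
            src.append(slice(0, n - di))
            dst.append(slice(di, n))
        else:
            src.append(slice(-di, n))
            dst.append(slice(0, n + di))
    return tuple(src), tuple(dst)


def glcm_matrix(q: QuantizedRoi, directions=DIRECTIONS_13) -> np.ndarray:
    """Symmetric co-occurrence count matrix pooled over ``directions``."""
    ng = q.n_bins
    counts = np.zeros((ng, ng), dtype=np.int64)
    lv = q.levels
    for d in directions:
        src, dst = _shift_slices(lv.shape, d)
        a = lv[src].ravel()
        b = lv[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok] - 1) * ng + (b[ok] - 1)
        flat = np.bincount(idx, minlength=ng * ng)
        counts += flat.reshape(ng, ng)
    return counts + counts.T  # symmetric: both orders


def _glcm_features_from_p(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    def ent(v):
        nz = v[v > 0]
        return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0

    # sum (k = i+j in 2..2Ng) and difference (k = |i-j| in 0..Ng-1) distributions
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    kd = np.arange(ng, dtype=float)

    sum_avg = float((ks * p_sum).sum())
    diff_avg = float((kd * p_diff).sum())
    hxy = ent(p.ravel())
    outer = np.outer(px, px)
    valid = (p > 0) & (outer > 0)
    hxy1 = float(-(p[valid] * np.log2(outer[valid])).sum())
    hxy2 = ent(outer.ravel())
    hx = ent(px)  # symmetric matrix: HX == HY, so max(HX, HY) == HX
    imc1 = (hxy - hxy1) / hx if hx > 0 else float("nan")
    imc2 = float(np.sqrt(max(0.0, 1.0 - 4.0 ** (-(hxy2 - hxy)))))

    off = ii != jj
    out = {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": (float((ii * jj * p).sum()) - mu * mu) / sigma2
        if sigma2 > 0
        else float("nan"),
        "difference_entropy": ent(p_diff),
        "difference_variance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "dissimilarity": diff_avg,
        "energy": float((p**2).sum()),
        "entropy": hxy,
        "homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float((p[off] / (ii - jj)[off].astype(float) ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": ent(p_sum),
        "sum_variance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "variance": sigma2,
        "mean": mu,
    }
    assert tuple(out) == GLCM_NAMES
    return out


def glcm_features(q: QuantizedRoi, aggregation: str = "merged") -> dict[str, float]:
    """The 22 GLCM features; NaN-valued if the quantization is degenerate."""
    if q.degenerate or q.n_levels_present < 2:
        return {n: float("nan") for n in GLCM_NAMES}
    if aggregation == "merged":
        counts = glcm_matrix(q)
        return _glcm_features_from_p(counts / counts.sum())
    if aggregation == "average":
        per_dir = []
        for d in DIRECTIONS_13:
            counts = glcm_matrix(q, directions=(d,))
            if counts.sum() == 0:
                continue
            per_dir.append(_glcm_features_from_p(counts / counts.sum()))
        return {n: float(np.nanmean([f[n] for f in per_dir])) for n in GLCM_NAMES}
    raise ValueError(f"unknown aggregation {aggregation!r}")


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_runs(q: QuantizedRoi, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-count matrix R[level-1, length-1] pooled over ``directions``.

    A run is a maximal sequence of collinear ROI voxels sharing one gray
    level; out-of-ROI voxels terminate runs.
    """
    lv = q.levels
    shape = lv.shape
    max_len = int(np.ceil(np.sqrt(sum(n**2 for n in shape)))) + 1
    rmat = np.zeros((q.n_bins, max_len), dtype=np.int64)
    for d in directions:
        src, dst = _shift_slices(shape, d)
        same = np.zeros(shape, dtype=bool)  # same[v]: successor v+d has same level
        same[src] = (lv[src] == lv[dst]) & (lv[src] > 0)
        prev_same = np.zeros(shape, dtype=bool)  # predecessor v-d has same level
        prev_same[dst] = same[src]
        starts = np.argwhere((lv > 0) & ~prev_same)
        for v in starts:
            v0, v1, v2 = int(v[0]), int(v[1]), int(v[2])
            length = 1
            while same[v0, v1, v2]:
                v0 += d[0]
                v1 += d[1]
                v2 += d[2]
                length += 1
            rmat[lv[v[0], v[1], v[2]] - 1, length - 1] += 1
    return rmat


def _glrlm_features_from_r(rmat: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    nr = float(rmat.sum())
    i = np.arange(1, rmat.shape[0] + 1, dtype=float)
    j = np.arange(1, rmat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    r = rmat.astype(float)
    out = {
        "short_run_emphasis": (r / jj**2).sum() / nr,
        "long_run_emphasis": (r * jj**2).sum() / nr,
        "gray_level_nonuniformity": (r.sum(axis=1) ** 2).sum() / nr,
        "run_length_nonuniformity": (r.sum(axis=0) ** 2).sum() / nr,
        "run_percentage": nr / (n_voxels * n_directions),
        "low_gray_level_run_emphasis": (r / ii**2).sum() / nr,
        "high_gray_level_run_emphasis": (r * ii**2).sum() / nr,
        "short_run_low_gray_level_emphasis": (r / (ii**2 * jj**2)).sum() / nr,
        "short_run_high_gray_level_emphasis": (r * ii**2 / jj**2).sum() / nr,
        "long_run_low_gray_level_emphasis": (r * jj**2 / ii**2).sum() / nr,
        "long_run_high_gray_level_emphasis": (r * ii**2 * jj**2).sum() / nr,
    }
    out = {k: float(v) for k, v in out.items()}
    assert tuple(out) == GLRLM_NAMES
    return out


def glrlm_features(q: QuantizedRoi, aggregation: str = "merged") -> dict[str, float]:
    """The 11 classic GLRLM features; NaN-valued on degenerate quantization.

    Run percentage is runs per (voxel, direction): each ROI voxel starts or
    extends exactly one run per direction, so the merged normalizer is
    ``n_voxels * 13``.
    """
    if q.degenerate or q.n_levels_present < 2:
        return {n: float("nan") for n in GLRLM_NAMES}
    n_vox = int(q.mask.sum())
    if aggregation == "merged":
        return _glrlm_features_from_r(glrlm_runs(q), n_vox, len(DIRECTIONS_13))
    if aggregation == "average":
        per_dir = [
            _glrlm_features_from_r(glrlm_runs(q, directions=(d,)), n_vox, 1)
            for d in DIRECTIONS_13
        ]
        return {n: float(np.mean([f[n] for f in per_dir])) for n in GLRLM_NAMES}
    raise ValueError(f"unknown aggregation {aggregation!r}")
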