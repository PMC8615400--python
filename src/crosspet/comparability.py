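"""Paired-device feature statistics: regression, ICC, tiers, interchange.

For every feature measured on the same subjects by two hybrid PET devices
(x = device A, conventionally the PET/CT role; y = device B, the PET/MR
role) the module fits an ordinary least-squares line y = slope*x +
intercept, computes r^2 (the squared Pearson correlation, identical to the
regression coefficient of determination for simple OLS) and the intraclass
correlation ICC(3,1) from the two-way subjects-by-device ANOVA, and assigns
a three-tier comparability level:

    strong   : r^2 > 0.85 and ICC > 0.75
    moderate : r^2 > 0.50 and ICC > 0.50   (and not strong)
    weak     : otherwise

Inequalities are strict.  Features in the strong and moderate tiers are
exported with their linear interchange equation y = slope*x + intercept and
its algebraic inverse.  Whether high-pass wavelet subbands degrade
agreement is assessed with paired t-tests of the 49 per-feature metrics of
each subband against the unfiltered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .radiomics.roster import IMAGE_SETS, MANIFEST_VERSION, roster_frame

SUBBANDS = [s for s in IMAGE_SETS if s != "original"]


@dataclass
class ClassificationThresholds:
    """Cut-offs of the three-tier rule (strict '>' comparisons)."""

    strong_r2: float = 0.85
    strong_icc: float = 0.75
    moderate_r2: float = 0.50
    moderate_icc: float = 0.50

    def __post_init__(self):
        if self.strong_r2 < self.moderate_r2 or self.strong_icc < self.moderate_icc:
            raise DegenerateDataError("strong thresholds must dominate moderate ones")


@dataclass
class PairedFeatureTable:
    """Per-feature paired measurements from two devices on the same subjects."""

    a: pd.DataFrame  # subjects x features, device A (x)
    b: pd.DataFrame  # subjects x features, device B (y)
    roster: pd.DataFrame | None = None  # name/family/image_set metadata
    manifest_version: str = MANIFEST_VERSION

    def __post_init__(self):
        if set(self.a.index) != set(self.b.index):
            missing = set(self.a.index) ^ set(self.b.index)
            raise DegenerateDataError(f"subject sets differ between devices: {sorted(missing)}")
        if list(self.a.columns) != list(self.b.columns):
            raise DegenerateDataError("feature columns differ between devices")
        self.b = self.b.loc[self.a.index]
        if self.roster is None:
            ros = roster_frame(include_conventional=True)
            self.roster = ros[ros["name"].isin(self.a.columns)].reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.a)

    @property
    def feature_names(self) -> list[str]:
        return list(self.a.columns)


@dataclass
class ComparabilityResult:
    feature: str
    family: str
    image_set: str
    slope: float
    intercept: float
    r2: float
    icc: float
    level: str  # strong | moderate | weak | not_assessable
    n_used: int
    max_cooks_distance: float = float("nan")


def fit_linear(x, y) -> tuple[float, float, float]:
    """OLS fit y = slope*x + intercept; returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("regression requires n >= 3 pairs")
    if np.ptp(x) == 0:
        raise DegenerateDataError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def icc_two_way_mixed_single(x, y, *, form: str = "consistency") -> float:
    """ICC from the two-way mixed model, single measurement, k = 2 raters.

    The consistency form is ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E);
    ``form='agreement'`` gives the absolute-agreement variant, which also
    charges the device main effect (column mean square) to disagreement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise DegenerateDataError("ICC requires n >= 3 aligned pairs")
    k = 2
    data = np.column_stack([x, y])
    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_tot = ((data - gm) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0 and mse == 0:
        raise DegenerateDataError("no variance at all; ICC undefined")
    if form == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise DegenerateDataError("zero denominator in ICC(3,1)")
        return float((msr - mse) / denom)
    if form == "agreement":
        msc = ss_cols / (k - 1)
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise DegenerateDataError("zero denominator in ICC(A,1)")
        return float((msr - mse) / denom)
    raise ValueError(f"unknown ICC form {form!r}")


def classify_comparability(
    r2: float, icc: float, thresholds: ClassificationThresholds | None = None
) -> str:
    """Three-tier rule with strict inequalities; non-finite inputs are weak."""
    t = thresholds or ClassificationThresholds()
    if not (np.isfinite(r2) and np.isfinite(icc)):
        return "weak"
    if r2 > t.strong_r2 and icc > t.strong_icc:
        return "strong"
    if r2 > t.moderate_r2 and icc > t.moderate_icc:
        return "moderate"
    return "weak"


def _max_cooks_distance(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    """Largest Cook's distance of the simple regression (leverage-point flag)."""
    n = x.size
    resid = y - (slope * x + intercept)
    mse = (resid**2).sum() / max(n - 2, 1)
    if mse == 0:
        return 0.0
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    d = resid**2 / (2 * mse) * h / (1 - h) ** 2
    return float(d.max())


def compare_modalities(
    table: PairedFeatureTable,
    thresholds: ClassificationThresholds | None = None,
    *,
    icc_form: str = "consistency",
) -> tuple[list[ComparabilityResult], dict]:
    """Per-feature paired statistics plus a per-family / per-subband summary.

    Degenerate features (NaN values, constant x, fewer than 3 complete
    pairs) are reported as ``not_assessable`` and never abort the run.
    """
    thresholds = thresholds or ClassificationThresholds()
    meta = table.roster.set_index("name") if table.roster is not None else None
    results: list[ComparabilityResult] = []
    for name in table.feature_names:
        x = table.a[name].to_numpy(dtype=float)
        y = table.b[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)  # pairwise deletion
        x, y = x[ok], y[ok]
        family, image_set = "unknown", "unknown"
        if meta is not None and name in meta.index:
            family = str(meta.loc[name, "family"])
            image_set = str(meta.loc[name, "image_set"])
        try:
            slope, intercept, r2 = fit_linear(x, y)
            icc = icc_two_way_mixed_single(x, y, form=icc_form)
            level = classify_comparability(r2, icc, thresholds)
            cooks = _max_cooks_distance(x, y, slope, intercept)
        except DegenerateDataError:
            results.append(
                ComparabilityResult(
                    name, family, image_set, float("nan"), float("nan"), float("nan"),
                    float("nan"), "not_assessable", int(ok.sum()),
                )
            )
            continue
        results.append(
            ComparabilityResult(
                name, family, image_set, slope, intercept, r2, icc, level,
                int(ok.sum()), cooks,
            )
        )
    return results, summarize(results)


def results_frame(results: list[ComparabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarize(results: list[ComparabilityResult]) -> dict:
    """Level counts/percentages and metric medians per family and image set."""
    df = results_frame(results)
    out: dict = {"n_features": len(df), "icc_form": None, "by_family": {}, "by_image_set": {}}

    def _group(sub: pd.DataFrame) -> dict:
        assessable = sub[sub["level"] != "not_assessable"]
        n = len(assessable)
        levels = {
            lvl: int((assessable["level"] == lvl).sum()) for lvl in ("strong", "moderate", "weak")
        }
        pct = {f"pct_{k}": (100.0 * v / n if n else float("nan")) for k, v in levels.items()}
        return {
            "n": int(len(sub)),
            "n_assessable": n,
            "n_not_assessable": int(len(sub) - n),
            **levels,
            **pct,
            "median_r2": float(assessable["r2"].median()) if n else float("nan"),
            "median_icc": float(assessable["icc"].median()) if n else float("nan"),
        }

    out["overall"] = _group(df)
    radiomic = df[df["family"] != "conventional"]
    out["radiomic"] = _group(radiomic)
    for fam, sub in df.groupby("family"):
        out["by_family"][fam] = _group(sub)
    for image_set in IMAGE_SETS:
        sub = df[df["image_set"] == image_set]
        if len(sub):
            out["by_image_set"][image_set] = _group(sub)
    return out


def paired_metric_test(metrics_a, metrics_b) -> tuple[float, float]:
    """Two-sided paired t-test between two aligned metric vectors.

    Pairs with a NaN in either vector are dropped.  Identical vectors give
    (t=0, p=1) by convention (zero differences carry no evidence).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateDataError("metric vectors must be aligned")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise DegenerateDataError("paired test requires >= 3 complete pairs")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def subband_vs_original_tests(
    results: list[ComparabilityResult], metric: str = "r2"
) -> pd.DataFrame:
    """Paired t-test of each subband's 49 per-feature metrics vs the original.

    Features are paired by their family-local definition (e.g. the GLCM
    contrast of LLL against the GLCM contrast of the unfiltered image).
    """
    df = results_frame(results)
    df = df[df["family"].isin(["histogram", "glcm", "glrlm"])].copy()
    df["base"] = [f.split("_", 1)[1] for f in df["feature"]]
    pivot = df.pivot(index="base", columns="image_set", values=metric)
    rows = []
    for sb in SUBBANDS:
        t, p = paired_metric_test(pivot[sb].to_numpy(), pivot["original"].to_numpy())
        rows.append(
            {
                "image_set": sb,
                "metric": metric,
                "t": t,
                "p": p,
                "median_subband": float(pivot[sb].median()),
                "median_original": float(pivot["original"].median()),
            }
        )
    return pd.DataFrame(rows)


def export_interchange(results: list[ComparabilityResult]) -> pd.DataFrame:
    """Interchange-equation table for strong + moderate features.

    ``slope``/``intercept`` map device A to device B (y = s*x + c); the
    inverse mapping x = (y - c)/s is reported algebraically, not refit.
    """
    rows = []
    for r in results:
        if r.level not in ("strong", "moderate"):
            continue
        rows.append(
            {
                "feature": r.feature,
                "family": r.family,
                "image_set": r.image_set,
                "level": r.level,
                "slope": r.slope,
                "intercept": r.intercept,
                "r2": r.r2,
                "icc": r.icc,
                "inverse_slope": 1.0 / r.slope if r.slope != 0 else float("nan"),
                "inverse_intercept": -r.intercept / r.slope if r.slope != 0 else float("nan"),
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "family", "image_set", "level", "slope", "intercept",
            "r2", "icc", "inverse_slope", "inverse_intercept", "n_used",
        ],
    )


@dataclass
class ComparisonReport:
    """Bundle of everything `compare` computes, for CLI serialization."""

    results: list[ComparabilityResult]
    summary: dict
    subband_tests_r2: pd.DataFrame
    subband_tests_icc: pd.DataFrame
    interchange: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_comparison(
    table: PairedFeatureTable,
    thresholds: ClassificationThresholds | None = None,
    *,
    icc_form: str = "consistency",
) -> ComparisonReport:
    results, summary = compare_modalities(table, thresholds, icc_form=icc_form)
    summary["icc_form"] = icc_form
    has_subbands = any(r.image_set in SUBBANDS for r in results) and any(
        r.image_set == "original" for r in results
    )
    empty = pd.DataFrame()
    return ComparisonReport(
        results=results,
        summary=summary,
        subband_tests_r2=subband_vs_original_tests(results, "r2") if has_subbands else empty,
        subband_tests_icc=subband_vs_original_tests(results, "icc") if has_subbands else empty,
        interchange=export_interchange(results),
    )
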