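"""Evaluation statistics: segmentation overlap, keypoint PCK, rater
reliability, and model-vs-reference agreement.

All keypoint distances are physical (mm): pixel offsets are scaled by the
pixel spacing before thresholding, so PCK thresholds are comparable across
images with different spacings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedStatisticError
from .geometry import KeyPointSet, Point2D

PCK_DEFAULT_THRESHOLDS = (1.0, 2.0, 3.0, 4.0, 5.0)


# ---------------------------------------------------------------------------
# Segmentation overlap
# ---------------------------------------------------------------------------

def dice_coefficient(pred: np.ndarray, ref: np.ndarray, klass: int) -> float:
    """2|A n B| / (|A| + |B|) for one class; 1.0 when both sets are empty."""
    if pred.shape != ref.shape:
        raise DataError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    a, b = pred == klass, ref == klass
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def pixel_accuracy(pred: np.ndarray, ref: np.ndarray, klass: int) -> float:
    """(TP + TN) / total for the one-vs-rest binarisation of one class."""
    if pred.shape != ref.shape:
        raise DataError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    a, b = pred == klass, ref == klass
    return float((a == b).mean())


# ---------------------------------------------------------------------------
# Keypoint distances / PCK
# ---------------------------------------------------------------------------

def _distance_mm(p: Point2D, q: Point2D, spacing: tuple[float, float]) -> float:
    row_mm, col_mm = spacing
    return math.hypot((p.x - q.x) * col_mm, (p.y - q.y) * row_mm)


def _paired_distances(pred: KeyPointSet, ref: KeyPointSet) -> dict[str, float]:
    if ref.pixel_spacing is None:
        raise DataError("pixel spacing required for mm-based keypoint metrics")
    names = set(pred.points) & set(ref.points)
    if not names:
        raise DataError("no common landmark names between prediction and reference")
    return {
        name: _distance_mm(pred[name], ref[name], ref.pixel_spacing)
        for name in names
    }


def pck(pred_sets: list[KeyPointSet], ref_sets: list[KeyPointSet],
        thresholds_mm: tuple[float, ...] = PCK_DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Percentage of predicted landmarks within r mm of the reference.

    Returns a table with one row per threshold and one column per landmark
    name (plus an ``all`` column pooled over landmarks); values in percent.
    """
    if len(pred_sets) != len(ref_sets):
        raise DataError("prediction and reference lists differ in length")
    per_name: dict[str, list[float]] = {}
    for pred, ref in zip(pred_sets, ref_sets):
        for name, d in _paired_distances(pred, ref).items():
            per_name.setdefault(name, []).append(d)
    names = sorted(per_name)
    rows = []
    for thr in thresholds_mm:
        row = {
            name: 100.0 * np.mean(np.asarray(per_name[name]) <= thr)
            for name in names
        }
        pooled = np.concatenate([per_name[name] for name in names])
        row["all"] = 100.0 * float(np.mean(pooled <= thr))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(thresholds_mm, name="threshold_mm"))


def observer_reliability(
    rater_sets: dict[str, dict[str, KeyPointSet]],
    thresholds_mm: tuple[float, ...] = PCK_DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Pairwise pooled agreement percentages between annotation sessions.

    ``rater_sets`` maps a session/rater name to {image id -> KeyPointSet}.
    Each unordered pair of sessions yields one row of percentages (pooled
    over images and landmarks).  Intra-observer reliability is the same
    computation applied to two sessions of one rater.
    """
    raters = sorted(rater_sets)
    if len(raters) < 2:
        raise DataError("need at least two annotation sessions")
    ids = {r: set(rater_sets[r]) for r in raters}
    common = set.intersection(*ids.values())
    if not common or any(ids[r] != common for r in raters):
        raise DataError("annotation sessions cover different image sets")
    rows = {}
    for i, r1 in enumerate(raters):
        for r2 in raters[i + 1 :]:
            dists = []
            for image_id in sorted(common):
                dists.extend(
                    _paired_distances(
                        rater_sets[r1][image_id], rater_sets[r2][image_id]
                    ).values()
                )
            d = np.asarray(dists)
            rows[f"{r1} vs. {r2}"] = [
                100.0 * float(np.mean(d <= thr)) for thr in thresholds_mm
            ]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=pd.Index(thresholds_mm, name="threshold_mm"),
    )


def reference_standard(annotation_sets: list[KeyPointSet]) -> KeyPointSet:
    """Coordinate-wise arithmetic mean of matched annotation sets."""
    if not annotation_sets:
        raise DataError("no annotation sets given")
    names = set(annotation_sets[0].points)
    for kps in annotation_sets[1:]:
        if set(kps.points) != names:
            raise DataError("annotation sets carry different landmark names")
    mean_points = {
        name: Point2D(
            float(np.mean([k[name].x for k in annotation_sets])),
            float(np.mean([k[name].y for k in annotation_sets])),
        )
        for name in names
    }
    first = annotation_sets[0]
    return KeyPointSet(
        points=mean_points,
        pixel_spacing=first.pixel_spacing,
        anterior_side=first.anterior_side,
    )


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedMeasurements:
    """Reference vs model values of one parameter over n cases."""

    name: str
    reference: np.ndarray
    model: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        mod = np.asarray(self.model, dtype=float)
        if ref.ndim != 1 or ref.shape != mod.shape:
            raise DataError("reference and model must be equal-length 1D vectors")
        if ref.size < 3:
            raise DataError("need n >= 3 paired measurements")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(mod))):
            raise DataError("non-finite entries in paired measurements")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "model", mod)

    @property
    def n(self) -> int:
        return int(self.reference.size)


def icc(paired: PairedMeasurements,
        alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with the F-based
    confidence interval of Shrout & Fleiss.  Raises
    UndefinedStatisticError when the table has no variance at all.
    """
    data = np.column_stack([paired.reference, paired.model])
    n, k = data.shape
    if np.allclose(data, data.flat[0]):
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise UndefinedStatisticError("degenerate ANOVA table: ICC undefined")
    value = (msr - mse) / denom

    # F-based CI (Shrout & Fleiss 1979, ICC(2,1)).
    if mse <= 0:
        return float(value), (float(value), float(value))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * value * fj + n * (1 + (k - 1) * value) - k * value
    ) ** 2
    vd = (n - 1) * k**2 * value**2 * fj**2 + (
        n * (1 + (k - 1) * value) - k * value
    ) ** 2
    v = vn / vd
    # ppf can overflow to inf for tiny denominator dof; the CI bounds have
    # finite limits there, so a large clamp is asymptotically exact.
    f_upper = float(min(stats.f.ppf(1 - alpha / 2, n - 1, v), 1e12))
    f_lower = float(min(stats.f.ppf(1 - alpha / 2, v, n - 1), 1e12))
    lo = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return float(value), (float(lo), float(hi))


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of one parameter's model values with the reference."""

    name: str
    n: int
    icc: float
    icc_ci: tuple[float, float]
    r: float  # NaN when undefined (constant vector)
    md: float  # signed mean difference, model - reference
    sd: float  # SD of the differences
    mae: float
    rmse: float
    t: float
    p: float
    five_number: tuple[float, float, float, float, float]  # of differences

    def as_dict(self) -> dict:
        return {
            "parameter": self.name,
            "n": self.n,
            "ICC": self.icc,
            "ICC_CI_low": self.icc_ci[0],
            "ICC_CI_high": self.icc_ci[1],
            "r": self.r,
            "MD": self.md,
            "SD": self.sd,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "t": self.t,
            "p": self.p,
            "err_min": self.five_number[0],
            "err_q1": self.five_number[1],
            "err_median": self.five_number[2],
            "err_q3": self.five_number[3],
            "err_max": self.five_number[4],
        }


def agreement_report(paired: PairedMeasurements) -> AgreementReport:
    """Full agreement panel: ICC, r, MD, SD, MAE, RMSE, paired t, box stats."""
    diff = paired.model - paired.reference
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    icc_value, icc_ci = icc(paired)
    if np.std(paired.reference) == 0 or np.std(paired.model) == 0:
        warnings.warn(
            f"{paired.name}: constant vector, Pearson r undefined", stacklevel=2
        )
        r = float("nan")
    else:
        r = float(stats.pearsonr(paired.reference, paired.model).statistic)
    if np.allclose(diff, diff[0]) and np.isclose(sd, 0.0):
        t_stat, p_value = float("nan"), float("nan")
    else:
        res = stats.ttest_rel(paired.model, paired.reference)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    q1, med, q3 = (float(q) for q in np.percentile(diff, (25, 50, 75)))
    return AgreementReport(
        name=paired.name, n=paired.n, icc=icc_value, icc_ci=icc_ci, r=r,
        md=md, sd=sd, mae=mae, rmse=rmse, t=t_stat, p=p_value,
        five_number=(float(diff.min()), q1, med, q3, float(diff.max())),
    )


def agreement_table(reports: list[AgreementReport]) -> pd.DataFrame:
    """One row per parameter, fixed column order."""
    return pd.DataFrame([r.as_dict() for r in reports]).set_index("parameter")
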