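"""Cut-point derivation by constrained ROC analysis, AUC grading and validity.

For each wear location two binary discriminations are run over pooled
analysis-window epochs: sedentary vs not (low SVMgs predicts sedentary, so the
positive region lies *below* the threshold) and moderate-PA vs not (high SVMgs
predicts MPA, positive at or above the threshold).  Candidate thresholds are
the midpoints between consecutive distinct scores plus sentinels outside the
observed range.  The selected cut-point maximises Youden's J = Se + Sp − 1
subject to the calibration floor min(Se, Sp) >= 60%; if no threshold meets the
floor, the unconstrained Youden optimum is returned flagged
``constraint_met = False``.

AUC is the Mann–Whitney probability that a random positive is scored more
extreme (toward the positive direction) than a random negative, ties counting
one half; its 95% CI uses the Hanley–McNeil normal approximation.  AUCs are
graded excellent (>= 0.90), good [0.80, 0.90), fair [0.70, 0.80), poor
(< 0.70).  SVMgs values between the two cut-points classify as light PA.
Criterion validity is Spearman's rank correlation between SVMgs and METs,
overall and within each intensity stratum, with and without cycling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_log = logging.getLogger("accelcal")

POSITIVE_AT_OR_ABOVE = "positive_at_or_above"
POSITIVE_BELOW = "positive_below"

_Z975 = float(stats.norm.ppf(0.975))

CALIBRATION_COLUMNS = [
    "analysis_variant",
    "intensity",
    "location",
    "auc",
    "ci_lo",
    "ci_hi",
    "sensitivity_pct",
    "specificity_pct",
    "cutpoint_gs",
    "grade",
    "constraint_met",
]

VALIDITY_COLUMNS = ["analysis_variant", "location", "stratum", "rho", "n_epochs"]


@dataclass
class RocCurve:
    """Sensitivity/specificity over all candidate thresholds."""

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    direction: str


@dataclass(frozen=True)
class CutPointResult:
    intensity: str
    location: str
    auc: float
    ci95: tuple[float, float]
    se_pct: float
    sp_pct: float
    cutpoint: float
    grade: str
    constraint_met: bool


@dataclass(frozen=True)
class LightBand:
    """Displayed light-PA interval between the SB and MPA cut-points."""

    location: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("light band lower bound must be below upper bound")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")


def _as_arrays(scores: Iterable[float], labels: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
    y = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s, y


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct scores plus below-min/above-max sentinels."""
    ds = np.unique(scores)
    mids = (ds[:-1] + ds[1:]) / 2.0
    return np.concatenate(([ds[0] - 1.0], mids, [ds[-1] + 1.0]))


def roc_points(
    scores: Iterable[float], labels: Iterable[int], direction: str = POSITIVE_AT_OR_ABOVE
) -> RocCurve:
    """Sensitivity and specificity at every candidate threshold.

    ``positive_at_or_above``: predicted positive iff score >= threshold.
    ``positive_below``: predicted positive iff score < threshold (used for the
    sedentary analysis, where low movement predicts the behaviour).
    """
    s, y = _as_arrays(scores, labels)
    _check_two_classes(y)
    if direction not in (POSITIVE_AT_OR_ABOVE, POSITIVE_BELOW):
        raise ValueError(f"unknown direction {direction!r}")
    thr = candidate_thresholds(s)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    n_pos, n_neg = len(pos), len(neg)
    pos_below = np.searchsorted(pos, thr, side="left")  # count of positives < thr
    neg_below = np.searchsorted(neg, thr, side="left")
    if direction == POSITIVE_AT_OR_ABOVE:
        tp = n_pos - pos_below
        tn = neg_below
    else:
        tp = pos_below
        tn = n_neg - neg_below
    return RocCurve(thresholds=thr, se=tp / n_pos, sp=tn / n_neg, direction=direction)


def auc(
    scores: Iterable[float], labels: Iterable[int], direction: str = POSITIVE_AT_OR_ABOVE
) -> float:
    """Mann–Whitney AUC: P(positive scored more extreme than negative), ties ½."""
    s, y = _as_arrays(scores, labels)
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(s)  # mid-ranks
    u_high = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    a = u_high / (n_pos * n_neg)
    if direction == POSITIVE_BELOW:
        a = 1.0 - a
    elif direction != POSITIVE_AT_OR_ABOVE:
        raise ValueError(f"unknown direction {direction!r}")
    return float(a)


def auc_ci95(auc_value: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley–McNeil 95% CI, clipped to [0, 1]."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one observation in each class")
    a = float(auc_value)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = np.sqrt(max(var, 0.0))
    return (max(0.0, a - _Z975 * se), min(1.0, a + _Z975 * se))


def select_cutpoint(
    curve: RocCurve, min_se_sp: float = 0.60
) -> tuple[float, float, float, bool]:
    """Best threshold by Youden's J under the min(Se, Sp) floor.

    Among thresholds with min(Se, Sp) >= ``min_se_sp``, pick the one
    maximising Se + Sp; ties break toward smaller |Se − Sp|, then the lower
    threshold.  If no threshold meets the floor, the unconstrained Youden
    optimum is returned with ``constraint_met = False``.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty ROC curve")
    feasible = np.minimum(curve.se, curve.sp) >= min_se_sp
    constraint_met = bool(feasible.any())
    idx = np.flatnonzero(feasible) if constraint_met else np.arange(len(curve.thresholds))
    j = curve.se[idx] + curve.sp[idx]
    order = np.lexsort(
        (curve.thresholds[idx], np.abs(curve.se[idx] - curve.sp[idx]), -j)
    )
    best = idx[order[0]]
    return (
        float(curve.thresholds[best]),
        float(curve.se[best]),
        float(curve.sp[best]),
        constraint_met,
    )


def grade_auc(auc_value: float) -> str:
    """Diagnostic-accuracy grade: >=0.90 excellent, 0.80s good, 0.70s fair, else poor."""
    if not (0.0 <= auc_value <= 1.0):
        raise ValueError("AUC must lie in [0, 1]")
    if auc_value >= 0.90:
        return "excellent"
    if auc_value >= 0.80:
        return "good"
    if auc_value >= 0.70:
        return "fair"
    return "poor"


def light_band(
    sb_cut: float, mpa_cut: float, location: str = "", display_resolution: float = 0.1
) -> LightBand:
    """Displayed light-PA band one display unit inside the open interval."""
    if sb_cut >= mpa_cut:
        raise ValueError(
            f"non-monotone calibration: SB cut {sb_cut} is not below MPA cut {mpa_cut}"
        )
    decimals = max(0, int(np.ceil(-np.log10(display_resolution))))
    return LightBand(
        location=location,
        lower=round(sb_cut + display_resolution, decimals),
        upper=round(mpa_cut - display_resolution, decimals),
    )


def classify_epochs(svmgs: Iterable[float], sb_cut: float, mpa_cut: float) -> np.ndarray:
    """Three-level intensity per epoch: SB below sb_cut, MPA at/above mpa_cut."""
    if sb_cut >= mpa_cut:
        raise ValueError("sb_cut must be strictly below mpa_cut")
    v = np.asarray(list(svmgs) if not isinstance(svmgs, np.ndarray) else svmgs, dtype=float)
    return np.where(v < sb_cut, "SB", np.where(v >= mpa_cut, "MPA", "LPA"))


def spearman(x: Iterable[float], y: Iterable[float]) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks."""
    xa = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    ya = np.asarray(list(y) if not isinstance(y, np.ndarray) else y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Spearman's rho is undefined for constant input")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


# --------------------------------------------------------------------------- pipeline


def _one_roc_analysis(
    table: pd.DataFrame,
    intensity: str,
    location: str,
    direction: str,
    min_se_sp: float,
) -> CutPointResult:
    scores = table["svmgs"].to_numpy(dtype=float)
    labels = (table["intensity3"] == intensity).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError(
            f"location {location!r}, intensity {intensity!r}: both classes must be "
            "present after exclusions"
        )
    curve = roc_points(scores, labels, direction)
    a = auc(scores, labels, direction)
    ci = auc_ci95(a, int(labels.sum()), int((~labels).sum()))
    cut, se, sp, ok = select_cutpoint(curve, min_se_sp)
    return CutPointResult(
        intensity=intensity,
        location=location,
        auc=a,
        ci95=ci,
        se_pct=100.0 * se,
        sp_pct=100.0 * sp,
        cutpoint=cut,
        grade=grade_auc(a),
        constraint_met=ok,
    )


def run_calibration(
    labeled: pd.DataFrame,
    locations: Sequence[str] | None = None,
    exclude_activities: Iterable[str] = (),
    min_se_sp: float = 0.60,
    display_resolution: float = 0.1,
) -> tuple[list[CutPointResult], list[LightBand], pd.DataFrame]:
    """One analysis variant: per-location SB and MPA cut-points plus validity.

    ``labeled`` is the labeled-epoch table (one row per analysis-window epoch
    per location).  Epochs of ``exclude_activities`` are dropped before any
    statistic is computed.  Returns cut-point results, light bands, and a
    Spearman validity table (overall and per intensity stratum).
    """
    excl = set(exclude_activities)
    table = labeled[~labeled["activity"].isin(excl)] if excl else labeled
    if table.empty:
        raise ValueError("labeled table is empty after exclusions")
    if locations is None:
        locations = sorted(table["location"].unique())
    results: list[CutPointResult] = []
    bands: list[LightBand] = []
    validity_rows = []
    for loc in locations:
        sub = table[table["location"] == loc]
        if sub.empty:
            raise ValueError(f"no epochs for location {loc!r}")
        sb = _one_roc_analysis(sub, "SB", loc, POSITIVE_BELOW, min_se_sp)
        mpa = _one_roc_analysis(sub, "MPA", loc, POSITIVE_AT_OR_ABOVE, min_se_sp)
        results.extend([sb, mpa])
        # A light band only makes sense when both cut-points are usable: an
        # unconstrained fallback cut (floor not met) can sit below the SB cut.
        if sb.constraint_met and mpa.constraint_met:
            bands.append(light_band(sb.cutpoint, mpa.cutpoint, loc, display_resolution))
        else:
            _log.warning(
                "location %r: no light band derived (Se/Sp floor unmet for %s)",
                loc,
                "/".join(
                    r.intensity for r in (sb, mpa) if not r.constraint_met
                ),
            )
        validity_rows.append(
            {
                "location": loc,
                "stratum": "overall",
                "rho": spearman(sub["svmgs"], sub["mets"]),
                "n_epochs": len(sub),
            }
        )
        for stratum in ("SB", "LPA", "MPA"):
            strat = sub[sub["intensity3"] == stratum]
            rho = np.nan
            if len(strat) >= 3:
                try:
                    rho = spearman(strat["svmgs"], strat["mets"])
                except ValueError:
                    rho = np.nan
            validity_rows.append(
                {
                    "location": loc,
                    "stratum": stratum,
                    "rho": rho,
                    "n_epochs": len(strat),
                }
            )
    return results, bands, pd.DataFrame(validity_rows)


def run_both_variants(
    labeled: pd.DataFrame,
    locations: Sequence[str] | None = None,
    exclude_activities: Iterable[str] = ("cycle",),
    min_se_sp: float = 0.60,
    display_resolution: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[LightBand]]]:
    """Full analysis twice: all activities, then with the exclusion set removed.

    Returns the calibration table (both variants stacked), the validity table,
    and the light bands per variant.
    """
    calib_rows = []
    validity_frames = []
    bands_by_variant: dict[str, list[LightBand]] = {}
    for variant, excl in (("all", ()), ("no_cycling", tuple(exclude_activities))):
        results, bands, validity = run_calibration(
            labeled, locations, excl, min_se_sp, display_resolution
        )
        bands_by_variant[variant] = bands
        for r in results:
            calib_rows.append(
                {
                    "analysis_variant": variant,
                    "intensity": r.intensity,
                    "location": r.location,
                    "auc": r.auc,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "sensitivity_pct": r.se_pct,
                    "specificity_pct": r.sp_pct,
                    "cutpoint_gs": r.cutpoint,
                    "grade": r.grade,
                    "constraint_met": r.constraint_met,
                }
            )
        validity = validity.copy()
        validity.insert(0, "analysis_variant", variant)
        validity_frames.append(validity)
    calibration = pd.DataFrame(calib_rows, columns=CALIBRATION_COLUMNS)
    validity_all = pd.concat(validity_frames, ignore_index=True)[VALIDITY_COLUMNS]
    return calibration, validity_all, bands_by_variant
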