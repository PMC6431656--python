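"""ROC cut-point machinery against brute-force oracles and printed examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from accelcal.calibration import (
    POSITIVE_AT_OR_ABOVE,
    POSITIVE_BELOW,
    RocCurve,
    auc,
    auc_ci95,
    classify_epochs,
    grade_auc,
    light_band,
    roc_points,
    run_calibration,
    select_cutpoint,
    spearman,
)

# ------------------------------------------------------------------ brute oracles


def brute_confusion(scores, labels, thr, direction):
    tp = fn = tn = fp = 0
    for s, y in zip(scores, labels):
        pred = (s >= thr) if direction == POSITIVE_AT_OR_ABOVE else (s < thr)
        if y and pred:
            tp += 1
        elif y:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return tp / (tp + fn), tn / (tn + fp)


def brute_auc(scores, labels, direction):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if direction == POSITIVE_AT_OR_ABOVE:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
            else:
                total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_select(curve: RocCurve, min_se_sp):
    rows = list(zip(curve.thresholds, curve.se, curve.sp))
    feas = [r for r in rows if min(r[1], r[2]) >= min_se_sp]
    pool = feas if feas else rows
    best = min(pool, key=lambda r: (-(r[1] + r[2]), abs(r[1] - r[2]), r[0]))
    return best[0], best[1], best[2], bool(feas)


def brute_spearman(x, y):
    rx = stats.rankdata(x)  # mid-ranks
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def random_instance(rng, n_max=30):
    n = int(rng.integers(6, n_max + 1))
    scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
    labels = rng.integers(0, 2, n).astype(bool)
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


# ------------------------------------------------------------------ roc_points


class TestRocPoints:
    def test_perfect_separation_threshold(self):
        curve = roc_points([1, 2, 3, 4], [0, 0, 1, 1], POSITIVE_AT_OR_ABOVE)
        i = np.argmin(np.abs(curve.thresholds - 2.5))
        assert curve.thresholds[i] == 2.5
        assert curve.se[i] == 1.0 and curve.sp[i] == 1.0

    def test_degenerate_identical_scores(self):
        curve = roc_points([5, 5, 5, 5], [0, 1, 0, 1], POSITIVE_AT_OR_ABOVE)
        pts = set(zip(curve.se, curve.sp))
        assert pts == {(1.0, 0.0), (0.0, 1.0)}

    @pytest.mark.parametrize("direction", [POSITIVE_AT_OR_ABOVE, POSITIVE_BELOW])
    def test_confusion_counts_match_bruteforce(self, rng, direction):
        for _ in range(20):
            scores, labels = random_instance(rng, 20)
            curve = roc_points(scores, labels, direction)
            for t, se, sp in zip(curve.thresholds, curve.se, curve.sp):
                bse, bsp = brute_confusion(scores, labels, t, direction)
                assert se == pytest.approx(bse, abs=1e-12)
                assert sp == pytest.approx(bsp, abs=1e-12)

    def test_sentinels_cover_degenerate_classifications(self):
        curve = roc_points([1.0, 2.0], [0, 1], POSITIVE_AT_OR_ABOVE)
        assert curve.thresholds[0] < 1.0 and curve.thresholds[-1] > 2.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points([1, 2, 3], [1, 1, 1], POSITIVE_AT_OR_ABOVE)


class TestAuc:
    def test_perfect_and_tied_limits(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([7, 7, 7, 7], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, 15)
            a = auc(scores, labels, POSITIVE_AT_OR_ABOVE)
            assert a == pytest.approx(brute_auc(scores, labels, POSITIVE_AT_OR_ABOVE), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_direction_coherence(self, seed):
        """Relabelling positives as negatives and flipping direction maps A -> 1 - A."""
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        a = auc(scores, labels, POSITIVE_AT_OR_ABOVE)
        b = auc(scores, ~labels, POSITIVE_BELOW)
        assert b == pytest.approx(a, abs=1e-12)
        c = auc(scores, labels, POSITIVE_BELOW)
        assert c == pytest.approx(1.0 - a, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 50.0))
    def test_raising_positive_scores_never_lowers_auc(self, seed, shift):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        before = auc(scores, labels, POSITIVE_AT_OR_ABOVE)
        shifted = scores + shift * labels
        assert auc(shifted, labels, POSITIVE_AT_OR_ABOVE) >= before - 1e-12


class TestAucCi:
    def test_symmetric_about_half(self):
        lo, hi = auc_ci95(0.5, 500, 500)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_clipped_at_one(self):
        lo, hi = auc_ci95(1.0, 50, 50)
        assert hi == 1.0 and lo <= 1.0

    def test_hanley_mcneil_hand_computation(self):
        a, n1, n2 = 0.9, 100, 100
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
        )
        z = stats.norm.ppf(0.975)
        lo, hi = auc_ci95(a, n1, n2)
        assert lo == pytest.approx(a - z * se, abs=1e-12)
        assert hi == pytest.approx(a + z * se, abs=1e-12)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            auc_ci95(0.8, 0, 10)


class TestSelectCutpoint:
    def test_perfect_separation(self):
        curve = roc_points([1, 2, 3, 4], [0, 0, 1, 1], POSITIVE_AT_OR_ABOVE)
        cut, se, sp, ok = select_cutpoint(curve)
        assert (cut, se, sp, ok) == (2.5, 1.0, 1.0, True)

    def test_constraint_dominates_raw_youden(self):
        # best Youden point violates the floor; a feasible point must win
        curve = RocCurve(
            thresholds=np.array([1.0, 2.0]),
            se=np.array([0.95, 0.80]),
            sp=np.array([0.55, 0.65]),
            direction=POSITIVE_AT_OR_ABOVE,
        )
        cut, se, sp, ok = select_cutpoint(curve, 0.60)
        assert (cut, se, sp, ok) == (2.0, 0.80, 0.65, True)

    def test_infeasible_curve_falls_back_unconstrained(self):
        curve = RocCurve(
            thresholds=np.array([1.0, 2.0]),
            se=np.array([0.9, 0.5]),
            sp=np.array([0.3, 0.55]),
            direction=POSITIVE_AT_OR_ABOVE,
        )
        cut, se, sp, ok = select_cutpoint(curve, 0.60)
        assert not ok and cut == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            curve = roc_points(scores, labels, POSITIVE_AT_OR_ABOVE)
            got = select_cutpoint(curve, 0.60)
            expected = brute_select(curve, 0.60)
            assert got == pytest.approx(expected)

    def test_floor_guarantee_whenever_flagged(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            curve = roc_points(scores, labels, POSITIVE_BELOW)
            _, se, sp, ok = select_cutpoint(curve, 0.60)
            if ok:
                assert min(se, sp) >= 0.60


class TestGradeAuc:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.977, "excellent"),
            (0.90, "excellent"),
            (0.869, "good"),
            (0.80, "good"),
            (0.742, "fair"),
            (0.70, "fair"),
            (0.669, "poor"),
            (0.0, "poor"),
        ],
    )
    def test_grading_scale(self, value, grade):
        assert grade_auc(value) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_auc(1.2)


class TestLightBand:
    def test_display_band_one_unit_inside(self):
        band = light_band(4.8, 12.0)
        assert (band.lower, band.upper) == (4.9, 11.9)

    def test_wide_ankle_band(self):
        band = light_band(4.4, 129.2)
        assert (band.lower, band.upper) == (4.5, 129.1)

    def test_non_monotone_cuts_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            light_band(5.0, 5.0)


class TestClassifyEpochs:
    def test_boundaries(self):
        out = classify_epochs([1.0, 5.0, 12.0, 11.99], sb_cut=4.8, mpa_cut=12.0)
        assert out.tolist() == ["SB", "LPA", "MPA", "LPA"]

    def test_partition_is_total(self, rng):
        vals = rng.uniform(0, 20, 1000)
        out = classify_epochs(vals, 4.8, 12.0)
        counts = pd.Series(out).value_counts()
        assert counts.sum() == 1000 and set(counts.index) <= {"SB", "LPA", "MPA"}

    def test_non_monotone_cuts_rejected(self):
        with pytest.raises(ValueError):
            classify_epochs([1.0], 5.0, 4.0)


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([1.0, 2.5, 4.0, 9.0, 16.0])
        assert spearman(x, np.exp(x / 10)) == pytest.approx(1.0)
        assert spearman(x, -np.exp(x / 10)) == pytest.approx(-1.0)

    def test_tied_instance_matches_midrank_oracle(self, rng):
        for _ in range(20):
            x = np.round(rng.normal(size=12), 0)
            y = np.round(rng.normal(size=12), 0)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------------ run_calibration


def separable_table(rng, locations=("waist", "ankle")):
    """Noise-free monotone SVMgs-MET mapping: perfectly separable classes."""
    rows = []
    for loc in locations:
        for b, (mets, i3) in enumerate(
            [(1.0, "SB"), (1.2, "SB"), (2.0, "LPA"), (2.5, "LPA"), (3.5, "MPA"), (4.5, "MPA")]
        ):
            for e in range(30):
                rows.append(
                    {
                        "participant_id": "P01",
                        "location": loc,
                        "activity": f"act{b}",
                        "epoch_start_s": float(e),
                        "svmgs": 10 * mets + 0.01 * e,
                        "mets": mets,
                        "intensity3": i3,
                    }
                )
    return pd.DataFrame(rows)


class TestRunCalibration:
    def test_separable_limit_all_aucs_one(self, rng):
        results, bands, validity = run_calibration(separable_table(rng))
        assert all(r.auc == 1.0 and r.grade == "excellent" for r in results)
        assert all(r.constraint_met for r in results)
        assert len(bands) == 2

    def test_excluding_cycle_is_local(self, rng):
        table = separable_table(rng)
        table.loc[table["activity"] == "act5", "activity"] = "cycle"
        res_all, _, _ = run_calibration(table)
        res_nc, _, _ = run_calibration(table, exclude_activities={"cycle"})
        assert len(res_all) == len(res_nc) == 4
        # remaining epochs keep their labels: SB analysis unchanged counts
        sb_all = [r for r in res_all if r.intensity == "SB"]
        sb_nc = [r for r in res_nc if r.intensity == "SB"]
        assert all(r.auc == 1.0 for r in sb_all + sb_nc)

    def test_missing_class_after_exclusion_named(self, rng):
        table = separable_table(rng)
        table.loc[table["intensity3"] == "MPA", "activity"] = "cycle"
        with pytest.raises(ValueError, match="MPA"):
            run_calibration(table, exclude_activities={"cycle"})

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.5, 20.0))
    def test_pipeline_monotonicity_shifting_mpa_up_never_hurts(self, seed, shift):
        rng = np.random.default_rng(seed)
        n = 120
        mets = rng.uniform(1.0, 5.0, n)
        labels = mets >= 3.0
        if labels.all() or not labels.any():
            return
        svmgs = 5 * mets + rng.normal(0, 3, n)
        before = auc(svmgs, labels, POSITIVE_AT_OR_ABOVE)
        after = auc(svmgs + shift * labels, labels, POSITIVE_AT_OR_ABOVE)
        assert after >= before - 1e-12
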