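import numpy as np
import pytest

from lumbometry.errors import DataError, UndefinedStatisticError
from lumbometry.geometry import KeyPointSet, Point2D
from lumbometry.metrics import (
    AgreementReport, PairedMeasurements, agreement_report, agreement_table,
    dice_coefficient, icc, observer_reliability, pck, pixel_accuracy,
    reference_standard,
)


def kps_from(points, spacing=(1.0, 1.0)):
    return KeyPointSet(
        points={k: Point2D(*v) for k, v in points.items()},
        pixel_spacing=spacing,
    )


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).integers(0, 3, (20, 20))
        assert dice_coefficient(m, m, 1) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), int)
        b = np.zeros((10, 10), int)
        a[:5], b[5:] = 1, 1
        assert dice_coefficient(a, b, 1) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), int)
        b = np.zeros((20, 20), int)
        a[0:10, 0:10] = 1
        b[5:15, 0:10] = 1
        assert dice_coefficient(a, b, 1) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((5, 5), int)
        assert dice_coefficient(z, z, 2) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 3, (15, 15)), rng.integers(0, 3, (15, 15))
        assert dice_coefficient(a, b, 1) == dice_coefficient(b, a, 1)

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            dice_coefficient(np.zeros((3, 3)), np.zeros((4, 4)), 1)


class TestPixelAccuracy:
    def test_identical(self):
        m = np.random.default_rng(0).integers(0, 3, (10, 10))
        assert pixel_accuracy(m, m, 1) == 1.0

    def test_complement(self):
        a = np.zeros((10, 10), int)
        b = np.ones((10, 10), int)
        assert pixel_accuracy(a, b, 1) == 0.0

    def test_hand_counted(self):
        a = np.zeros((10, 10), int)
        b = np.zeros((10, 10), int)
        b[0, :] = 1  # 10 disagreeing pixels out of 100
        assert pixel_accuracy(a, b, 1) == pytest.approx(0.9)


class TestPck:
    def test_identity_hundred_everywhere(self):
        kps = kps_from({"L1SA": (3, 4), "L5IP": (10, 20)})
        table = pck([kps], [kps])
        assert (table.values == 100.0).all()

    def test_one_of_ten_displaced(self):
        names = ["L1SA", "L1SP", "L4IA", "L4IP", "L5SA",
                 "L5SP", "L5IA", "L5IP", "S1SA", "S1SP"]
        ref = kps_from({n: (10.0 * i, 5.0) for i, n in enumerate(names)})
        shifted = {n: (10.0 * i, 5.0) for i, n in enumerate(names)}
        shifted["S1SP"] = (90.0, 9.0)  # 4 mm away at 1 mm/px
        pred = kps_from(shifted)
        table = pck([pred], [ref], thresholds_mm=(3.0,))
        assert table.loc[3.0, "all"] == pytest.approx(90.0)
        assert table.loc[3.0, "S1SP"] == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        names = ["L1SA", "L5IA", "S1SP"]
        preds, refs = [], []
        for _ in range(30):
            ref = kps_from({n: tuple(rng.uniform(0, 50, 2)) for n in names})
            pred = kps_from(
                {
                    n: (ref[n].x + rng.normal(0, 2), ref[n].y + rng.normal(0, 2))
                    for n in names
                }
            )
            preds.append(pred)
            refs.append(ref)
        table = pck(preds, refs, thresholds_mm=(1, 2, 3, 4, 5))
        for col in table.columns:
            vals = table[col].to_numpy()
            assert np.all(np.diff(vals) >= 0)

    def test_spacing_respected(self):
        ref = kps_from({"L1SA": (0.0, 0.0)}, spacing=(0.5, 0.5))
        pred = kps_from({"L1SA": (4.0, 0.0)}, spacing=(0.5, 0.5))  # 2 mm
        table = pck([pred], [ref], thresholds_mm=(1.0, 3.0))
        assert table.loc[1.0, "L1SA"] == 0.0
        assert table.loc[3.0, "L1SA"] == 100.0

    def test_missing_spacing_raises(self):
        ref = kps_from({"L1SA": (0, 0)}, spacing=None)
        with pytest.raises(DataError):
            pck([ref], [ref])


class TestObserverReliability:
    def test_identical_sessions(self):
        sets = {
            "S1": {"img": kps_from({"L1SA": (1, 2), "S1SP": (3, 4)})},
            "S2": {"img": kps_from({"L1SA": (1, 2), "S1SP": (3, 4)})},
        }
        table = observer_reliability(sets)
        assert (table.loc["S1 vs. S2"].values == 100.0).all()

    def test_uniform_shift(self):
        base = {"L1SA": (10.0, 10.0), "L5IP": (30.0, 40.0)}
        shifted = {k: (x + 2.5, y) for k, (x, y) in base.items()}
        sets = {
            "a": {"img": kps_from(base)},
            "b": {"img": kps_from(shifted)},
        }
        table = observer_reliability(sets, thresholds_mm=(1, 2, 3, 4, 5))
        assert list(table.loc["a vs. b"]) == [0.0, 0.0, 100.0, 100.0, 100.0]

    def test_monte_carlo_oracle(self):
        # Three raters with iid isotropic 1-mm-per-axis noise: the pooled
        # percentage within r of each other matches simulation within 2 pts.
        rng = np.random.default_rng(0)
        names = ["L1SA", "L4IA", "L5SP", "S1SA"]
        sets = {r: {} for r in ("S1", "S2", "S3")}
        for i in range(1000):
            base = {n: rng.uniform(20, 80, 2) for n in names}
            for r in sets:
                sets[r][f"img{i:03d}"] = kps_from(
                    {n: tuple(base[n] + rng.normal(0, 1.0, 2)) for n in names}
                )
        table = observer_reliability(sets, thresholds_mm=(2.0,))
        # distance of two iid N(0,1)^2 points ~ sqrt(2)*chi_2; MC oracle:
        sim = np.random.default_rng(1).normal(0, 1.0, (200_000, 2, 2))
        d = np.hypot(*(sim[:, 0] - sim[:, 1]).T)
        expected = 100.0 * float(np.mean(d <= 2.0))
        for row in table.index:
            assert table.loc[row, 2.0] == pytest.approx(expected, abs=2.0)

    def test_mismatched_images_raise(self):
        sets = {
            "a": {"x": kps_from({"L1SA": (0, 0)})},
            "b": {"y": kps_from({"L1SA": (0, 0)})},
        }
        with pytest.raises(DataError):
            observer_reliability(sets)


class TestReferenceStandard:
    def test_single_set_unchanged(self):
        kps = kps_from({"L1SA": (3.0, 4.0)})
        mean = reference_standard([kps])
        assert mean["L1SA"] == kps["L1SA"]

    def test_arithmetic_mean(self):
        sets = [kps_from({"L1SA": (x, 0.0)}) for x in (0.0, 2.0, 4.0)]
        assert reference_standard(sets)["L1SA"] == Point2D(2.0, 0.0)

    def test_mean_beats_single_rater(self):
        rng = np.random.default_rng(0)
        truth = {"L1SA": np.array([40.0, 50.0])}
        raters = [
            kps_from({"L1SA": tuple(truth["L1SA"] + rng.normal(0, 2, 2))})
            for _ in range(3)
        ]
        mean = reference_standard(raters)
        rms_mean = np.hypot(mean["L1SA"].x - 40, mean["L1SA"].y - 50)
        rms_raters = np.mean(
            [np.hypot(r["L1SA"].x - 40, r["L1SA"].y - 50) for r in raters]
        )
        assert rms_mean < rms_raters

    def test_mismatched_names_raise(self):
        with pytest.raises(DataError):
            reference_standard(
                [kps_from({"L1SA": (0, 0)}), kps_from({"L1SP": (0, 0)})]
            )


def icc21_bruteforce(x, y):
    """Independent ANOVA mean-squares oracle for ICC(2,1), two raters."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(1, keepdims=True)
            - data.mean(0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (ms_rows - mse) / (
        ms_rows + (k - 1) * mse + k * (ms_cols - mse) / n
    )


class TestIcc:
    def test_perfect_agreement(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        value, (lo, hi) = icc(PairedMeasurements("x", v, v.copy()))
        assert value == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 21))
            ref = rng.normal(50, 8, n)
            mod = ref + rng.normal(1, 2, n)
            value, _ = icc(PairedMeasurements("x", ref, mod))
            assert value == pytest.approx(icc21_bruteforce(ref, mod), abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 12
        ref = rng.normal(50, 8, n)
        mod = ref + rng.normal(1, 2, n)
        value, (lo, hi) = icc(PairedMeasurements("x", ref, mod))
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(n), 2),
                "raters": np.repeat(["a", "b"], n),
                "ratings": np.concatenate([ref, mod]),
            }
        )
        row = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).iloc[1]  # ICC(A,1) == ICC(2,1)
        assert value == pytest.approx(row["ICC"], abs=1e-9)
        assert lo == pytest.approx(row["CI95"][0], abs=0.01)
        assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_bias_lowers_icc_not_r(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        ref = rng.normal(50, 8, 20)
        mod = ref + rng.normal(0, 1, 20)
        base, _ = icc(PairedMeasurements("x", ref, mod))
        biased, _ = icc(PairedMeasurements("x", ref, mod + 5.0))
        assert biased < base
        r1 = stats.pearsonr(ref, mod).statistic
        r2 = stats.pearsonr(ref, mod + 5.0).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_undefined(self):
        v = np.full(5, 3.0)
        with pytest.raises(UndefinedStatisticError):
            icc(PairedMeasurements("x", v, v.copy()))

    def test_needs_three_pairs(self):
        with pytest.raises(DataError):
            PairedMeasurements("x", np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestAgreementReport:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 5.0])
        with pytest.warns(UserWarning, match="r undefined") if False else \
                np.errstate():
            rep = agreement_report(PairedMeasurements("LL", v, v.copy()))
        assert rep.md == 0.0
        assert rep.mae == 0.0
        assert rep.rmse == 0.0
        assert np.isnan(rep.t)

    def test_constant_shift(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        rep = agreement_report(PairedMeasurements("LL", v, v + 2.0))
        assert rep.md == pytest.approx(2.0)
        assert rep.sd == pytest.approx(0.0)
        assert rep.mae == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(2.0)

    def test_brute_force_recomputation(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(40, 6, 25)
        mod = ref + rng.normal(1, 3, 25)
        rep = agreement_report(PairedMeasurements("SHA", ref, mod))
        diff = mod - ref
        assert rep.mae == pytest.approx(np.abs(diff).mean(), abs=1e-9)
        assert rep.rmse == pytest.approx(np.sqrt((diff**2).mean()), abs=1e-9)
        assert rep.mae <= rep.rmse
        assert rep.md == pytest.approx(diff.mean(), abs=1e-9)
        assert rep.five_number[0] == diff.min()
        assert rep.five_number[4] == diff.max()
        assert rep.five_number == tuple(sorted(rep.five_number))

    def test_reorder_invariance(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(40, 6, 15)
        mod = ref + rng.normal(1, 2, 15)
        rep1 = agreement_report(PairedMeasurements("x", ref, mod))
        perm = rng.permutation(15)
        rep2 = agreement_report(PairedMeasurements("x", ref[perm], mod[perm]))
        assert rep1.icc == pytest.approx(rep2.icc, abs=1e-12)
        assert rep1.mae == pytest.approx(rep2.mae, abs=1e-12)
        assert rep1.t == pytest.approx(rep2.t, abs=1e-9)

    def test_constant_vector_r_warns(self):
        ref = np.full(5, 2.0)
        mod = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="undefined"):
            rep = agreement_report(PairedMeasurements("x", ref, mod))
        assert np.isnan(rep.r)

    def test_table_layout(self):
        rng = np.random.default_rng(6)
        reports = []
        for name in ("LL", "SHA"):
            ref = rng.normal(40, 6, 10)
            reports.append(
                agreement_report(
                    PairedMeasurements(name, ref, ref + rng.normal(1, 2, 10))
                )
            )
        table = agreement_table(reports)
        assert list(table.index) == ["LL", "SHA"]
        assert list(table.columns[:8]) == [
            "n", "ICC", "ICC_CI_low", "ICC_CI_high", "r", "MD", "SD", "MAE"
        ]
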