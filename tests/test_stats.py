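"""Agreement statistics: Dice conventions, exact CIs, kappa, ICC, Bland-Altman."""

import itertools

import numpy as np
import pandas as pd
import pytest

import octquant as oq
from octquant.errors import (
    DomainError,
    EmptySetError,
    GeometryMismatchError,
    IndexMismatchError,
    TooFewPairsError,
    UndefinedScoreError,
)
from octquant.schema import LIPID
from octquant.stats import ConfusionTable, FrameDiceRecord, confusion_from_presence


def _frame(labels, spacing=0.01):
    labels = np.asarray(labels, dtype=np.int16)
    geom = oq.PixelGeometry(spacing_mm=spacing, frame_shape=labels.shape)
    return oq.Frame(labels, geom)


# Internal-test frame-wise identification table: per-class 2x2 counts and the
# published percentage cells they imply (value, then each metric as %).
IDENTIFICATION_FIXTURE = {
    "lipid": dict(tp=100, fp=18, fn=2, tn=98, accuracy=90.8, sensitivity=98.0,
                  specificity=84.5, ppv=84.7, npv=98.0, kappa=0.817),
    "lrp": dict(tp=73, fp=13, fn=3, tn=129, accuracy=92.7, sensitivity=96.1,
                specificity=90.8, ppv=84.9, npv=97.7, kappa=0.843),
    "calcium": dict(tp=47, fp=11, fn=6, tn=154, accuracy=92.2, sensitivity=88.7,
                    specificity=93.3, ppv=81.0, npv=96.3, kappa=0.795),
    "side_branch": dict(tp=36, fp=9, fn=10, tn=163, accuracy=91.3, sensitivity=78.3,
                        specificity=94.8, ppv=80.0, npv=94.2, kappa=0.736),
    "thrombus": dict(tp=19, fp=3, fn=2, tn=194, accuracy=97.7, sensitivity=90.5,
                     specificity=98.5, ppv=86.4, npv=99.0, kappa=0.871),
    "plaque_rupture": dict(tp=5, fp=9, fn=1, tn=203, accuracy=95.4, sensitivity=83.3,
                           specificity=95.8, ppv=35.7, npv=99.5, kappa=0.480),
}


class TestDiceFrame:
    def test_identical_masks(self):
        a = np.zeros((40, 40));  a[5:15, 5:15] = LIPID
        rec = oq.dice_frame(_frame(a), _frame(a), LIPID)
        assert rec.dice == 1.0 and rec.category == "TP"

    def test_missing_prediction_is_false_negative(self):
        a = np.zeros((40, 40)); a[5:15, 5:15] = LIPID
        rec = oq.dice_frame(_frame(a), _frame(np.zeros((40, 40))), LIPID)
        assert rec.dice == 0.0 and rec.category == "FN"

    def test_spurious_prediction_is_false_positive(self):
        b = np.zeros((40, 40)); b[5:15, 5:15] = LIPID
        rec = oq.dice_frame(_frame(np.zeros((40, 40))), _frame(b), LIPID)
        assert rec.dice == 0.0 and rec.category == "FP"

    def test_both_absent_true_negative_no_score(self):
        rec = oq.dice_frame(_frame(np.zeros((40, 40))), _frame(np.zeros((40, 40))), LIPID)
        assert rec.dice is None and rec.category == "TN"

    def test_half_overlap_closed_form(self):
        a = np.zeros((40, 40)); a[0:10, 0:10] = LIPID        # 100 px
        b = np.zeros((40, 40)); b[5:15, 0:10] = LIPID        # 100 px, overlap 50
        rec = oq.dice_frame(_frame(a), _frame(b), LIPID)
        assert rec.dice == pytest.approx(0.5)

    def test_symmetric(self):
        a = np.zeros((40, 40)); a[0:10, 0:10] = LIPID
        b = np.zeros((40, 40)); b[5:15, 0:10] = LIPID
        assert oq.dice_frame(_frame(a), _frame(b), LIPID).dice == \
               oq.dice_frame(_frame(b), _frame(a), LIPID).dice

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryMismatchError):
            oq.dice_frame(_frame(np.zeros((40, 40))), _frame(np.zeros((48, 48))), LIPID)


class TestAggregateDice:
    def test_fp_fn_drag_the_all_mode_mean(self):
        recs = [
            FrameDiceRecord(LIPID, 0, 0.8, "TP"),
            FrameDiceRecord(LIPID, 1, 0.0, "FN"),
            FrameDiceRecord(LIPID, 2, None, "TN"),
        ]
        mean_all, _ = oq.aggregate_dice(recs, "all")
        mean_tp, _ = oq.aggregate_dice(recs, "tp_only")
        assert mean_all == pytest.approx(0.4)
        assert mean_tp == pytest.approx(0.8)

    def test_all_true_negative_raises(self):
        with pytest.raises(EmptySetError):
            oq.aggregate_dice([FrameDiceRecord(LIPID, 0, None, "TN")], "all")

    def test_perfect_scores(self):
        recs = [FrameDiceRecord(LIPID, i, 1.0, "TP") for i in range(5)]
        assert oq.aggregate_dice(recs, "all") == (1.0, 0.0)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(5, 14, 0.128, 0.649), (100, 102, 0.931, 0.998)],
    )
    def test_published_intervals(self, k, n, lo, hi):
        got = oq.clopper_pearson(k, n)
        assert round(got[0], 3) == lo and round(got[1], 3) == hi

    def test_boundaries(self):
        assert oq.clopper_pearson(0, 10)[0] == 0.0
        assert oq.clopper_pearson(10, 10)[1] == 1.0

    def test_interval_contains_point_and_narrows_with_n(self):
        for k, n in [(3, 10), (30, 100), (300, 1000)]:
            lo, hi = oq.clopper_pearson(k, n)
            assert lo <= k / n <= hi
        widths = [np.diff(oq.clopper_pearson(3 * m, 10 * m))[0] for m in (1, 10, 100)]
        assert widths[0] > widths[1] > widths[2]

    def test_domain_error(self):
        with pytest.raises(DomainError):
            oq.clopper_pearson(5, 4)


class TestBinaryMetrics:
    @pytest.mark.parametrize("cls", sorted(IDENTIFICATION_FIXTURE))
    def test_reproduces_published_percentages(self, cls):
        fx = IDENTIFICATION_FIXTURE[cls]
        t = ConfusionTable(fx["tp"], fx["fp"], fx["fn"], fx["tn"])
        assert t.n == 218
        res = oq.binary_metrics(t)
        for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert res[metric].estimate * 100 == pytest.approx(fx[metric], abs=0.05)

    def test_rupture_ppv_interval(self):
        res = oq.binary_metrics(ConfusionTable(5, 9, 1, 203))
        ppv = res["ppv"]
        assert round(ppv.estimate * 100, 1) == 35.7
        assert round(ppv.ci_low * 100, 1) == 12.8
        assert round(ppv.ci_high * 100, 1) == 64.9

    def test_perfect_classifier_ci_excludes_zero_width(self):
        res = oq.binary_metrics(ConfusionTable(tp=20, fp=0, fn=0, tn=0))
        acc = res["accuracy"]
        assert acc.estimate == 1.0 and acc.ci_low > 0.0 and acc.ci_high == 1.0
        assert "specificity" not in res  # zero denominator omitted


class TestCohensKappa:
    @pytest.mark.parametrize("cls", sorted(IDENTIFICATION_FIXTURE))
    def test_reproduces_published_kappas(self, cls):
        fx = IDENTIFICATION_FIXTURE[cls]
        k = oq.cohens_kappa(ConfusionTable(fx["tp"], fx["fp"], fx["fn"], fx["tn"]))
        assert round(k.estimate, 3) == fx["kappa"]

    def test_perfect_agreement(self):
        assert oq.cohens_kappa(ConfusionTable(10, 0, 0, 10)).estimate == 1.0

    def test_independence_gives_zero(self):
        assert oq.cohens_kappa(ConfusionTable(25, 25, 25, 25)).estimate == 0.0

    def test_matches_brute_force_over_all_small_tables(self):
        """Exhaustive oracle: direct (po-pe)/(1-pe) on every 2x2 with n <= 50."""
        checked = 0
        for n in range(1, 51):
            for tp, fp, fn in itertools.product(range(n + 1), repeat=3):
                tn = n - tp - fp - fn
                if tn < 0:
                    continue
                po = (tp + tn) / n
                pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
                if pe == 1.0:
                    continue
                expected = (po - pe) / (1.0 - pe)
                got = oq.cohens_kappa(ConfusionTable(tp, fp, fn, tn)).estimate
                assert got == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 100_000

    def test_ci_brackets_estimate(self):
        k = oq.cohens_kappa(ConfusionTable(100, 18, 2, 98))
        assert k.ci_low < k.estimate < k.ci_high


class TestIccAbsolute:
    def test_identical_raters_give_one(self):
        x = np.arange(10.0)
        assert oq.icc_absolute(x, x).estimate == pytest.approx(1.0)

    def test_constant_offset_penalized_vs_consistency(self):
        rng = np.random.default_rng(5)
        base = rng.normal(50, 10, 30)
        shifted = base + 25.0
        icc_a = oq.icc_absolute(base, shifted).estimate
        # ICC(3,1) consistency ignores the rater bias entirely
        assert icc_a < 0.5 < 1.0

    def test_matches_pingouin_icc2(self):
        import pingouin as pg

        rng = np.random.default_rng(0)
        subj = rng.normal(0, 10, 40)
        r1 = subj + rng.normal(0, 3, 40)
        r2 = subj + 2 + rng.normal(0, 3, 40)
        ours = oq.icc_absolute(r1, r2)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile(["a", "b"], 40),
                "scores": np.column_stack([r1, r2]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "scores")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)"].iloc[0] if (ref["Type"] == "ICC(A,1)").any() \
            else ref.loc[ref["Type"] == "ICC2"].iloc[0]
        assert ours.estimate == pytest.approx(float(icc2["ICC"]), abs=1e-9)
        assert ours.ci_low == pytest.approx(float(icc2["CI95"][0]), abs=0.01)
        assert ours.ci_high == pytest.approx(float(icc2["CI95"][1]), abs=0.01)

    def test_recovers_variance_components(self):
        """ICC(2,1) -> sigma_s^2 / (sigma_s^2 + sigma_r^2 + sigma_e^2)."""
        rng = np.random.default_rng(11)
        target = 100.0 / (100.0 + 9.0)  # subject SD 10, error SD 3, no rater effect
        est = []
        for _ in range(500):
            subj = rng.normal(0, 10, 20)
            r1 = subj + rng.normal(0, 3, 20)
            r2 = subj + rng.normal(0, 3, 20)
            est.append(oq.icc_absolute(r1, r2).estimate)
        assert np.mean(est) == pytest.approx(target, abs=0.02)

    def test_too_few_pairs(self):
        with pytest.raises(TooFewPairsError):
            oq.icc_absolute([1, 2], [1, 2])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = oq.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["mean_diff"] == 0.0 and res["sd_diff"] == 0.0

    def test_constant_offset(self):
        res = oq.bland_altman([6.0, 7.0, 8.0], [1.0, 2.0, 3.0])
        assert res["mean_diff"] == 5.0 and res["sd_diff"] == 0.0
        assert res["loa_low"] == res["loa_high"] == 5.0

    def test_recovers_simulated_bias_and_sd(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(100, 20, 10_000)
        pred = ref + rng.normal(2, 4, 10_000)
        res = oq.bland_altman(pred, ref)
        assert res["mean_diff"] == pytest.approx(2.0, abs=0.15)
        assert res["sd_diff"] == pytest.approx(4.0, abs=0.15)
        assert res["loa_low"] == pytest.approx(2 - 1.96 * 4, abs=0.3)

    def test_too_few_pairs(self):
        with pytest.raises(TooFewPairsError):
            oq.bland_altman([1.0], [2.0])


class TestConsensusAndReference:
    def test_consensus_subset_size(self):
        rng = np.random.default_rng(8)
        idx = pd.RangeIndex(392)
        obs1 = pd.Series(rng.random(392) < 0.5, index=idx)
        # force agreement on exactly 306 frames
        obs2 = obs1.copy()
        flip = rng.choice(392, size=392 - 306, replace=False)
        obs2.iloc[flip] = ~obs2.iloc[flip]
        cons = oq.consensus_frames(obs1, obs2)
        assert len(cons) == 306
        assert (cons == obs1[cons.index]).all()

    def test_full_agreement_and_disagreement(self):
        a = pd.Series([True, False, True])
        assert len(oq.consensus_frames(a, a)) == 3
        assert len(oq.consensus_frames(a, ~a)) == 0

    def test_index_mismatch(self):
        a = pd.Series([True], index=[0])
        b = pd.Series([True], index=[5])
        with pytest.raises(IndexMismatchError):
            oq.consensus_frames(a, b)

    def test_mean_reference(self):
        assert oq.mean_reference([100.0], [120.0])[0] == 110.0
        np.testing.assert_allclose(oq.mean_reference([3.0, 4.0], [3.0, 4.0]), [3.0, 4.0])

    def test_confusion_from_presence(self):
        t = confusion_from_presence([True, True, False, False], [True, False, True, False])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)
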