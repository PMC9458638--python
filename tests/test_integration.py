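"""ROC calibration, likelihood-ratio integration, thresholding, enrichment."""

import numpy as np
import pandas as pd
import pytest

from hetscreen import (
    enrichment_curves,
    integrate_table,
    integrated_score,
    roc_calibrate,
    select_threshold,
    simulate_benchmark,
)
from hetscreen.integrate import Calibration
from sklearn.metrics import roc_auc_score


def _bench(n_pos, n_neg, effects, seed=0):
    df = simulate_benchmark(n_pos, n_neg, effects, seed=seed)
    return df.drop(columns=["variant_id", "label"]), df["label"].to_numpy()


class TestCalibration:
    def test_no_signal_area_near_half(self):
        scores, labels = _bench(400, 400, {"x": 0.0}, seed=1)
        calib = roc_calibrate(scores, labels)
        assert calib.channels["x"].auc == pytest.approx(0.5, abs=0.06)

    def test_separable_channel(self):
        scores = pd.DataFrame({"x": np.r_[np.ones(50), np.zeros(50)]})
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        calib = roc_calibrate(scores, labels)
        cc = calib.channels["x"]
        assert cc.auc == pytest.approx(1.0)
        tpr, fpr = cc.operating_point(1.0)
        assert tpr / fpr == max(
            cc.operating_point(t)[0] / cc.operating_point(t)[1]
            for t in (0.0, 0.5, 1.0)
        )

    def test_effect_ordering_recovered(self):
        scores, labels = _bench(1500, 1500, {"weak": 0.3, "strong": 1.5}, seed=2)
        calib = roc_calibrate(scores, labels)
        assert calib.channels["strong"].auc > calib.channels["weak"].auc

    def test_direction_autodetected(self):
        scores, labels = _bench(500, 500, {"x": 1.0}, seed=3)
        calib = roc_calibrate(scores, labels)
        # positives shifted downward -> smaller raw score = damaging
        assert calib.channels["x"].direction == -1
        assert calib.channels["x"].auc > 0.7

    def test_monotone_transform_invariance(self):
        scores, labels = _bench(300, 300, {"x": 1.0}, seed=4)
        calib1 = roc_calibrate(scores, labels)
        calib2 = roc_calibrate(scores.apply(lambda c: np.exp(0.5 * c)), labels)
        v = float(scores["x"].iloc[10])
        assert calib1.channels["x"].operating_point(v) == pytest.approx(
            calib2.channels["x"].operating_point(float(np.exp(0.5 * v))))

    def test_endpoints_present(self):
        scores, labels = _bench(50, 50, {"x": 1.0}, seed=5)
        cc = roc_calibrate(scores, labels).channels["x"]
        assert cc.tpr[0] == 0.0 and cc.tpr[-1] == 1.0
        assert cc.fpr[0] == 0.0 and cc.fpr[-1] == 1.0
        assert (np.diff(cc.tpr) >= 0).all() and (np.diff(cc.fpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_calibrate(pd.DataFrame({"x": [1.0, 2.0]}), [True, True])

    def test_json_round_trip(self, tmp_path):
        scores, labels = _bench(100, 100, {"x": 1.0, "y": 0.5}, seed=6)
        calib = roc_calibrate(scores, labels)
        path = tmp_path / "calib.json"
        calib.to_json(path)
        back = Calibration.from_json(path)
        for name, cc in calib.channels.items():
            bc = back.channels[name]
            assert bc.direction == cc.direction and bc.auc == pytest.approx(cc.auc)
            np.testing.assert_allclose(bc.thresholds, cc.thresholds)


def _hand_calibration():
    """2 positives, 5 negatives; one item of each class above value 0.5.

    At threshold 0.5: TP=1, FP=1, smoothed TPR = 1.5/3 = 0.5 and
    FPR = 1.5/6 = 0.25, so the single-channel term is log2(2) = 1 bit.
    """
    scores = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0],
                           "y": [1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0]})
    labels = np.array([True, True, False, False, False, False, False])
    return roc_calibrate(scores, labels)


class TestIntegratedScore:
    def test_zero_channels_is_prior(self):
        calib = _hand_calibration()
        assert integrated_score({}, calib, o_prior=1.0).combined == 0.0
        assert integrated_score({}, calib, o_prior=4.0).combined == pytest.approx(2.0)

    def test_single_channel_one_bit(self):
        calib = _hand_calibration()
        s = integrated_score({"x": 0.5}, calib)
        assert s.combined == pytest.approx(1.0)
        assert s.n_channels == 1

    def test_additivity_over_channels(self):
        calib = _hand_calibration()
        sx = integrated_score({"x": 0.5}, calib).combined
        sy = integrated_score({"y": 0.5}, calib).combined
        sxy = integrated_score({"x": 0.5, "y": 0.5}, calib).combined
        assert sxy == pytest.approx(sx + sy)

    def test_hand_arithmetic_at_other_operating_points(self):
        calib = _hand_calibration()
        # threshold 1.0: TP=1, FP=1 -> same point; threshold below all
        # values: TP=2, FP=5 -> term log2((2.5/3)/(5.5/6))
        s_low = integrated_score({"x": -1.0}, calib).combined
        assert s_low == pytest.approx(np.log2((2.5 / 3) / (5.5 / 6)))

    def test_nan_channel_skipped_and_unknown_rejected(self):
        calib = _hand_calibration()
        s = integrated_score({"x": 0.5, "y": float("nan")}, calib)
        assert s.n_channels == 1
        with pytest.raises(ValueError, match="mystery"):
            integrated_score({"mystery": 1.0}, calib)

    def test_rank_invariant_to_prior(self):
        scores, labels = _bench(300, 300, {"a": 1.0, "b": 0.6}, seed=7)
        calib = roc_calibrate(scores, labels)
        df = scores.copy()
        df["variant_id"] = [f"v{i}" for i in range(len(df))]
        r1 = integrate_table(df, calib, o_prior=1.0)["impact_score"].rank()
        r9 = integrate_table(df, calib, o_prior=9.0)["impact_score"].rank()
        assert (r1 == r9).all()

    def test_integration_beats_single_channels(self):
        """Two independent informative channels integrate to a higher AUC."""
        scores, labels = _bench(800, 800, {"a": 0.8, "b": 0.8}, seed=8)
        calib = roc_calibrate(scores, labels)
        df = scores.copy()
        df["variant_id"] = [f"v{i}" for i in range(len(df))]
        combined = integrate_table(df, calib)["impact_score"]
        auc_comb = roc_auc_score(labels, combined)
        auc_a = roc_auc_score(labels, -scores["a"])
        auc_b = roc_auc_score(labels, -scores["b"])
        assert auc_comb >= max(auc_a, auc_b) - 0.01


class TestSelectThreshold:
    def test_separated_classes(self):
        res = select_threshold([5.0, 6.0, 1.0, 0.0], [True, True, False, False])
        assert res.attainable and res.fdr == 0.0 and res.fpr == 0.0
        assert 1.0 < res.threshold <= 5.0

    def test_loose_bounds_give_minimum_score(self):
        scores = [3.0, 1.0, 2.0]
        res = select_threshold(scores, [True, False, True], max_fdr=1.0, max_fpr=1.0)
        assert res.threshold == 1.0

    def test_unattainable_reported_not_raised(self):
        res = select_threshold([1.0, 1.0], [True, False],
                               max_fdr=0.01, max_fpr=0.01)
        assert not res.attainable and res.threshold is None

    def test_unlabelled_fraction_tracks_planted_rate(self):
        """The fraction of fresh variants called matches the damaging fraction."""
        effects = {c: 1.8 for c in ("a", "b", "c", "d")}
        scores, labels = _bench(2000, 2000, effects, seed=9)
        calib = roc_calibrate(scores, labels)
        df = scores.copy()
        df["variant_id"] = [f"v{i}" for i in range(len(df))]
        bench_scores = integrate_table(df, calib)["impact_score"]
        sel = select_threshold(bench_scores, labels, max_fdr=0.05, max_fpr=0.05)
        assert sel.attainable
        # an independent draw with 30% damaging
        fresh = simulate_benchmark(300, 700, effects, seed=10)
        fresh_scores = integrate_table(
            fresh.drop(columns=["label"]), calib)["impact_score"]
        frac = float((fresh_scores >= sel.threshold).mean())
        called_pos = float(
            (bench_scores[labels] >= sel.threshold).mean())  # benchmark TPR
        expected = 0.3 * called_pos + 0.7 * sel.fpr
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 1000) + 0.02


class TestEnrichmentCurves:
    def test_fractions_bounded_and_flat_when_independent(self):
        rng = np.random.default_rng(11)
        scored = pd.DataFrame({
            "impact_score": rng.normal(0, 1, 4000),
            "het": rng.integers(0, 300, 4000),
            "hom": rng.integers(0, 8, 4000),
        })
        by_het, by_hom = enrichment_curves(scored, impact_threshold=0.0)
        for df in (by_het, by_hom):
            ok = df["frac_impact"].dropna()
            assert ((ok >= 0) & (ok <= 1)).all()
        spread = by_hom["frac_impact"].dropna()
        assert spread.max() - spread.min() < 0.15

    def test_empty_bins_reported_as_missing(self):
        scored = pd.DataFrame({"impact_score": [1.0], "het": [50], "hom": [0]})
        by_het, by_hom = enrichment_curves(scored, impact_threshold=0.0)
        assert by_het["frac_impact"].isna().sum() > 0
        assert by_hom.loc[by_hom["hom"] == 5, "frac_impact"].isna().all()
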