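import numpy as np
import pytest

from oxiscreen.evaluate import (bland_altman, confusion_metrics,
                                confusion_metrics_from_counts,
                                evaluate_agreement, icc, mountain_plot,
                                roc_auc, severity_class)
from oracles import auc_mannwhitney, mountain_bruteforce


class TestICC:
    def test_perfect_agreement(self, rng):
        a = rng.uniform(0, 60, 30)
        val, ci = icc(a, a.copy())
        assert val == pytest.approx(1.0)
        assert ci[1] <= 1.0

    def test_matches_variance_components_closed_form(self, rng):
        a = rng.normal(30, 10, 1000)
        b = a + rng.normal(0, 5, 1000)
        val, _ = icc(a, b)
        # the rater-noise variance splits between the two columns:
        # ICC -> sigma_a^2 / (sigma_a^2 + sigma_e^2 / 2)
        expected = 10 ** 2 / (10 ** 2 + 5 ** 2 / 2)
        assert val == pytest.approx(expected, abs=0.05)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        a = rng.uniform(0, 60, 40)
        b = a * 0.9 + rng.normal(2, 6, 40)
        val, ci = icc(a, b, "agreement")
        df = pd.DataFrame({
            "target": np.repeat(np.arange(40), 2),
            "rater": np.tile(["A", "B"], 40),
            "score": np.column_stack([a, b]).ravel()})
        ref = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score").set_index("Type")
        assert val == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        # pingouin reports the CI rounded to 2 decimals
        np.testing.assert_allclose(ci, ref.loc["ICC(A,1)", "CI95"], atol=0.005)

    def test_matches_pingouin_consistency(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        a = rng.uniform(0, 60, 25)
        b = a + rng.normal(5, 4, 25)
        val, _ = icc(a, b, "consistency")
        df = pd.DataFrame({
            "target": np.repeat(np.arange(25), 2),
            "rater": np.tile(["A", "B"], 25),
            "score": np.column_stack([a, b]).ravel()})
        ref = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score").set_index("Type")
        assert val == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc(np.full(10, 5.0), np.full(10, 5.0))
        with pytest.raises(ValueError):
            icc(np.arange(2), np.arange(2))


class TestBlandAltman:
    def test_identical_series(self, rng):
        a = rng.uniform(0, 60, 20)
        bias, lo, hi, width = bland_altman(a, a)
        assert bias == 0 and width == 0

    def test_pure_offset(self, rng):
        a = rng.uniform(0, 60, 20)
        bias, lo, hi, width = bland_altman(a, a + 5)
        assert bias == pytest.approx(5.0)
        assert width == pytest.approx(0.0, abs=1e-9)

    def test_width_is_2x196_sd(self, rng):
        a = rng.uniform(0, 60, 500)
        d = rng.normal(0, 7, 500)
        bias, lo, hi, width = bland_altman(a, a + d)
        assert width == pytest.approx(2 * 1.96 * d.std(ddof=1))
        assert lo <= bias <= hi

    def test_swapping_flips_bias_sign(self, rng):
        a = rng.uniform(0, 60, 50)
        b = a + rng.normal(3, 2, 50)
        bias_ab, *_, w_ab = bland_altman(a, b)
        bias_ba, *_, w_ba = bland_altman(b, a)
        assert bias_ab == pytest.approx(-bias_ba)
        assert w_ab == pytest.approx(w_ba)


class TestMountain:
    def test_matches_folding_oracle(self, rng):
        d = rng.normal(1, 4, 20)
        pts = mountain_plot(d)
        oracle = mountain_bruteforce(d.tolist())
        for (x1, p1), (x2, p2) in zip(pts, oracle):
            assert x1 == pytest.approx(x2)
            assert p1 == pytest.approx(p2)

    def test_symmetric_peak_near_zero(self, rng):
        d = np.concatenate([rng.normal(0, 3, 500), -rng.normal(0, 3, 500)])
        pts = mountain_plot(d)
        peak_x = max(pts, key=lambda t: t[1])[0]
        assert abs(peak_x) < 0.6


class TestConfusion:
    def test_perfect_prediction_flags_lr_pos_na(self, rng):
        true = rng.uniform(0, 60, 40)
        rep = confusion_metrics(true, true, cutoff=15)
        assert rep.se == rep.sp == rep.acc == 100.0
        assert rep.lr_pos is None  # Sp = 100 % leaves LR+ undefined

    def test_hand_contingency_values(self):
        rep = confusion_metrics_from_counts(tp=79, fn=2, tn=17, fp=12)
        assert rep.se == pytest.approx(97.5, abs=0.05)
        assert rep.sp == pytest.approx(58.6, abs=0.05)
        assert rep.acc == pytest.approx(87.3, abs=0.05)
        assert rep.lr_pos == pytest.approx(2.36, abs=0.01)
        assert rep.lr_neg == pytest.approx(0.04, abs=0.01)

    def test_accuracy_weighted_identity(self, rng):
        pred = rng.uniform(0, 60, 200)
        true = rng.uniform(0, 60, 200)
        rep = confusion_metrics(pred, true, cutoff=30)
        n_pos = rep.tp + rep.fn
        n_neg = rep.tn + rep.fp
        acc = (rep.se * n_pos + rep.sp * n_neg) / (n_pos + n_neg)
        assert rep.acc == pytest.approx(acc)

    def test_positive_iff_at_or_above_cutoff(self):
        rep = confusion_metrics(np.array([15.0, 14.99]), np.array([15.0, 14.99]),
                                cutoff=15)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (1, 0, 1, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci, curve = roc_auc(np.array([1, 2, 3, 10, 11, 12]),
                                 np.array([0, 0, 0, 1, 1, 1]))
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(5):
            scores = np.round(rng.uniform(0, 10, 40), 1)  # force some ties
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            auc, _, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(
                auc_mannwhitney(scores.tolist(), labels.tolist()), abs=1e-10)

    def test_uninformative_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(1, 5, 100)
        labels = (scores + rng.normal(0, 1, 100)) > 3
        a1, _, _ = roc_auc(scores, labels)
        a2, _, _ = roc_auc(np.exp(scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5))


class TestSeverity:
    @pytest.mark.parametrize("ahi,expected", [
        (0.0, "normal"), (4.2, "normal"), (5.0, "mild"), (14.9, "mild"),
        (15.0, "moderate"), (29.9, "moderate"), (30.0, "severe"), (80.0, "severe"),
    ])
    def test_boundaries(self, ahi, expected):
        assert severity_class(ahi) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            severity_class(-1.0)


def test_evaluate_agreement_bundles_consistent_report(rng):
    ref = rng.uniform(0, 60, 60)
    est = np.clip(ref + rng.normal(1, 6, 60), 0, None)
    rep = evaluate_agreement(ref, est)
    assert rep.loa_low <= rep.bias <= rep.loa_high
    assert -1 <= rep.icc <= 1
    assert len(rep.mountain) == 60
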