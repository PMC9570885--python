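import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esngait.core_io import EventPredictions, EventTargets
from esngait.metrics import (
    OutcomeCounts,
    classify_outcomes,
    evaluate_detection,
    mae_per_series,
    mae_tp_only,
    match_errors,
    rates,
    remove_median_bias,
)


def brute_force_table(target_idx, pred_idx, T, fs, threshold_s):
    """Literal implementation of the outcome-classification table for one
    class and one timeseries: errors are target minus nearest prediction;
    TP if |error| <= threshold, FN otherwise, FP = #predictions - TP,
    TN = T - (TP + FP + FN)."""
    errors = []
    for t in target_idx:
        if len(pred_idx) == 0:
            errors.append(np.inf)
        else:
            errors.append(min(((t - p) / fs for p in pred_idx), key=abs))
    tp = sum(1 for e in errors if abs(e) <= threshold_s)
    fn = len(errors) - tp
    fp = len(pred_idx) - tp
    tn = T - (tp + fp + fn)
    return OutcomeCounts(TP=tp, FP=fp, FN=fn, TN=tn)


class TestMatchErrors:
    def test_sign_convention(self):
        tgt = EventTargets(["HS"], [np.array([100])], 400)
        prd = EventPredictions(["HS"], [np.array([102])], 100.0)
        err = match_errors(tgt, prd, 100.0)
        np.testing.assert_allclose(err["HS"], [-0.02])

    def test_nearest_rule(self):
        tgt = EventTargets(["HS"], [np.array([100, 200])], 400)
        prd = EventPredictions(["HS"], [np.array([100])], 100.0)
        err = match_errors(tgt, prd, 100.0)
        np.testing.assert_allclose(err["HS"], [0.0, 1.0])

    def test_no_predictions_inf_sentinels(self):
        tgt = EventTargets(["HS"], [np.array([5, 10])], 20)
        prd = EventPredictions(["HS"], [np.array([], dtype=np.int64)], 100.0)
        err = match_errors(tgt, prd, 100.0)
        assert np.all(np.isinf(err["HS"]))

    def test_prediction_only_class(self):
        tgt = EventTargets(["HS"], [np.array([5])], 20)
        prd = EventPredictions(["HS", "TO"], [np.array([5]), np.array([9])], 100.0)
        err = match_errors(tgt, prd, 100.0)
        assert err["TO"].size == 0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        fs = 200.0
        tgt_idx = np.sort(rng.choice(4000, 20, replace=False))
        prd_idx = np.sort(rng.choice(4000, 25, replace=False))
        tgt = EventTargets(["HS"], [tgt_idx], 4000)
        prd = EventPredictions(["HS"], [prd_idx], fs)
        got = match_errors(tgt, prd, fs)["HS"]
        for e, t in zip(got, tgt_idx):
            expect = min(((t - p) / fs for p in prd_idx), key=abs)
            assert e == pytest.approx(expect, abs=1e-12)


class TestRemoveMedianBias:
    def test_simple_centering(self):
        errs = [{"HS": np.array([0.010, 0.020, 0.030])}]
        centered, bias = remove_median_bias(errs)
        np.testing.assert_allclose(centered[0]["HS"], [-0.010, 0.0, 0.010])
        assert bias["HS"] == pytest.approx(0.020)

    def test_symmetric_unchanged(self):
        errs = [{"HS": np.array([-0.01, 0.0, 0.01])}]
        centered, bias = remove_median_bias(errs)
        assert bias["HS"] == 0.0
        np.testing.assert_array_equal(centered[0]["HS"], errs[0]["HS"])

    def test_pooled_median_across_series(self):
        # two series each biased +50 ms: pooled median removes the shared bias
        e1 = {"HS": 0.050 + np.array([-0.002, 0.0, 0.002])}
        e2 = {"HS": 0.050 + np.array([-0.001, 0.0, 0.001])}
        centered, bias = remove_median_bias([e1, e2])
        pooled = np.concatenate([e1["HS"], e2["HS"]])
        assert bias["HS"] == pytest.approx(np.median(pooled))
        for c in centered:
            assert abs(np.median(c["HS"])) < 0.003

    def test_inf_untouched(self):
        errs = [{"HS": np.array([0.01, np.inf, 0.03])}]
        centered, _ = remove_median_bias(errs)
        assert np.isinf(centered[0]["HS"][1])


class TestClassifyOutcomes:
    def test_worked_example(self):
        # targets [100, 300], preds [105, 600] at 200 Hz, threshold 65 ms:
        # errors -25 ms (TP) and -1500 ms (FN); FP = 2 - 1 = 1
        fs, T = 200.0, 4000
        tgt = EventTargets(["HS"], [np.array([100, 300])], T)
        prd = EventPredictions(["HS"], [np.array([105, 600])], fs)
        err = match_errors(tgt, prd, fs)["HS"]
        counts = classify_outcomes([err], n_predictions=2, total_samples=T)
        assert (counts.TP, counts.FP, counts.FN) == (1, 1, 1)
        assert counts.TN == T - 3

    def test_perfect_predictions(self):
        err = [np.zeros(7)]
        counts = classify_outcomes(err, n_predictions=7, total_samples=1000)
        assert (counts.TP, counts.FP, counts.FN) == (7, 0, 0)

    def test_zero_predictions(self):
        err = [np.full(4, np.inf)]
        counts = classify_outcomes(err, n_predictions=0, total_samples=100)
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 4)

    def test_matches_bruteforce_table(self):
        # randomized instances against a literal table implementation
        rng = np.random.default_rng(7)
        fs, threshold = 200.0, 0.065
        for _ in range(200):
            T = int(rng.integers(500, 3000))
            nt = int(rng.integers(0, 12))
            npred = int(rng.integers(0, 12))
            tgt_idx = np.sort(rng.choice(T, nt, replace=False))
            prd_idx = np.sort(rng.choice(T, npred, replace=False))
            tgt = EventTargets(["HS"], [tgt_idx], T)
            prd = EventPredictions(["HS"], [prd_idx], fs)
            err = match_errors(tgt, prd, fs)["HS"]
            got = classify_outcomes([err], npred, T, threshold)
            expect = brute_force_table(tgt_idx, prd_idx, T, fs, threshold)
            assert got == expect
            # conservation laws
            assert got.TP + got.FN == nt
            assert got.FP == npred - got.TP
            assert got.TP + got.FP + got.FN + got.TN == T

    def test_threshold_boundary_inclusive(self):
        err = [np.array([0.065])]
        counts = classify_outcomes([np.array([0.065])], 1, 100)
        assert counts.TP == 1


class TestRates:
    def test_symmetric_example(self):
        r = rates(OutcomeCounts(TP=9, FP=1, FN=1, TN=100))
        assert r["TPR"] == pytest.approx(0.9)
        assert r["PPV"] == pytest.approx(0.9)
        assert r["T1"] == pytest.approx(0.9)

    def test_harmonic_mean_closed_form(self):
        r = rates(OutcomeCounts(TP=1, FP=0, FN=1, TN=10))
        assert r["TPR"] == pytest.approx(0.5)
        assert r["PPV"] == pytest.approx(1.0)
        assert r["T1"] == pytest.approx(2 / 3)

    def test_degenerate_zero(self):
        r = rates(OutcomeCounts(TP=0, FP=0, FN=0, TN=10))
        assert r["T1"] == 0.0

    def test_printed_variant_swaps_denominators(self):
        c = OutcomeCounts(TP=8, FP=2, FN=4, TN=100)
        std = rates(c)
        alt = rates(c, printed_variant=True)
        assert std["TPR"] == alt["PPV"] and std["PPV"] == alt["TPR"]

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 1000))
    def test_harmonic_mean_inequality_and_bounds(self, tp, fp, fn, tn):
        r = rates(OutcomeCounts(TP=tp, FP=fp, FN=fn, TN=tn))
        for v in r.values():
            assert 0.0 <= v <= 1.0
        assert r["T1"] <= (r["TPR"] + r["PPV"]) / 2 + 1e-12


class TestMAE:
    def test_simple_mean_abs(self):
        mae, _ = mae_per_series([np.array([-0.010, 0.0, 0.010])])
        assert mae[0] == pytest.approx(0.02 / 3)

    def test_all_zero(self):
        mae, _ = mae_per_series([np.zeros(5)])
        assert mae[0] == 0.0

    def test_random_equals_direct(self):
        rng = np.random.default_rng(1)
        vecs = [rng.normal(size=100) for _ in range(4)]
        mae, summary = mae_per_series(vecs)
        for k, v in enumerate(vecs):
            assert mae[k] == pytest.approx(np.mean(np.abs(v)))
        vals = np.array(list(mae.values()))
        assert summary["median"] == pytest.approx(np.median(vals))

    def test_series_without_finite_errors_skipped(self):
        mae, _ = mae_per_series([np.array([np.inf]), np.array([0.01])])
        assert 0 not in mae and 1 in mae

    def test_tp_only_filter(self):
        mean, _ = mae_tp_only(np.array([0.010, 0.030, 0.090]))
        assert mean == pytest.approx(0.020)

    def test_tp_only_all_above_threshold(self):
        with pytest.raises(ValueError, match="no errors"):
            mae_tp_only(np.array([0.5, 0.9]))

    def test_tp_only_random_oracle(self):
        rng = np.random.default_rng(2)
        errs = rng.normal(scale=0.05, size=200)
        mean, sd = mae_tp_only(errs, 0.040)
        kept = np.abs(errs[np.abs(errs) <= 0.040])
        assert mean == pytest.approx(kept.mean())
        assert sd == pytest.approx(kept.std())


class TestEvaluateDetection:
    def test_shift_invariance_of_tp_count(self):
        # a uniform bias across all predictions does not change the TP set
        # once the median bias is removed
        fs = 200.0
        tgt_idx = np.arange(100, 4100, 200)  # 20 well-separated events
        tgt = EventTargets(["HS"], [tgt_idx], 6000)
        base = EventPredictions(["HS"], [tgt_idx], fs)
        shifted = EventPredictions(["HS"], [tgt_idx + 30], fs)
        r1 = evaluate_detection([tgt], [base], fs)
        r2 = evaluate_detection([tgt], [shifted], fs)
        assert r1.counts["HS"].TP == r2.counts["HS"].TP == 20
        assert r2.median_bias_s["HS"] == pytest.approx(-30 / fs)

    def test_report_structure(self):
        fs = 100.0
        tgt = EventTargets(["HS", "TO"],
                           [np.array([100, 300]), np.array([150, 350])], 500)
        prd = EventPredictions(["HS", "TO"],
                               [np.array([101, 301]), np.array([152])], fs)
        rep = evaluate_detection([tgt], [prd], fs)
        assert set(rep.classes) == {"HS", "TO"}
        assert rep.counts["HS"].TP == 2
        assert rep.total_samples == 500
        assert 0.0 <= rep.rates["TO"]["T1"] <= 1.0

    def test_length_mismatch(self):
        tgt = EventTargets(["HS"], [np.array([1])], 10)
        with pytest.raises(ValueError):
            evaluate_detection([tgt], [], 100.0)
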