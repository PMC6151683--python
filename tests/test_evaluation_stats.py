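import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from retino_entropy import evaluation_stats as es
from retino_entropy.cnn_referable import PredictionSet
from .conftest import auc_bruteforce


def _preds(calls, scores=None, prefix="i"):
    calls = np.asarray(calls, dtype=np.int64)
    scores = np.asarray(scores, dtype=float) if scores is not None \
        else calls.astype(float)
    ids = [f"{prefix}{k}" for k in range(len(calls))]
    return PredictionSet(ids=ids, scores=scores, calls=calls)


class TestConfusion:
    def test_all_correct(self):
        truth = {f"i{k}": int(k < 10) for k in range(20)}
        preds = _preds([int(k < 10) for k in range(20)])
        c = es.confusion(preds, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_flipped_calls_swap_counts(self):
        truth = {f"i{k}": int(k < 7) for k in range(20)}
        calls = [int(k < 7) for k in range(20)]
        c = es.confusion(_preds(calls), truth)
        cf = es.confusion(_preds([1 - v for v in calls]), truth)
        assert (cf.tp, cf.fn) == (c.fn, c.tp)
        assert (cf.tn, cf.fp) == (c.fp, c.tn)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.confusion(PredictionSet(ids=[], scores=np.empty(0),
                                       calls=np.empty(0, dtype=int)), {})

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            es.confusion(_preds([1]), {"other": 1})


class TestMetrics:
    def test_worked_example_accuracy_8610(self):
        """2,583 correct of 3,000 is exactly 86.10% accuracy."""
        c = es.ConfusionCounts(tp=1099, tn=1484, fp=96, fn=321)
        m = es.metrics(c)
        assert c.total == 3000
        assert m["accuracy"] * 100 == pytest.approx(86.10, abs=1e-9)

    def test_perfect_classifier(self):
        m = es.metrics(es.ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_all_negative_calls(self):
        m = es.metrics(es.ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["accuracy"] == 0.5

    def test_undefined_flagged_not_crash(self):
        m = es.metrics(es.ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert m["sensitivity"] is None
        assert m["specificity"] == 0.5


class TestRocAuc:
    def test_perfect_separation(self):
        r = es.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r["auc"] == 1.0

    def test_all_ties(self):
        r = es.roc_auc([0.5] * 8, [1, 0] * 4)
        assert r["auc"] == 0.5

    def test_enumerated_four_pair_example(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        truth = [1, 1, 0, 0]
        expected = auc_bruteforce(scores, truth)  # 3 of 4 pairs concordant
        assert expected == 0.75
        assert es.roc_auc(scores, truth)["auc"] == pytest.approx(expected)

    def test_matches_bruteforce_on_random_inputs(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 100))
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert es.roc_auc(scores, truth)["auc"] == pytest.approx(
                auc_bruteforce(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            es.roc_auc([0.1, 0.9], [1, 1])

    def test_curve_monotone(self, rng):
        truth = rng.integers(0, 2, 50)
        truth[:2] = [0, 1]
        r = es.roc_auc(rng.random(50), truth)
        assert (np.diff(r["fpr"]) >= 0).all()
        assert (np.diff(r["tpr"]) >= 0).all()


def _paired(truth, calls_a, calls_b):
    n = len(truth)
    return es.PairedOutcomes(ids=[f"i{k}" for k in range(n)],
                             truth=np.asarray(truth),
                             calls_a=np.asarray(calls_a),
                             calls_b=np.asarray(calls_b))


class TestMcnemar:
    def _from_bc(self, b, c, extra_concordant=5):
        """Build truth-positive outcomes with given discordant counts."""
        truth, ca, cb = [], [], []
        for _ in range(b):      # A right, B wrong
            truth.append(1); ca.append(1); cb.append(0)
        for _ in range(c):      # A wrong, B right
            truth.append(1); ca.append(0); cb.append(1)
        for _ in range(extra_concordant):
            truth.append(1); ca.append(1); cb.append(1)
        return _paired(truth, ca, cb)

    def test_corrected_chi_square_at_b_equals_c_15(self):
        out = es.mcnemar(self._from_bc(15, 15), "sensitivity")
        assert out["statistic"] == pytest.approx(1 / 30)
        assert out["p_value"] == pytest.approx(0.855, abs=5e-3)

    def test_exact_branch_one_sided_discordance(self):
        out = es.mcnemar(self._from_bc(10, 0), "sensitivity")
        assert out["method"] == "exact binomial"
        assert out["p_value"] == pytest.approx(2 * 0.5 ** 10)

    def test_no_discordance_p_one(self):
        out = es.mcnemar(self._from_bc(0, 0), "sensitivity")
        assert out["p_value"] == 1.0

    def test_exact_branch_matches_statsmodels(self):
        for b, c in [(3, 8), (0, 5), (12, 10)]:
            out = es.mcnemar(self._from_bc(b, c), "sensitivity")
            table = [[1, b], [c, 1]]
            ref = sm_mcnemar(table, exact=True)
            assert out["p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_branches_agree_near_switchover(self):
        """Exact and corrected-asymptotic p-values agree closely for
        moderately asymmetric discordance around the branch threshold."""
        for b, c in [(18, 8), (20, 10), (9, 17), (21, 7), (16, 10)]:
            exact = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
            asymp = float(stats.chi2.sf((abs(b - c) - 1) ** 2 / (b + c), 1))
            assert abs(exact - asymp) < 0.02

    def test_specificity_subset_uses_truth_negatives(self):
        # truth-negative stratum: A right on 4/B wrong, plus concordant
        truth = [0] * 6 + [1] * 3
        ca = [0, 0, 0, 0, 0, 0, 1, 1, 1]
        cb = [1, 1, 1, 1, 0, 0, 1, 1, 1]
        out = es.mcnemar(_paired(truth, ca, cb), "specificity")
        assert (out["b"], out["c"]) == (4, 0)


class TestChisqAccuracy:
    def test_identical_proportions(self):
        c = es.ConfusionCounts(tp=30, tn=30, fp=20, fn=20)
        out = es.chisq_accuracy(c, c)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_screening_scale_difference_significant(self):
        """81.80% vs 86.10% correct of 3,000 each is significant far below
        the 0.001 level."""
        c_a = es.ConfusionCounts(tp=1000, tn=1454, fp=300, fn=246)  # 2454
        c_b = es.ConfusionCounts(tp=1099, tn=1484, fp=96, fn=321)   # 2583
        out = es.chisq_accuracy(c_a, c_b)
        assert out["p_value"] < 0.001

    def test_hand_computed_pearson(self):
        # table [[8,2],[4,6]]: expected from margins, sum (O-E)^2/E
        c_a = es.ConfusionCounts(tp=8, tn=0, fp=0, fn=2)
        c_b = es.ConfusionCounts(tp=4, tn=0, fp=0, fn=6)
        table = np.array([[8.0, 2.0], [4.0, 6.0]])
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        hand = ((table - expected) ** 2 / expected).sum()
        out = es.chisq_accuracy(c_a, c_b)
        assert out["statistic"] == pytest.approx(hand)

    def test_doubling_cells_doubles_statistic(self):
        c_a = es.ConfusionCounts(tp=40, tn=0, fp=0, fn=10)
        c_b = es.ConfusionCounts(tp=30, tn=0, fp=0, fn=20)
        c_a2 = es.ConfusionCounts(tp=80, tn=0, fp=0, fn=20)
        c_b2 = es.ConfusionCounts(tp=60, tn=0, fp=0, fn=40)
        s1 = es.chisq_accuracy(c_a, c_b)["statistic"]
        s2 = es.chisq_accuracy(c_a2, c_b2)["statistic"]
        assert s2 == pytest.approx(2 * s1)


class TestAucCompare:
    def _simulated_scores(self, seed, n_pos=20, n_neg=20, shift_b=0.0):
        rng = np.random.default_rng(seed)
        truth = np.array([1] * n_pos + [0] * n_neg)
        a = np.where(truth == 1, rng.normal(0.8, 0.5, truth.shape),
                     rng.normal(0.0, 0.5, truth.shape))
        b = np.where(truth == 1, rng.normal(0.8 + shift_b, 0.5, truth.shape),
                     rng.normal(0.0, 0.5, truth.shape))
        return a, b, truth

    def test_identical_scores_p_one(self):
        a, _, truth = self._simulated_scores(0)
        out = es.delong_paired(a, a, truth)
        assert out["difference"] == 0.0
        assert out["p_value"] == 1.0

    def test_symmetry_under_swap(self):
        a, b, truth = self._simulated_scores(1)
        pab = es.delong_paired(a, b, truth)
        pba = es.delong_paired(b, a, truth)
        assert pab["p_value"] == pytest.approx(pba["p_value"])
        assert pab["difference"] == pytest.approx(-pba["difference"])

    def test_matches_reference_implementation(self):
        """Frozen regression value computed with pROC's paired DeLong test
        (roc.test, method="delong") on the identical 40 paired scores."""
        a, b, truth = self._simulated_scores(7, shift_b=-0.35)
        out = es.delong_paired(a, b, truth)
        assert out["auc_a"] == pytest.approx(0.875)
        assert out["auc_b"] == pytest.approx(0.76)
        assert out["p_value"] == pytest.approx(0.1661438, abs=1e-6)

    def test_agrees_with_permutation_oracle(self):
        """DeLong p on 40 paired scores tracks a paired sign-flip
        permutation of the AUC difference: the asymptotic and exact answers
        agree to about 0.02 at this sample size."""
        rng = np.random.default_rng(0)
        n_rep = 2000
        gaps = []
        for seed in (1, 4, 7):
            a, b, truth = self._simulated_scores(seed, shift_b=-0.35)
            observed = abs(es.roc_auc(a, truth)["auc"]
                           - es.roc_auc(b, truth)["auc"])
            count = 0
            for _ in range(n_rep):
                swap = rng.random(len(truth)) < 0.5
                pa = np.where(swap, b, a)
                pb = np.where(swap, a, b)
                d = abs(es.roc_auc(pa, truth)["auc"]
                        - es.roc_auc(pb, truth)["auc"])
                count += d >= observed - 1e-12
            perm_p = count / n_rep
            delong_p = es.delong_paired(a, b, truth)["p_value"]
            gaps.append(abs(delong_p - perm_p))
        assert sorted(gaps)[len(gaps) // 2] < 0.02  # median agreement
        assert max(gaps) < 0.045                    # worst-case asymptotics

    def test_bootstrap_route_available(self):
        a, b, truth = self._simulated_scores(3)
        out = es.auc_compare(a, b, truth, method="bootstrap", seed=5)
        assert 0.0 < out["p_value"] <= 1.0
        again = es.auc_compare(a, b, truth, method="bootstrap", seed=5)
        assert out["p_value"] == again["p_value"]

    def test_type_one_error_rates(self):
        """With two identical stochastic classifiers, each paired test
        rejects at about the nominal 5% level across 200 replicates."""
        rng = np.random.default_rng(2024)
        n = 200
        rejects = {"chisq": 0, "mcn_sens": 0, "mcn_spec": 0, "delong": 0}
        n_rep = 200
        for _ in range(n_rep):
            truth = np.array([1] * (n // 2) + [0] * (n // 2))
            err_a = rng.random(n) < 0.2
            err_b = rng.random(n) < 0.2
            calls_a = np.where(err_a, 1 - truth, truth)
            calls_b = np.where(err_b, 1 - truth, truth)
            paired = _paired(truth, calls_a, calls_b)
            sa = np.clip(calls_a + rng.normal(0, 0.2, n), 0, 1)
            sb = np.clip(calls_b + rng.normal(0, 0.2, n), 0, 1)
            c_a = es.ConfusionCounts(
                tp=int(((calls_a == 1) & (truth == 1)).sum()),
                tn=int(((calls_a == 0) & (truth == 0)).sum()),
                fp=int(((calls_a == 1) & (truth == 0)).sum()),
                fn=int(((calls_a == 0) & (truth == 1)).sum()))
            c_b = es.ConfusionCounts(
                tp=int(((calls_b == 1) & (truth == 1)).sum()),
                tn=int(((calls_b == 0) & (truth == 0)).sum()),
                fp=int(((calls_b == 1) & (truth == 0)).sum()),
                fn=int(((calls_b == 0) & (truth == 1)).sum()))
            rejects["chisq"] += es.chisq_accuracy(c_a, c_b)["p_value"] < 0.05
            rejects["mcn_sens"] += es.mcnemar(paired, "sensitivity")[
                "p_value"] < 0.05
            rejects["mcn_spec"] += es.mcnemar(paired, "specificity")[
                "p_value"] < 0.05
            rejects["delong"] += es.delong_paired(sa, sb, truth)[
                "p_value"] < 0.05
        for name, k in rejects.items():
            rate = k / n_rep
            assert 0.0 <= rate <= 0.105, f"{name} rejected at {rate}"
        # the uncorrected tests should not be grossly conservative either
        assert rejects["chisq"] / n_rep >= 0.005
        assert rejects["delong"] / n_rep >= 0.005


class TestReport:
    def _run(self, seed, flip=0):
        rng = np.random.default_rng(seed)
        n = 40
        truth = {f"i{k}": k % 2 for k in range(n)}
        calls = np.array([k % 2 for k in range(n)])
        noisy = np.where(rng.random(n) < 0.2, 1 - calls, calls)
        scores = np.clip(noisy + rng.normal(0, 0.1, n), 0, 1)
        return _preds(noisy, scores), truth

    def test_identical_runs_all_p_one(self):
        preds, truth = self._run(0)
        rep = es.report(preds, preds, truth)
        assert rep.p_accuracy == 1.0
        assert rep.p_sensitivity == 1.0
        assert rep.p_specificity == 1.0
        assert rep.p_auc == 1.0
        assert rep.metrics_a == rep.metrics_b

    def test_frame_layout(self):
        preds_a, truth = self._run(1)
        preds_b, _ = self._run(2)
        rep = es.report(preds_a, preds_b, truth)
        frame = rep.to_frame()
        assert list(frame["metric"]) == ["accuracy", "sensitivity",
                                         "specificity", "auc"]
        assert {"original", "entropy", "p_value"} <= set(frame.columns)

    def test_round_trip_preserves_values(self, tmp_path):
        import json
        import pandas as pd
        preds_a, truth = self._run(3)
        preds_b, _ = self._run(4)
        rep = es.report(preds_a, preds_b, truth)
        rep.save(tmp_path / "r.csv", tmp_path / "r.json")
        frame = pd.read_csv(tmp_path / "r.csv")
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["auc_a"] == rep.auc_a
        assert frame.loc[0, "p_value"] == pytest.approx(rep.p_accuracy)

    def test_mismatched_test_sets_rejected(self):
        preds_a, truth = self._run(5)
        other = _preds([0, 1], prefix="zz")
        with pytest.raises(ValueError, match="same test set"):
            es.report(preds_a, other, truth)
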