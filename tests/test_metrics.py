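import numpy as np
import pytest
from scipy import stats

import dwfuse as dw
from dwfuse.metrics_eval import (ConfusionMatrix, auc_rank, confusion,
                                 delong_test, fold_ci, metric_suite,
                                 univariable_report)

# pooled cross-validation counts of the fused model and the logistic
# baseline: 180/231 sensitive and 67/91 resistant stratified correctly
# (fusion); 136/231 sensitive (baseline)
DWF_POOLED = ConfusionMatrix(tp=67, fn=24, tn=180, fp=51)
LR_POOLED = ConfusionMatrix(tp=67, fn=24, tn=136, fp=95)


class TestConfusion:
    def test_mixed_example(self):
        cm = confusion(np.array([1, 1, 0, 0]), np.array([1, 0, 0, 1]))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        cm = confusion(y, y)
        assert cm.fn == 0 and cm.fp == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 0]), np.array([1]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 2]), np.array([1, 0]))

    def test_pooled_matrix_is_sum_of_fold_matrices(self):
        rng = np.random.default_rng(0)
        y = (rng.random(60) < 0.4).astype(int)
        pred = (rng.random(60) < 0.5).astype(int)
        folds = np.repeat([0, 1, 2], 20)
        total = confusion(y, pred)
        parts = [confusion(y[folds == f], pred[folds == f]) for f in range(3)]
        pooled = parts[0] + parts[1] + parts[2]
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == \
            (total.tp, total.fp, total.tn, total.fn)


class TestMetricSuite:
    def test_fused_model_pooled_counts(self):
        m = metric_suite(DWF_POOLED)
        assert m["sensitivity"] == pytest.approx(0.736, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.767, abs=5e-4)
        # 180/231 = 0.77922...: 0.779 at 3 d.p.
        assert m["specificity"] == pytest.approx(0.779, abs=5e-4)

    def test_baseline_specificity(self):
        m = metric_suite(LR_POOLED)
        assert m["specificity"] == pytest.approx(0.589, abs=5e-4)

    def test_gmean_identity(self):
        m = metric_suite(DWF_POOLED)
        assert m["gmean"] == pytest.approx(
            np.sqrt(m["sensitivity"] * m["specificity"]), abs=1e-12)

    def test_zero_denominator_flagged_not_fatal(self):
        m = metric_suite(ConfusionMatrix(tp=0, fn=0, tn=5, fp=3))
        assert np.isnan(m["sensitivity"])
        assert "sensitivity" in m["undefined"]

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(1)
        y = (rng.random(40) < 0.5).astype(int)
        pred = (rng.random(40) < 0.5).astype(int)
        perm = rng.permutation(40)
        assert metric_suite(confusion(y, pred)) == \
            metric_suite(confusion(y[perm], pred[perm]))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc_rank(np.array([0.9, 0.8, 0.1]),
                        np.array([1, 1, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc_rank(np.ones(10), np.array([1] * 4 + [0] * 6)) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(20), 1)   # induce some ties
        labels = (rng.random(20) < 0.4).astype(int)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        concordant = sum((p > n) for p in pos for n in neg)
        ties = sum((p == n) for p in pos for n in neg)
        oracle = (concordant + 0.5 * ties) / (len(pos) * len(neg))
        assert auc_rank(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        a = auc_rank(scores, labels)
        b = auc_rank(np.exp(5 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLong:
    def test_identical_scores_give_null(self):
        rng = np.random.default_rng(4)
        s = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        delta, var, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(40), rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        d_ab, v_ab, p_ab = delong_test(a, b, y)
        d_ba, v_ba, p_ba = delong_test(b, a, y)
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_variance_matches_longhand_structural_components(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(30), rng.random(30)
        y = np.array([1] * 12 + [0] * 18)
        delta, var, _ = delong_test(a, b, y)

        # longhand placement values
        def v10(s):
            pos, neg = s[y == 1], s[y == 0]
            return np.array([np.mean((neg < x) + 0.5 * (neg == x))
                             for x in pos])

        def v01(s):
            pos, neg = s[y == 1], s[y == 0]
            return np.array([np.mean((pos > x) + 0.5 * (pos == x))
                             for x in neg])

        def cov(u, v):
            return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

        xa, xb = v10(a), v10(b)
        ya, yb = v01(a), v01(b)
        var_ref = ((cov(xa, xa) + cov(xb, xb) - 2 * cov(xa, xb)) / 12
                   + (cov(ya, ya) + cov(yb, yb) - 2 * cov(ya, yb)) / 18)
        assert var == pytest.approx(var_ref, abs=1e-12)
        assert delta == pytest.approx(auc_rank(a, y) - auc_rank(b, y),
                                      abs=1e-12)


class TestFoldCI:
    def test_constant_folds_zero_width(self):
        mean, lo, hi = fold_ci(np.full(5, 0.7))
        assert mean == lo == hi == 0.7

    def test_two_fold_longhand(self):
        mean, lo, hi = fold_ci(np.array([0.7, 0.8]))
        t = stats.t.ppf(0.975, 1)
        half = t * np.std([0.7, 0.8], ddof=1) / np.sqrt(2)
        assert mean == pytest.approx(0.75)
        assert lo == pytest.approx(max(0.75 - half, 0.0), abs=1e-12)
        assert hi == pytest.approx(min(0.75 + half, 1.0), abs=1e-12)

    def test_truncated_to_unit_interval(self):
        _, lo, hi = fold_ci(np.array([0.95, 0.99, 0.97]))
        assert hi <= 1.0 and lo >= 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            fold_ci(np.array([0.5]))


class TestUnivariable:
    def test_null_feature_or_ci_covers_one(self):
        # type-I behaviour: for an outcome-independent feature the Wald CI
        # should cover OR = 1 in about 95% of replicates
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(size=(120, 1))
            y = (rng.random(120) < 0.4).astype(int)
            row = univariable_report(x, y, ["f"]).iloc[0]
            if row["or_low"] <= 1.0 <= row["or_high"]:
                covered += 1
        assert covered >= 0.90 * n_rep

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        row = univariable_report(x, y, ["f"]).iloc[0]
        assert not row["converged"]

    def test_rescaling_halves_beta(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=120)
        y = (rng.random(120) < 1 / (1 + np.exp(-x))).astype(int)
        r1 = univariable_report(x[:, None], y, ["f"]).iloc[0]
        r2 = univariable_report(2 * x[:, None], y, ["f"]).iloc[0]
        beta1, beta2 = np.log(r1["or"]), np.log(r2["or"])
        assert beta2 == pytest.approx(beta1 / 2, rel=1e-4)
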