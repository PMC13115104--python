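import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dwfuse as dw
from dwfuse.dwf_core import (CellResult, combined_score, fuse,
                             make_outer_folds, optimize_threshold,
                             select_top, softmax_weights)
from dwfuse.metrics_eval import gmean_score


class TestOuterFolds:
    def test_study_size_split_counts(self):
        # 322 patients, 91 positive, 5 folds -> validation folds of 64-65
        # patients carrying 18-19 positives each
        y = np.array([1] * 91 + [0] * 231)
        assignment = make_outer_folds(y, 5, seed=0)
        for fold in range(5):
            rows = assignment == fold
            assert rows.sum() in (64, 65)
            assert y[rows].sum() in (18, 19)

    def test_two_by_two(self):
        y = np.array([0, 0, 1, 1])
        assignment = make_outer_folds(y, 2, seed=1)
        for fold in (0, 1):
            assert y[assignment == fold].tolist().count(1) == 1

    def test_same_seed_identical(self):
        y = np.array([0, 1] * 20)
        np.testing.assert_array_equal(make_outer_folds(y, 4, seed=7),
                                      make_outer_folds(y, 4, seed=7))

    def test_class_too_small_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="stratify"):
            make_outer_folds(y, 5, seed=0)


class TestCombinedScore:
    @pytest.mark.parametrize("auc,gmean,expected", [
        (1.0, 1.0, 1.0),
        (0.5, 0.0, 0.30),
        (0.760, 0.757, 0.7588),
    ])
    def test_weighted_sum(self, auc, gmean, expected):
        assert combined_score(auc, gmean) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combined_score(1.2, 0.5)


class TestSoftmaxWeights:
    def test_equal_scores_give_uniform_weights(self):
        w = softmax_weights(np.full(10, 0.75))
        np.testing.assert_allclose(w, 0.1, atol=1e-15)

    def test_two_score_closed_form(self):
        # cs = [0.8, 0.7], T = 0.1: omega_1 = 1/(1+e^-1)
        w = softmax_weights(np.array([0.8, 0.7]), 0.1)
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=5e-6)
        assert w[0] == pytest.approx(0.73106, abs=1e-5)
        assert w[1] == pytest.approx(0.26894, abs=1e-5)

    def test_low_temperature_limit_is_argmax(self):
        cs = np.array([0.70, 0.72, 0.71])
        w = softmax_weights(cs, 1e-4)
        assert w[1] == pytest.approx(1.0, abs=1e-12)

    def test_high_temperature_limit_is_uniform(self):
        cs = np.array([0.1, 0.9, 0.5])
        w = softmax_weights(cs, 1e4)
        np.testing.assert_allclose(w, 1 / 3, atol=1e-4)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.floats(0.01, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_and_monotonicity(self, cs, temp):
        cs = np.array(cs)
        w = softmax_weights(cs, temp)
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w > 0).all()
        order_cs = np.argsort(cs, kind="stable")
        assert (np.diff(w[order_cs]) >= -1e-15).all()

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmax_weights(np.array([0.5]), 0.0)


class TestFuse:
    def test_identical_vectors_unchanged(self):
        P = np.tile(np.linspace(0, 1, 7), (10, 1))
        w = softmax_weights(np.random.default_rng(0).random(10))
        np.testing.assert_allclose(fuse(P, w), P[0], atol=1e-12)

    def test_degenerate_weight_selects_one_learner(self):
        P = np.random.default_rng(1).random((3, 5))
        w = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(fuse(P, w), P[1])

    def test_matches_longhand_loop(self):
        rng = np.random.default_rng(2)
        P = rng.random((10, 20))
        w = softmax_weights(rng.random(10))
        expected = np.zeros(20)
        for i in range(10):
            for j in range(20):
                expected[j] += w[i] * P[i, j]
        np.testing.assert_allclose(fuse(P, w), expected, atol=1e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(3)
        P = rng.random((6, 30))
        w = softmax_weights(rng.random(6), 0.5)
        out = fuse(P, w)
        assert (out >= P.min(axis=0) - 1e-12).all()
        assert (out <= P.max(axis=0) + 1e-12).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.ones((2, 4)), np.array([1.0]))


class TestThreshold:
    def test_perfect_separation_reaches_gmean_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        theta = optimize_threshold(scores, labels)
        pred = (scores > theta).astype(int)
        assert gmean_score(labels, pred) == 1.0
        assert 0.0 < theta < 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.35).astype(int)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        theta = optimize_threshold(scores, labels)
        g_opt = gmean_score(labels, (scores > theta).astype(int))
        grid = np.linspace(0.0, 1.0, 1001)
        g_grid = max(gmean_score(labels, (scores > t).astype(int))
                     for t in grid)
        assert g_opt >= g_grid - 1e-12

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


def _cell(s, l, gmean, auc):
    return CellResult(s, l, np.arange(3), None, auc, gmean)


class TestSelectTop:
    def test_largest_gmeans_kept(self):
        cells = [_cell("S", str(i), g, 0.5)
                 for i, g in enumerate(np.linspace(0.1, 0.9, 12))]
        top = select_top(cells, 10)
        assert len(top) == 10
        assert top[0].gmean == pytest.approx(0.9)
        assert min(c.gmean for c in top) > 0.1

    def test_gmean_tie_broken_by_auc(self):
        cells = [_cell("A", "x", 0.7, 0.65), _cell("B", "y", 0.7, 0.70)]
        top = select_top(cells, 1)
        assert top[0].selector_id == "B"

    def test_short_grid_returns_everything(self):
        cells = [_cell("A", str(i), 0.5 + 0.01 * i, 0.6) for i in range(4)]
        assert len(select_top(cells, 10)) == 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_top([], 10)


class TestGridStructure:
    def test_full_roster_enumerates_168_cells(self):
        assert len(dw.grid_cells()) == 168

    def test_restricted_roster(self):
        cfg = dw.RunConfig(selectors=["T_score", "Fisher"],
                           learners=["LR", "DT", "KNN"])
        assert len(dw.grid_cells(cfg)) == 6


@pytest.fixture(scope="module")
def fitted_small(small_cohort):
    cfg = dw.RunConfig(selectors=["T_score", "Fisher"],
                       learners=["LR", "DT"], search_iterations=3, seed=21)
    return dw.fit_dwf(small_cohort, cfg=cfg), small_cohort


class TestFitDWF:
    def test_pooled_predictions_cover_cohort(self, fitted_small):
        model, table = fitted_small
        assert len(model.pooled_scores) == table.n_patients
        assert not np.isnan(model.pooled_scores).any()

    def test_degenerate_grid_weights_span_four_cells(self, fitted_small):
        model, _ = fitted_small
        for ens in model.ensembles:
            assert len(ens.cells) == 4
            assert len(ens.weights) == 4
            assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert (ens.weights > 0).all()
            assert 0.0 < ens.theta_opt < 1.0

    def test_cell_cs_identity(self, fitted_small):
        model, _ = fitted_small
        for ens in model.ensembles:
            for c in ens.cells:
                assert c.cs == pytest.approx(0.6 * c.auc + 0.4 * c.gmean,
                                             abs=1e-12)

    def test_grid_rerun_is_deterministic(self, small_cohort):
        cfg = dw.RunConfig(selectors=["T_score"], learners=["LR", "KNN"],
                           search_iterations=3, seed=33)
        a = dw.fit_dwf(small_cohort, cfg=cfg)
        b = dw.fit_dwf(small_cohort, cfg=cfg)
        np.testing.assert_array_equal(a.pooled_scores, b.pooled_scores)
        for ea, eb in zip(a.ensembles, b.ensembles):
            assert [c.cell_id for c in ea.cells] == [c.cell_id for c in eb.cells]
            np.testing.assert_array_equal(ea.weights, eb.weights)

    def test_predict_with_provenance_reproduces_pooled(self, fitted_small):
        model, table = fitted_small
        scores, labels = model.predict(table,
                                       fold_provenance=model.fold_assignment)
        np.testing.assert_allclose(scores, model.pooled_scores, atol=1e-12)
        np.testing.assert_array_equal(labels, model.pooled_pred)

    def test_deployment_score_is_fold_mean(self, fitted_small):
        model, table = fitted_small
        scores, labels = model.predict(table)
        sub = table.subset(np.arange(5))
        per_fold = np.array([
            ens.predict_scores(prep.apply(sub.X))
            for prep, ens in zip(model.preprocessors, model.ensembles)])
        np.testing.assert_allclose(scores[:5], per_fold.mean(axis=0),
                                   atol=1e-12)
        theta = np.mean([e.theta_opt for e in model.ensembles])
        np.testing.assert_array_equal(labels, (scores > theta).astype(int))

    def test_missing_columns_rejected_at_predict(self, fitted_small):
        model, table = fitted_small
        stripped = dw.CohortTable(table.patient_ids, table.X[:, :-1],
                                  table.feature_names[:-1], table.y)
        with pytest.raises(ValueError, match="missing feature"):
            model.predict(stripped)

    def test_validation_perturbation_leaves_fit_state_unchanged(self,
                                                                tiny_matrix):
        cfg = dw.RunConfig(selectors=["T_score", "Fisher"],
                           learners=["LR", "DT"], search_iterations=3,
                           seed=55)
        model_a = dw.fit_dwf(tiny_matrix, cfg=cfg)
        # perturb only fold 0's validation rows
        fold0 = model_a.fold_assignment == 0
        X2 = tiny_matrix.X.copy()
        X2[fold0] = X2[fold0] * 3.0 + 1.0
        table2 = dw.CohortTable(tiny_matrix.patient_ids, X2,
                                tiny_matrix.feature_names, tiny_matrix.y)
        model_b = dw.fit_dwf(table2, cfg=cfg)
        assert (model_b.fold_assignment == model_a.fold_assignment).all()
        # training-side state of fold 0 must be identical
        assert (model_a.preprocessors[0].to_json()
                == model_b.preprocessors[0].to_json())
        sets_a = {(s, l): f.tolist() for s, l, f in model_a.ensembles[0].all_cells}
        sets_b = {(s, l): f.tolist() for s, l, f in model_b.ensembles[0].all_cells}
        assert sets_a == sets_b
        params_a = {c.cell_id: c.learner.params
                    for c in model_a.ensembles[0].cells}
        params_b = {c.cell_id: c.learner.params
                    for c in model_b.ensembles[0].cells}
        for cid in set(params_a) & set(params_b):
            assert params_a[cid] == params_b[cid]
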