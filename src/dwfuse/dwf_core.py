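"""Dynamic weighted fusion: grid evaluation, selection, weighting, fusion
and threshold optimization over a stratified outer cross-validation.

Per outer fold the pipeline is: preprocess (fit on the training split) ->
borderline oversampling of the training split -> for every enabled
(selector, learner) cell, select top-k features and tune/fit the learner
-> evaluate each cell on the validation fold -> keep the top-n cells by
G-mean -> combined score CS = 0.6*AUC + 0.4*G-mean -> temperature-Softmax
weights -> fused probability -> G-mean-optimal threshold.

Validation rows never influence preprocessing statistics, selector
scores, or hyperparameter tuning; an oversampling audit runs at the end
of every fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import importance as importance_mod
from . import learners as learners_mod
from . import metrics_eval as me
from . import selectors as selectors_mod
from .cohort_io import CohortTable, ReferenceRangeMap, RunConfig, log_stage
from .imbalance import OversampleConfig, OversampleResult, borderline_smote, \
    guard_no_leakage
from .preprocess import PreprocessModel, fit_transform_pipeline


def stage_seed(master: int, *tags: int) -> int:
    """Deterministic sub-seed derived from the master seed and stage tags."""
    ss = np.random.SeedSequence([int(master)] + [int(t) for t in tags])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


# ------------------------------------------------------------- fold layout

def make_outer_folds(y: np.ndarray, n_folds: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Stratified outer-fold assignment: entry i is the validation fold of
    row i."""
    y = np.asarray(y)
    counts = np.bincount(y)
    if (counts < n_folds).any():
        raise ValueError("class too small to stratify into requested folds")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, val_idx) in enumerate(cv.split(np.zeros((len(y), 1)), y)):
        assignment[val_idx] = fold
    return assignment


# -------------------------------------------------------------- arithmetic

def combined_score(auc: float, gmean: float,
                   weights: tuple[float, float] = (0.6, 0.4)) -> float:
    """CS = 0.6*AUC + 0.4*G-mean (default weighting)."""
    if not (0 <= auc <= 1 and 0 <= gmean <= 1):
        raise ValueError("AUC and G-mean must lie in [0, 1]")
    return weights[0] * auc + weights[1] * gmean


def softmax_weights(cs: np.ndarray, temperature: float = 0.1) -> np.ndarray:
    """omega_i = exp(cs_i/T) / sum_j exp(cs_j/T), max-subtracted for
    overflow safety.  Low T sharpens toward the best score."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    cs = np.asarray(cs, dtype=float)
    if cs.size == 0:
        raise ValueError("empty score list")
    z = cs / temperature
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def fuse(probabilities: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of aligned probability vectors (rows = learners)."""
    P = np.asarray(probabilities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if P.shape[0] != len(w):
        raise ValueError("one weight per probability vector required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w @ P


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold on the fused score maximizing G-mean on the validation
    scores (candidates: midpoints of consecutive distinct scores plus 0/1
    guards; predicted positive means score > threshold; ties take the
    smallest threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes required to optimize the threshold")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    best_theta, best_g = None, -1.0
    for theta in candidates:
        pred = scores > theta
        sens = np.sum(pred & pos) / n_pos
        spec = np.sum(~pred & ~pos) / n_neg
        g = np.sqrt(sens * spec)
        if g > best_g + 1e-15:
            best_theta, best_g = float(theta), float(g)
    return min(max(best_theta, 1e-12), 1.0 - 1e-12)


# ------------------------------------------------------------ grid structs

@dataclass
class CellResult:
    """One (selector, learner) cell of the grid with validation metrics."""

    selector_id: str
    learner_id: str
    feature_indices: np.ndarray
    learner: learners_mod.FittedLearner | None
    auc: float
    gmean: float
    cs: float = 0.0

    @property
    def cell_id(self) -> str:
        return f"{self.selector_id}+{self.learner_id}"


@dataclass
class FoldEnsemble:
    """Per-fold fused model: top cells, Softmax weights, threshold."""

    fold: int
    cells: list[CellResult]
    weights: np.ndarray
    temperature: float
    theta_opt: float
    fused_val_scores: np.ndarray
    val_rows: np.ndarray
    all_cells: list[tuple[str, str, np.ndarray]] = field(default_factory=list)
    failed_cells: list[tuple[str, str, str]] = field(default_factory=list)
    # validation-fold class-1 probabilities of every successful grid cell,
    # kept so single-cell baselines can be pooled across folds
    cell_val_proba: dict[str, np.ndarray] = field(default_factory=dict)

    def predict_scores(self, X_processed: np.ndarray) -> np.ndarray:
        P = np.vstack([c.learner.predict_proba(X_processed)
                       for c in self.cells])
        return fuse(P, self.weights)


def grid_cells(cfg: RunConfig | None = None) -> list[tuple[str, str]]:
    """Enumerate the (selector, learner) roster; defaults to the full
    14 x 12 = 168-cell grid."""
    cfg = cfg or RunConfig()
    sels = cfg.selectors or selectors_mod.SELECTOR_IDS
    lrns = cfg.learners or learners_mod.LEARNER_IDS
    return [(s, l) for s in sels for l in lrns]


def evaluate_grid(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    cfg: RunConfig, fold: int,
    feature_names: list[str] | None = None,
    X_select: np.ndarray | None = None,
    y_select: np.ndarray | None = None,
) -> tuple[list[CellResult], list[tuple[str, str, str]]]:
    """Fit and validate every enabled cell of the selector x learner grid.

    Selector scores are computed once per selector on the (optionally
    pre-oversampling) training view; failed or unavailable cells are
    recorded and excluded with a warning rather than aborting the grid.
    """
    cells = grid_cells(cfg)
    sel_ids = sorted({s for s, _ in cells})
    Xs = X_select if X_select is not None else X_train
    ys = y_select if y_select is not None else y_train

    sel_features: dict[str, np.ndarray] = {}
    failed: list[tuple[str, str, str]] = []
    for s_idx, sid in enumerate(sel_ids):
        try:
            scores = selectors_mod.score_features(sid, Xs, ys)
            k = min(cfg.top_k_features, Xs.shape[1])
            sel_features[sid] = selectors_mod.top_k(scores, k)
        except Exception as exc:  # degraded-grid contract
            log_stage("selector_failed", selector=sid, error=type(exc).__name__)
            for s2, l2 in cells:
                if s2 == sid:
                    failed.append((s2, l2, f"selector: {exc}"))

    results: list[CellResult] = []
    for cell_idx, (sid, lid) in enumerate(cells):
        if sid not in sel_features:
            continue
        feats = sel_features[sid]
        seed = stage_seed(cfg.seed, 2, fold, cell_idx)
        try:
            fitted = learners_mod.tune_and_fit(
                lid, X_train, y_train, feature_indices=feats,
                n_iter=cfg.search_iterations, inner_folds=cfg.n_inner_folds,
                seed=seed,
                feature_names=[feature_names[j] for j in feats]
                if feature_names else None)
            proba = fitted.predict_proba(X_val)
            auc = me.auc_rank(proba, y_val)
            gmean = me.gmean_score(y_val, (proba > 0.5).astype(int))
            results.append(CellResult(sid, lid, feats, fitted, auc, gmean))
        except Exception as exc:
            log_stage("cell_failed", selector=sid, learner=lid,
                      error=type(exc).__name__)
            failed.append((sid, lid, str(exc)))
    log_stage("evaluate_grid", fold=fold, attempted=len(cells),
              succeeded=len(results), failed=len(failed))
    return results, failed


def select_top(cells: list[CellResult], n: int = 10) -> list[CellResult]:
    """Top-n cells by descending G-mean; ties by higher AUC, then by
    selector/learner id."""
    if not cells:
        raise ValueError("no successful grid cells")
    ranked = sorted(cells, key=lambda c: (-c.gmean, -c.auc,
                                          c.selector_id, c.learner_id))
    if len(ranked) < n:
        log_stage("select_top_short", available=len(ranked), requested=n)
    return ranked[:n]


def pooled_cell_gmeans(ensembles: list[FoldEnsemble],
                       y: np.ndarray) -> dict[str, float]:
    """Pooled G-mean of every single grid cell across the outer folds.

    Each cell gets the same treatment as the fused model: a G-mean-optimal
    threshold per validation fold, hard predictions pooled over folds.
    Only cells that succeeded in every fold are reported.
    """
    y = np.asarray(y)
    common = set(ensembles[0].cell_val_proba)
    for ens in ensembles[1:]:
        common &= set(ens.cell_val_proba)
    out = {}
    for cid in sorted(common):
        pred = np.zeros(len(y), dtype=int)
        for ens in ensembles:
            proba = ens.cell_val_proba[cid]
            theta = optimize_threshold(proba, y[ens.val_rows])
            pred[ens.val_rows] = (proba > theta).astype(int)
        out[cid] = me.gmean_score(y, pred)
    return out


# ----------------------------------------------------------------- the fit

@dataclass
class DWFModel:
    """Fitted fusion model: per-fold preprocessing state and ensembles,
    pooled validation predictions, importance ranking, evaluation report."""

    config: RunConfig
    feature_names: list[str]
    fold_assignment: np.ndarray
    preprocessors: list[PreprocessModel]
    ensembles: list[FoldEnsemble]
    pooled_scores: np.ndarray
    pooled_pred: np.ndarray
    importance: "importance_mod.ImportanceRanking"
    report: dict
    leakage_audit: dict

    def predict(self, table: CohortTable,
                fold_provenance: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """Score new patients.

        Without provenance each row is scored by all fold ensembles
        (through each fold's own preprocessing state) and the scores are
        averaged with equal fold weights; the label threshold is the mean
        of the per-fold optimized thresholds.  With ``fold_provenance``
        (the training fold assignment) each row is scored only by the
        ensemble that held it out, reproducing pooled validation scores.
        """
        missing = [f for f in self.feature_names if f not in table.feature_names]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        order = [table.feature_names.index(f) for f in self.feature_names]
        X_raw = table.X[:, order]

        per_fold = np.vstack([
            ens.predict_scores(prep.apply(X_raw))
            for prep, ens in zip(self.preprocessors, self.ensembles)])
        if fold_provenance is not None:
            scores = per_fold[np.asarray(fold_provenance),
                              np.arange(len(table.y))]
            thetas = np.array([self.ensembles[f].theta_opt
                               for f in fold_provenance])
            labels = (scores > thetas).astype(int)
        else:
            scores = per_fold.mean(axis=0)
            theta = float(np.mean([e.theta_opt for e in self.ensembles]))
            labels = (scores > theta).astype(int)
        return scores, labels

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "dwfuse-model-v1",
            "config": self.config.to_dict(),
            "feature_names": self.feature_names,
            "fold_thetas": [e.theta_opt for e in self.ensembles],
            "report": self.report,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(self, directory / "model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "DWFModel":
        return joblib.load(Path(directory) / "model.joblib")


def fit_dwf(table: CohortTable, ranges: ReferenceRangeMap | None = None,
            cfg: RunConfig | None = None) -> DWFModel:
    """Fit the full fusion model with outer cross-validation.

    See the module docstring for the per-fold pipeline; the returned model
    carries pooled validation predictions for every patient (each scored
    by the fold that held it out), the recurrence-frequency importance
    ranking, and the evaluation report.
    """
    cfg = cfg or RunConfig()
    ranges = ranges or ReferenceRangeMap({})
    n0, n1 = table.class_counts()
    if min(n0, n1) < 2 * cfg.n_outer_folds:
        raise ValueError("minority class too small for the outer folds")

    assignment = make_outer_folds(table.y, cfg.n_outer_folds,
                                  seed=stage_seed(cfg.seed, 0))
    pooled_scores = np.full(table.n_patients, np.nan)
    pooled_pred = np.zeros(table.n_patients, dtype=int)
    preprocessors: list[PreprocessModel] = []
    ensembles: list[FoldEnsemble] = []
    fold_metrics: list[dict] = []
    fold_cms: list[me.ConfusionMatrix] = []
    smote_records: dict[int, OversampleResult] = {}

    for fold in range(cfg.n_outer_folds):
        val_rows = np.flatnonzero(assignment == fold)
        train_rows = np.flatnonzero(assignment != fold)
        y_tr, y_va = table.y[train_rows], table.y[val_rows]

        prep, X_tr = fit_transform_pipeline(table.X[train_rows],
                                            table.feature_names, ranges)
        X_va = prep.apply(table.X[val_rows])

        if cfg.honest_selection:
            # carve a selection subset out of the training split so the
            # validation fold is untouched by ranking/weighting/thresholding
            tr_i, sel_i = train_test_split(
                np.arange(len(train_rows)), test_size=0.2, stratify=y_tr,
                random_state=stage_seed(cfg.seed, 3, fold))
            X_rank, y_rank = X_tr[sel_i], y_tr[sel_i]
            X_fit_base, y_fit_base = X_tr[tr_i], y_tr[tr_i]
            fit_global = train_rows[tr_i]
        else:
            X_rank, y_rank = X_va, y_va
            X_fit_base, y_fit_base = X_tr, y_tr
            fit_global = train_rows

        os_res = borderline_smote(
            X_fit_base, y_fit_base,
            OversampleConfig(cfg.smote_m_neighbors, cfg.smote_k_neighbors,
                             cfg.smote_target_ratio,
                             seed=stage_seed(cfg.seed, 1, fold)))
        # map synthesis parents back to original cohort rows for the audit
        smote_records[fold] = replace(os_res, parents=[
            (int(fit_global[p]), int(fit_global[q]), u)
            for p, q, u in os_res.parents])

        select_view = (X_fit_base, y_fit_base) if cfg.select_before_oversample \
            else (os_res.X, os_res.y)
        cells, failed = evaluate_grid(
            os_res.X, os_res.y, X_rank, y_rank, cfg, fold,
            feature_names=table.feature_names,
            X_select=select_view[0], y_select=select_view[1])

        top = select_top(cells, cfg.top_n_classifiers)
        for c in top:
            c.cs = combined_score(c.auc, c.gmean, cfg.cs_weights)
        weights = softmax_weights(np.array([c.cs for c in top]),
                                  cfg.temperature)
        fused_rank = fuse(np.vstack([c.learner.predict_proba(X_rank)
                                     for c in top]), weights)
        theta = optimize_threshold(fused_rank, y_rank)

        fused_val = fuse(np.vstack([c.learner.predict_proba(X_va)
                                    for c in top]), weights)
        pred_val = (fused_val > theta).astype(int)
        cm = me.confusion(y_va, pred_val)
        metrics = me.metric_suite(cm)
        metrics["auc"] = me.auc_rank(fused_val, y_va)
        metrics.pop("undefined", None)
        fold_metrics.append(metrics)
        fold_cms.append(cm)
        pooled_scores[val_rows] = fused_val
        pooled_pred[val_rows] = pred_val

        all_sets = [(c.selector_id, c.learner_id, c.feature_indices)
                    for c in cells]
        cell_val = {c.cell_id: c.learner.predict_proba(X_va) for c in cells}
        top_ids = {id(c) for c in top}
        for c in cells:          # drop fitted state of non-top cells
            if id(c) not in top_ids:
                c.learner = None
        ensembles.append(FoldEnsemble(
            fold=fold, cells=top, weights=weights,
            temperature=cfg.temperature, theta_opt=theta,
            fused_val_scores=fused_val, val_rows=val_rows,
            all_cells=all_sets, failed_cells=failed,
            cell_val_proba=cell_val))
        preprocessors.append(prep)
        log_stage("fold_done", fold=fold, auc=round(metrics["auc"], 4),
                  gmean=round(metrics["gmean"], 4), theta=round(theta, 4))

    audit = guard_no_leakage(assignment, smote_records, strict=True)
    ranking = importance_mod.accumulate_importance(ensembles,
                                                   table.feature_names)
    pooled_cm = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled_cm = pooled_cm + cm
    report = me.report_from_folds(fold_metrics, pooled_cm,
                                  me.auc_rank(pooled_scores, table.y))
    return DWFModel(
        config=cfg, feature_names=list(table.feature_names),
        fold_assignment=assignment, preprocessors=preprocessors,
        ensembles=ensembles, pooled_scores=pooled_scores,
        pooled_pred=pooled_pred, importance=ranking, report=report,
        leakage_audit=audit.to_dict())
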