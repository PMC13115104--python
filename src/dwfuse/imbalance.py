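"""Borderline oversampling of the minority (resistant) class.

Implements the borderline-1 variant: only minority points whose
m-neighborhood is half-or-more majority — but not purely majority — are
considered to sit on the decision boundary (the DANGER set) and seed
synthetic samples.  Synthesis interpolates toward random minority
neighbors, so every synthetic row lies componentwise between two original
minority training rows.  Oversampling must only ever be applied to
training folds; ``guard_no_leakage`` audits that contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .cohort_io import log_stage


@dataclass
class OversampleConfig:
    m_neighbors: int = 5      # neighborhood size for DANGER detection
    k_neighbors: int = 5      # minority neighbors used for synthesis
    target_ratio: float = 1.0  # minority:majority after resampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_neighbors < 1 or self.k_neighbors < 1:
            raise ValueError("neighbor counts must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")


@dataclass
class OversampleResult:
    X: np.ndarray
    y: np.ndarray
    n_original: int
    # per-synthetic-row provenance: (parent_p, parent_q, u), indices into
    # the original training matrix
    parents: list[tuple[int, int, float]] = field(default_factory=list)
    danger_indices: np.ndarray | None = None


def _nearest_neighbors(D: np.ndarray, i: int, k: int,
                       candidates: np.ndarray) -> np.ndarray:
    """Indices of the k nearest candidates to row i (self excluded),
    distance ties broken by ascending row index."""
    cand = candidates[candidates != i]
    order = np.lexsort((cand, D[i, cand]))
    return cand[order[:k]]


def borderline_smote(X: np.ndarray, y: np.ndarray,
                     cfg: OversampleConfig | None = None) -> OversampleResult:
    """Oversample the minority class up to ``target_ratio`` of the majority.

    Original rows are preserved, in order, ahead of the synthetic rows.
    Returns unchanged input (with a logged warning) when already at target
    or when no DANGER points exist.
    """
    cfg = cfg or OversampleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_count = int(counts.max())
    if len(min_idx) < 2:
        raise ValueError("minority count < 2")

    deficit = int(round(cfg.target_ratio * maj_count)) - len(min_idx)
    if deficit <= 0:
        return OversampleResult(X, y, len(y), [], np.array([], dtype=int))

    D = cdist(X, X)
    all_rows = np.arange(len(y))

    # DANGER: m/2 <= majority neighbors < m (pure-majority = noise, skipped)
    danger = []
    for p in min_idx:
        nn = _nearest_neighbors(D, p, cfg.m_neighbors, all_rows)
        m_prime = int(np.sum(y[nn] != minority))
        if cfg.m_neighbors / 2 <= m_prime < cfg.m_neighbors:
            danger.append(p)
    danger = np.array(danger, dtype=int)
    if len(danger) == 0:
        log_stage("borderline_smote_no_danger", minority=len(min_idx))
        return OversampleResult(X, y, len(y), [], danger)

    # k nearest minority neighbors of each danger point
    nbrs = {p: _nearest_neighbors(D, p, cfg.k_neighbors, min_idx)
            for p in danger}

    rng = np.random.default_rng(cfg.seed)
    synth_rows = []
    parents = []
    for i in range(deficit):
        p = danger[i % len(danger)]
        q = int(rng.choice(nbrs[p]))
        u = float(rng.uniform())
        synth_rows.append(X[p] + u * (X[q] - X[p]))
        parents.append((int(p), q, u))

    X_out = np.vstack([X, np.array(synth_rows)])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=int)])
    log_stage("borderline_smote", danger=len(danger), synthesized=deficit)
    return OversampleResult(X_out, y_out, len(y), parents, danger)


@dataclass
class LeakageReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": list(self.violations)}


def guard_no_leakage(
    fold_assignment: np.ndarray,
    oversample_records: dict[int, OversampleResult],
    strict: bool = True,
) -> LeakageReport:
    """Audit that synthetic rows descend only from training-fold members.

    ``fold_assignment[i]`` is the validation fold of original row i;
    ``oversample_records[f]`` must carry, as parent indices, positions in
    the ORIGINAL cohort (the caller maps training-local indices back).
    Validation folds must consist of original rows only, with their
    original class counts.
    """
    report = LeakageReport()
    fold_assignment = np.asarray(fold_assignment)
    for fold, rec in oversample_records.items():
        train_rows = set(np.flatnonzero(fold_assignment != fold).tolist())
        for s, (p, q, _u) in enumerate(rec.parents):
            for parent in (p, q):
                if parent not in train_rows:
                    report.violations.append(
                        f"fold {fold}: synthetic row {s} has parent {parent} "
                        f"outside the training split")
        if rec.n_original > len(train_rows):
            report.violations.append(
                f"fold {fold}: oversampled base has {rec.n_original} rows, "
                f"more than the {len(train_rows)}-row training split")
    if strict and not report.ok:
        raise RuntimeError("oversampling leakage detected: "
                           + "; ".join(report.violations))
    return report
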