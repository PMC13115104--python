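"""Recurrence-frequency feature importance.

A feature's importance is how often it appears in the selected-feature
sets of the fused top classifiers — at the default configuration, the
5 folds x 10 top cells = 50 optimized classifiers — normalized to [0, 1]
by that cell count.  A score of 0.8 therefore means the feature was
prioritized by 40 of the 50 classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ImportanceRanking:
    """Per-feature recurrence counts and normalized ranking scores."""

    table: pd.DataFrame      # columns: feature, count, score, rank
    n_cells: int             # normalization denominator

    def score_of(self, feature: str) -> float:
        row = self.table.loc[self.table["feature"] == feature, "score"]
        return float(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"n_cells": self.n_cells,
                "features": self.table.to_dict(orient="records")}


def accumulate_importance(fold_ensembles, feature_names: list[str]
                          ) -> ImportanceRanking:
    """Count feature appearances over the top cells of every fold.

    score = count / (number of counted cells); every feature is listed,
    including zero-count ones; score ties are broken by feature-name
    lexicographic order.
    """
    if not fold_ensembles:
        raise ValueError("no fitted folds")
    counts = np.zeros(len(feature_names), dtype=int)
    n_cells = 0
    for ens in fold_ensembles:
        for cell in ens.cells:
            counts[np.asarray(cell.feature_indices, dtype=int)] += 1
            n_cells += 1
    scores = counts / n_cells
    df = pd.DataFrame({"feature": feature_names, "count": counts,
                       "score": scores})
    df = df.sort_values(["score", "feature"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceRanking(table=df, n_cells=n_cells)


def unique_selected_features(fold_ensembles, feature_names: list[str],
                             population: str = "top") -> dict:
    """Union of selected-feature sets with per-cell provenance.

    ``population="top"`` unions over the fused top cells only;
    ``population="all"`` unions over every successful grid cell.
    """
    if population not in ("top", "all"):
        raise ValueError("population must be 'top' or 'all'")
    provenance: dict[str, list[str]] = {}
    for ens in fold_ensembles:
        if population == "top":
            sets = [(c.selector_id, c.learner_id, c.feature_indices)
                    for c in ens.cells]
        else:
            sets = ens.all_cells
        for sid, lid, feats in sets:
            for j in np.asarray(feats, dtype=int):
                provenance.setdefault(feature_names[j], []).append(
                    f"fold{ens.fold}:{sid}+{lid}")
    return {"features": sorted(provenance), "n_unique": len(provenance),
            "provenance": provenance}
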