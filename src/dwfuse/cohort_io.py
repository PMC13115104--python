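"""Cohort table, reference-range, and run-configuration I/O.

A cohort is a patient-by-feature numeric matrix with a binary outcome
(1 = platinum-resistant, the positive class; 0 = platinum-sensitive).
Files are comma-separated UTF-8 with a header row and "." decimals;
empty cells and "NA" are treated as missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dwfuse")

_MISSING_TOKENS = ["", "NA"]


def get_logger() -> logging.Logger:
    """Package logger; line-oriented records carry stage/fold/seed context."""
    return logger


def log_stage(stage: str, **context) -> None:
    ctx = " ".join(f"{k}={v}" for k, v in context.items())
    logger.info("stage=%s %s", stage, ctx)


@dataclass
class CohortTable:
    """Patient-by-feature matrix with binary outcome labels.

    Missing values are stored as NaN in ``X``; ``missing_mask`` marks them.
    """

    patient_ids: np.ndarray          # shape (n,), opaque identifiers
    X: np.ndarray                    # shape (n, p), float, NaN = missing
    feature_names: list[str]
    y: np.ndarray                    # shape (n,), int in {0, 1}; 1 = resistant

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        if len(self.patient_ids) != n or len(self.y) != n:
            raise ValueError("row count mismatch between ids, matrix and outcome")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match matrix width")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.X)

    def class_counts(self) -> tuple[int, int]:
        """(n_sensitive, n_resistant)."""
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    def subset(self, rows: np.ndarray) -> "CohortTable":
        return CohortTable(
            patient_ids=self.patient_ids[rows],
            X=self.X[rows],
            feature_names=list(self.feature_names),
            y=self.y[rows],
        )

    def with_X(self, X: np.ndarray) -> "CohortTable":
        return replace(self, X=np.asarray(X, dtype=float))

    def to_frame(self, outcome_column: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        df[outcome_column] = self.y
        return df


def read_cohort(path: str | Path, outcome_column: str,
                id_column: str = "patient_id") -> CohortTable:
    """Read a delimited cohort table.

    Non-numeric feature cells become missing; the outcome column must hold
    exactly two distinct values after numeric coercion.
    """
    # sniff the raw header: pandas silently mangles duplicate column names
    if hasattr(path, "readline"):
        header = path.readline()
        path.seek(0)
    else:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
    raw_names = [c.strip() for c in header.rstrip("\n").split(",")]
    dupes = {c for c in raw_names if raw_names.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate feature names: {sorted(dupes)}")

    df = pd.read_csv(path, na_values=_MISSING_TOKENS, keep_default_na=False,
                     float_precision="round_trip")
    if outcome_column not in df.columns:
        raise ValueError(f"missing outcome column {outcome_column!r}")
    y_raw = pd.to_numeric(df[outcome_column], errors="coerce")
    if y_raw.isna().any():
        raise ValueError("outcome column contains missing/non-numeric values")
    uniq = sorted(y_raw.unique())
    if len(uniq) != 2:
        if len(uniq) == 1:
            raise ValueError("single-class outcome")
        raise ValueError(f"outcome must be binary, found values {uniq}")
    if uniq != [0, 1]:
        raise ValueError(f"outcome values must be 0/1, found {uniq}")

    if id_column in df.columns:
        ids = df[id_column].astype(str).to_numpy()
        feat_df = df.drop(columns=[id_column, outcome_column])
    else:
        ids = np.array([f"P{i:04d}" for i in range(len(df))])
        feat_df = df.drop(columns=[outcome_column])
    names = list(feat_df.columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    X = feat_df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    table = CohortTable(ids, X, names, y_raw.to_numpy(dtype=int))
    log_stage("read_cohort", path=path, n=table.n_patients, p=table.n_features,
              missing=int(table.missing_mask.sum()))
    return table


def write_cohort(table: CohortTable, path: str | Path,
                 outcome_column: str = "outcome") -> None:
    """Write a cohort as CSV; missing cells are emitted as empty strings.

    Floats are written at shortest round-trip precision so read_cohort
    recovers numeric cells bit-identically.
    """
    df = table.to_frame(outcome_column)
    df.to_csv(path, index=False, na_rep="")


@dataclass
class ReferenceRangeMap:
    """Per-feature optional upper limits used for value capping.

    Features without an entry pass through uncapped.
    """

    upper: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, limit in self.upper.items():
            limit = float(limit)
            if not np.isfinite(limit) or limit <= 0:
                raise ValueError(f"reference upper limit for {name!r} must be "
                                 f"finite and positive, got {limit}")
            self.upper[name] = limit

    def get(self, feature: str) -> float | None:
        return self.upper.get(feature)

    def __len__(self) -> int:
        return len(self.upper)


def read_reference_ranges(path: str | Path) -> ReferenceRangeMap:
    """Read upper reference limits from JSON ({feature: limit}) or a
    two-column CSV (feature, upper)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return ReferenceRangeMap({})
    if path.suffix.lower() == ".json" or text.startswith("{"):
        raw = json.loads(text)
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("reference-range CSV needs (feature, upper) columns")
        raw = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
    upper = {}
    for name, limit in raw.items():
        try:
            upper[name] = float(limit)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric limit for {name!r}: {limit!r}") from exc
    return ReferenceRangeMap(upper)


def write_reference_ranges(ranges: ReferenceRangeMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ranges.upper, indent=1, sort_keys=True))


@dataclass
class RunConfig:
    """Run configuration for the fusion pipeline.

    Defaults mirror the framework's published operating point: 5 outer folds,
    3 inner tuning folds, top-10 features per selector, top-10 classifiers
    fused, Softmax temperature 0.1, combined score 0.6·AUC + 0.4·G-mean.
    """

    n_outer_folds: int = 5
    n_inner_folds: int = 3
    top_k_features: int = 10
    top_n_classifiers: int = 10
    temperature: float = 0.1
    cs_weights: tuple[float, float] = (0.6, 0.4)   # (AUC, G-mean)
    search_iterations: int = 20
    seed: int = 0
    # oversampling
    smote_m_neighbors: int = 5
    smote_k_neighbors: int = 5
    smote_target_ratio: float = 1.0
    # roster restriction; None = full registry
    selectors: list[str] | None = None
    learners: list[str] | None = None
    # pipeline switches
    select_before_oversample: bool = False
    boxcox_all_features: bool = True
    honest_selection: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if abs(sum(self.cs_weights) - 1.0) > 1e-9:
            raise ValueError("cs_weights must sum to 1")
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.top_k_features < 1 or self.top_n_classifiers < 1:
            raise ValueError("top_k_features and top_n_classifiers must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cs_weights" in raw:
            raw["cs_weights"] = tuple(raw["cs_weights"])
        if "selectors" in raw and raw["selectors"] is not None:
            raw["selectors"] = list(raw["selectors"])
        if "learners" in raw and raw["learners"] is not None:
            raw["learners"] = list(raw["learners"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cs_weights"] = list(self.cs_weights)
        return d


def cohort_from_frame(df: pd.DataFrame, outcome_column: str,
                      id_column: str = "patient_id") -> CohortTable:
    """Build a CohortTable from an in-memory DataFrame (same coercions as
    read_cohort)."""
    import io

    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_cohort(buf, outcome_column, id_column=id_column)  # type: ignore[arg-type]
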