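"""Synthetic cohort generator.

Emulates the statistical structure of a routine-laboratory ovarian-cancer
cohort: 322 patients (91 platinum-resistant / 231 platinum-sensitive), 70
features in correlated blocks (clinical, complete blood count,
liver/renal panel, tumor markers, coagulation profile), right-skewed
lognormal marginals for the tumor markers and fibrin-degradation
features, class-dependent standardized mean shifts for the markers known
to separate the groups (age, inflammatory indices, urea, coagulation),
and ~1.62% completely-at-random missingness.

The effect sizes are free calibration parameters, chosen so single-feature
discrimination lands in the modest univariable AUC range typical of routine
laboratory markers (~0.60); they are not estimates of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortTable, ReferenceRangeMap, log_stage

# Table of feature blocks: four laboratory categories plus clinical.
FEATURE_BLOCKS: dict[str, list[str]] = {
    "clinical": ["Age", "BMI"],
    "blood_count": [
        "WBC", "LYM", "MID", "GRAN", "EOS", "BASO", "LYM#", "MID#",
        "GRAN#", "EOS#", "BASO#", "RBC", "HGB", "HCT", "MCV", "MCH",
        "MCHC", "RDWCV", "RDWSD", "PLT", "MPV", "PCT", "PDW", "NL",
    ],
    "liver_renal": [
        "TBIL", "DBIL", "IBIL", "ALP", "ALT", "AST", "ASTM", "LDH",
        "GGT", "TP", "ALB", "GELO", "A/G", "NEFA", "PA", "GLDH",
        "CYSC", "GA", "UREA", "CRE", "UA", "GLU", "CA", "P", "MG",
        "K", "NA", "CL", "TCO2",
    ],
    "tumor_markers": [
        "SCCA", "CA19-9", "CA125", "AFP", "CEA", "NSE", "HCG-B", "HE4",
    ],
    "coagulation": ["PT", "FIB", "APTT", "TT", "INR", "DDI", "FDP"],
}

ALL_FEATURES: list[str] = [f for block in FEATURE_BLOCKS.values()
                           for f in block]

# right-skewed marginals: the 8 tumor markers plus fibrin degradation
LOGNORMAL_FEATURES: set[str] = set(FEATURE_BLOCKS["tumor_markers"]) | {
    "FDP", "DDI"}

# standardized latent-scale mean shifts of the resistant class
DEFAULT_CLASS_EFFECTS: dict[str, float] = {
    "Age": 0.45, "NL": 0.35, "GRAN": 0.35, "GRAN#": 0.30, "WBC": 0.25,
    "UREA": 0.25, "FIB": 0.30, "FDP": 0.30, "LYM": -0.30,
}

# plausible location/scale for marquee laboratory features (normal family:
# value = loc + scale*z; lognormal family: value = exp(loc + scale*z))
_MARGINALS: dict[str, tuple[float, float]] = {
    "Age": (57.0, 10.0), "BMI": (23.4, 2.8),
    "WBC": (6.9, 2.0), "LYM": (22.0, 6.0), "GRAN": (71.0, 8.0),
    "GRAN#": (4.9, 1.7), "NL": (3.9, 1.6), "PLT": (260.0, 80.0),
    "HGB": (122.0, 15.0), "RBC": (4.2, 0.5),
    "UREA": (4.4, 1.3), "CRE": (60.0, 12.0), "ALB": (41.0, 4.5),
    "PA": (220.0, 50.0), "UA": (280.0, 70.0), "NA": (140.0, 3.0),
    "PT": (11.5, 1.0), "FIB": (3.9, 0.8), "APTT": (28.0, 3.5),
    "TT": (16.5, 1.5), "INR": (1.0, 0.08),
    # lognormal (log-scale) parameters
    "CA125": (4.6, 1.4), "HE4": (4.4, 0.9), "CA19-9": (2.8, 1.1),
    "CEA": (0.7, 0.9), "AFP": (1.1, 0.8), "NSE": (2.6, 0.5),
    "SCCA": (0.2, 0.7), "HCG-B": (0.5, 1.0),
    "DDI": (0.1, 0.9), "FDP": (1.6, 0.7),
}
_GENERIC_NORMAL = (10.0, 3.0)


@dataclass
class SyntheticCohortConfig:
    """Parameters of the generator; defaults are the emulated cohort
    conditions (322 patients at a ~2:5 class ratio, 70-feature panel)."""

    n_resistant: int = 91
    n_sensitive: int = 231
    within_block_corr: float = 0.5
    between_block_corr: float = 0.1
    class_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS))
    missing_rate: float = 0.0162
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resistant < 2 or self.n_sensitive < 2:
            raise ValueError("need >= 2 patients per class")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")


def _block_correlation(within: float, between: float) -> np.ndarray:
    p = len(ALL_FEATURES)
    R = np.full((p, p), between)
    start = 0
    for names in FEATURE_BLOCKS.values():
        end = start + len(names)
        R[start:end, start:end] = within
        start = end
    np.fill_diagonal(R, 1.0)
    return R


def generate(cfg: SyntheticCohortConfig | None = None) -> CohortTable:
    """Draw one synthetic cohort.

    Latent per-patient Gaussians follow the block correlation matrix;
    resistant patients get the configured standardized mean shifts before
    the marginal maps (affine for normal-family features, exponential for
    the lognormal family); missing cells are punched completely at random.
    Class counts are exact, and the outcome is never missing.
    """
    cfg = cfg or SyntheticCohortConfig()
    R = _block_correlation(cfg.within_block_corr, cfg.between_block_corr)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("block correlation matrix is not positive "
                         "definite") from exc
    unknown = set(cfg.class_effects) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"class effects for unknown features: {unknown}")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_resistant + cfg.n_sensitive
    p = len(ALL_FEATURES)
    y = np.concatenate([np.ones(cfg.n_resistant, dtype=int),
                        np.zeros(cfg.n_sensitive, dtype=int)])

    Z = rng.standard_normal((n, p)) @ chol.T
    shift = np.array([cfg.class_effects.get(f, 0.0) for f in ALL_FEATURES])
    Z[y == 1] += shift

    X = np.empty((n, p))
    for j, name in enumerate(ALL_FEATURES):
        loc, scale = _MARGINALS.get(name, _GENERIC_NORMAL)
        if name in LOGNORMAL_FEATURES:
            X[:, j] = np.exp(loc + scale * Z[:, j])
        else:
            X[:, j] = loc + scale * Z[:, j]

    if cfg.missing_rate > 0:
        holes = rng.random((n, p)) < cfg.missing_rate
        X[holes] = np.nan

    ids = np.array([f"SYN{i:04d}" for i in range(n)])
    table = CohortTable(ids, X, list(ALL_FEATURES), y)
    log_stage("synth_generate", n=n, p=p, seed=cfg.seed,
              missing=int(table.missing_mask.sum()))
    return table


def emit_reference_ranges(table: CohortTable,
                          quantile: float = 0.975) -> ReferenceRangeMap:
    """Stand-in upper reference limits: the given quantile of each feature
    in the sensitive class (synthetic surrogate for laboratory ranges)."""
    sens = table.X[table.y == 0]
    upper = {}
    for j, name in enumerate(table.feature_names):
        col = sens[:, j]
        col = col[~np.isnan(col)]
        q = float(np.quantile(col, quantile))
        if np.isfinite(q) and q > 0:
            upper[name] = q
    return ReferenceRangeMap(upper)


def validate_structure(table: CohortTable,
                       cfg: SyntheticCohortConfig | None = None) -> dict:
    """Diagnostics of a generated cohort against its configuration.

    Reports realized class counts, missing fraction, mean within- vs
    between-block correlation, and realized standardized class shifts;
    deviations beyond loose Monte-Carlo tolerances are flagged.
    """
    cfg = cfg or SyntheticCohortConfig()
    n0, n1 = table.class_counts()
    missing_frac = float(table.missing_mask.mean())

    # correlations on a log scale for the skewed family, to undo the
    # exponential marginal map
    X = table.X.copy()
    for j, name in enumerate(table.feature_names):
        if name in LOGNORMAL_FEATURES:
            X[:, j] = np.log(np.maximum(X[:, j], 1e-12))
    C = np.ma.corrcoef(np.ma.masked_invalid(X), rowvar=False).filled(np.nan)
    block_of = {}
    start = 0
    for bname, names in FEATURE_BLOCKS.items():
        for k in range(len(names)):
            block_of[start + k] = bname
        start += len(names)
    within, between = [], []
    p = table.n_features
    for i in range(p):
        for j in range(i + 1, p):
            (within if block_of[i] == block_of[j] else between).append(C[i, j])
    within_mean = float(np.nanmean(within))
    between_mean = float(np.nanmean(between))

    shifts = {}
    for name, eff in cfg.class_effects.items():
        j = table.feature_names.index(name)
        col = X[:, j]
        a = col[(table.y == 1) & ~np.isnan(col)]
        b = col[(table.y == 0) & ~np.isnan(col)]
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                      + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
        shifts[name] = {"target": eff,
                        "realized": float((a.mean() - b.mean()) / sp)}

    flags = []
    if (n1, n0) != (cfg.n_resistant, cfg.n_sensitive):
        flags.append("class counts differ from configuration")
    if abs(missing_frac - cfg.missing_rate) > 0.005:
        flags.append("missing fraction outside +/-0.005 of configured rate")
    if within_mean <= between_mean:
        flags.append("within-block correlation not above between-block")
    for name, d in shifts.items():
        if abs(d["realized"] - d["target"]) > 0.35:
            flags.append(f"class shift of {name} far from target")
    return {
        "n_resistant": n1, "n_sensitive": n0,
        "missing_fraction": missing_frac,
        "within_block_corr": within_mean,
        "between_block_corr": between_mean,
        "class_shifts": shifts,
        "flags": flags,
    }
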