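"""Registry of the 14 feature-scoring methods behind one contract.

``score_features(selector_id, X, y)`` returns one finite score per feature
with the sign convention normalized so that larger always means more
relevant (methods that are natively smaller-is-better, such as the
Laplacian score, are negated).  ``top_k`` turns scores into ranked indices
with deterministic tie-breaking.

Roster:

* classical filters — ``F_score`` (one-way ANOVA F), ``T_score``
  (pooled-variance two-sample t), ``Fisher`` (between/within class
  variance ratio), ``reliefF`` (neighborhood margin), ``Laplacian``
  (locality preservation on a heat-kernel 5-NN graph);
* mutual-information family — ``JMI``, ``DISR``, ``ICAP``: greedy forward
  selection on equal-frequency 5-bin discretized variables, the selection
  order mapped to descending ranks;
* sparse-learning family — ``LS_l21`` / ``LL_l21`` (least-squares /
  logistic loss with an l2,1 row-sparsity penalty), ``MCFS``
  (spectral embedding + sparse regression), ``NDFS`` (nonnegative
  spectral analysis with l2,1-regularized regression), ``UDFS``
  (l2,1-regularized orthogonal projection of local scatter), and
  ``TraceRatio`` (iterative trace-ratio criterion on class scatters).

Supervised scores depend only on the rows they are given, so running them
on the training split alone is leakage-safe by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla
from scipy.spatial.distance import cdist
from sklearn.feature_selection import f_classif
from sklearn.linear_model import Lars

_EPS = 1e-12


# ----------------------------------------------------------- basic filters

def f_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature."""
    F, _ = f_classif(X, y)
    return np.nan_to_num(F, nan=0.0)


def t_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute pooled-variance two-sample t statistic per feature."""
    X0, X1 = X[y == 0], X[y == 1]
    n0, n1 = len(X0), len(X1)
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1)
    v1 = X1.var(axis=0, ddof=1)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    denom = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    return np.abs(m1 - m0) / np.maximum(denom, _EPS)


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Between-class over within-class variance per feature.

    sum_c n_c (m_cf - m_f)^2 / sum_c n_c s_cf^2; a feature identical in
    both classes scores 0.
    """
    m = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in np.unique(y):
        Xc = X[y == c]
        nc = len(Xc)
        num += nc * (Xc.mean(axis=0) - m) ** 2
        den += nc * Xc.var(axis=0)
    out = np.zeros(X.shape[1])
    np.divide(num, den, out=out, where=den > _EPS)
    return out


def relieff(X: np.ndarray, y: np.ndarray, n_neighbors: int = 10) -> np.ndarray:
    """ReliefF weights using all instances and k nearest hits/misses.

    Feature differences are normalized by the feature range; for the
    binary-outcome case the miss term has unit class-probability weight.
    """
    n, p = X.shape
    rng_span = np.maximum(X.max(axis=0) - X.min(axis=0), _EPS)
    D = cdist(X, X)
    W = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        diff = np.flatnonzero(y != y[i])
        k_h = min(n_neighbors, len(same))
        k_m = min(n_neighbors, len(diff))
        if k_h == 0 or k_m == 0:
            continue
        hits = same[np.lexsort((same, D[i, same]))[:k_h]]
        misses = diff[np.lexsort((diff, D[i, diff]))[:k_m]]
        W -= np.abs(X[hits] - X[i]).sum(axis=0) / (rng_span * k_h)
        W += np.abs(X[misses] - X[i]).sum(axis=0) / (rng_span * k_m)
    return W / n


# ----------------------------------------------- graph-based (unsupervised)

def _knn_heat_graph(X: np.ndarray, k: int = 5) -> np.ndarray:
    """Symmetric heat-kernel affinity on a k-NN graph; bandwidth is the
    mean squared distance over connected edges."""
    n = len(X)
    D2 = cdist(X, X) ** 2
    np.fill_diagonal(D2, np.inf)   # exclude self from neighborhoods
    order = np.argsort(D2, axis=1, kind="stable")
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, :k].ravel()] = True
    adj |= adj.T
    t = D2[adj].mean() if adj.any() else 1.0
    W = np.where(adj, np.exp(-D2 / max(t, _EPS)), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def laplacian_score(X: np.ndarray, y: np.ndarray | None = None,
                    n_neighbors: int = 5) -> np.ndarray:
    """Negated Laplacian score (natively smaller-is-better)."""
    W = _knn_heat_graph(X, n_neighbors)
    d = W.sum(axis=1)
    L = np.diag(d) - W
    dsum = max(d.sum(), _EPS)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ d) / dsum
        den = f_t @ (d * f_t)
        scores[j] = (f_t @ L @ f_t) / den if den > _EPS else np.inf
    return -scores


# --------------------------------------------------- mutual-information set

def discretize_equal_frequency(X: np.ndarray, bins: int = 5) -> np.ndarray:
    """Equal-frequency binning per column into integer codes [0, bins)."""
    codes = np.empty(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _entropy_from_codes(*cols: np.ndarray) -> float:
    """Joint Shannon entropy (nats) of integer-coded columns."""
    combined = cols[0].astype(np.int64).copy()
    for c in cols[1:]:
        combined = combined * (int(c.max()) + 1) + c
    counts = np.bincount(combined)
    p = counts[counts > 0] / combined.size
    return float(-(p * np.log(p)).sum())


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    return _entropy_from_codes(a) + _entropy_from_codes(b) - _entropy_from_codes(a, b)


def _greedy_mi_order(X: np.ndarray, y: np.ndarray, criterion: str,
                     bins: int = 5) -> list[int]:
    """Greedy forward-selection order under a conditional-MI criterion."""
    Z = discretize_equal_frequency(X, bins)
    yc = y.astype(np.int64)
    p = X.shape[1]
    rel = np.array([_mi(Z[:, j], yc) for j in range(p)])
    H_y = _entropy_from_codes(yc)
    H_f = np.array([_entropy_from_codes(Z[:, j]) for j in range(p)])

    # pairwise tables, filled lazily
    I_fs = np.full((p, p), np.nan)         # I(f; s)
    I_fs_y = np.full((p, p), np.nan)       # I(f; s | y)
    I_joint_y = np.full((p, p), np.nan)    # I((f,s); y)
    H_fsy = np.full((p, p), np.nan)        # H(f, s, y)

    def fill(f: int, s: int) -> None:
        if not np.isnan(I_fs[f, s]):
            return
        a, b = Z[:, f], Z[:, s]
        H_ab = _entropy_from_codes(a, b)
        H_aby = _entropy_from_codes(a, b, yc)
        H_ay = _entropy_from_codes(a, yc)
        H_by = _entropy_from_codes(b, yc)
        I_fs[f, s] = I_fs[s, f] = H_f[f] + H_f[s] - H_ab
        # I(f; s | y) = H(f,y) + H(s,y) - H(f,s,y) - H(y)
        I_fs_y[f, s] = I_fs_y[s, f] = H_ay + H_by - H_aby - H_y
        I_joint_y[f, s] = I_joint_y[s, f] = H_ab + H_y - H_aby
        H_fsy[f, s] = H_fsy[s, f] = H_aby

    first = int(np.lexsort((np.arange(p), -rel))[0])
    order = [first]
    remaining = [j for j in range(p) if j != first]
    while remaining:
        best_j, best_val = None, -np.inf
        for j in remaining:
            for s in order:
                fill(j, s)
            if criterion == "JMI":
                val = float(sum(I_joint_y[j, s] for s in order))
            elif criterion == "DISR":
                val = float(sum(I_joint_y[j, s] / max(H_fsy[j, s], _EPS)
                                for s in order))
            elif criterion == "ICAP":
                val = rel[j] - float(sum(max(0.0, I_fs[j, s] - I_fs_y[j, s])
                                         for s in order))
            else:  # pragma: no cover
                raise ValueError(criterion)
            if val > best_val + _EPS or (abs(val - best_val) <= _EPS
                                         and (best_j is None or j < best_j)):
                best_j, best_val = j, val
        order.append(best_j)
        remaining.remove(best_j)
    return order


def _order_to_scores(order: list[int]) -> np.ndarray:
    p = len(order)
    scores = np.empty(p)
    scores[np.array(order)] = np.arange(p, 0, -1, dtype=float)
    return scores


def jmi(X, y, bins: int = 5):
    return _order_to_scores(_greedy_mi_order(X, y, "JMI", bins))


def disr(X, y, bins: int = 5):
    return _order_to_scores(_greedy_mi_order(X, y, "DISR", bins))


def icap(X, y, bins: int = 5):
    return _order_to_scores(_greedy_mi_order(X, y, "ICAP", bins))


# --------------------------------------------------- sparse-learning family

def _row_norm_weights(W: np.ndarray) -> np.ndarray:
    return np.sqrt((W ** 2).sum(axis=1))


def _standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scoring: the sparse-learning objectives score features by
    coefficient row norms, which is only meaningful on a common scale."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / np.where(sd > _EPS, sd, 1.0)


def _one_hot(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    Y = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    return Y


def ls_l21(X: np.ndarray, y: np.ndarray, gamma: float = 0.1,
           n_iter: int = 50) -> np.ndarray:
    """Least-squares loss with l2,1 row-sparsity, solved by iteratively
    reweighted ridge systems; scores are the row norms of W."""
    X = _standardize(X)
    Y = _one_hot(y)
    Y = Y - Y.mean(axis=0)
    p = X.shape[1]
    G = X.T @ X
    XtY = X.T @ Y
    d = np.ones(p)
    W = np.zeros((p, Y.shape[1]))
    for _ in range(n_iter):
        W_new = np.linalg.solve(G + gamma * np.diag(d), XtY)
        d = 1.0 / (2.0 * np.maximum(_row_norm_weights(W_new), _EPS))
        if np.max(np.abs(W_new - W)) < 1e-8:
            W = W_new
            break
        W = W_new
    return _row_norm_weights(W)


def ll_l21(X: np.ndarray, y: np.ndarray, gamma: float = 0.01,
           n_iter: int = 200) -> np.ndarray:
    """Binary logistic loss with a row-sparsity penalty via proximal
    gradient (for a single logit the l2,1 norm reduces to l1); scores are
    absolute coefficients."""
    X = _standardize(X)
    n, p = X.shape
    yy = (y == np.unique(y).max()).astype(float)
    w = np.zeros(p)
    b = 0.0
    L = np.linalg.norm(X, 2) ** 2 / (4.0 * n) + 0.25
    step = 1.0 / L
    for _ in range(n_iter):
        z = X @ w + b
        mu = 1.0 / (1.0 + np.exp(-z))
        grad_w = X.T @ (mu - yy) / n
        grad_b = float(np.mean(mu - yy))
        w = w - step * grad_w
        b -= step * grad_b
        w = np.sign(w) * np.maximum(np.abs(w) - step * gamma, 0.0)
    return np.abs(w)


def mcfs(X: np.ndarray, y: np.ndarray | None = None, n_clusters: int = 5,
         n_neighbors: int = 5, n_nonzero: int = 10) -> np.ndarray:
    """Multi-cluster selection: spectral embedding on a 5-NN heat-kernel
    graph, then per-eigenvector sparse (LARS) regression; each feature
    scores its largest absolute coefficient across eigenvectors."""
    X = _standardize(X)
    W = _knn_heat_graph(X, n_neighbors)
    d = np.maximum(W.sum(axis=1), _EPS)
    d_isqrt = 1.0 / np.sqrt(d)
    S = d_isqrt[:, None] * W * d_isqrt[None, :]
    vals, vecs = sla.eigh(S)
    k = min(n_clusters, len(vals) - 1)
    emb = d_isqrt[:, None] * vecs[:, ::-1][:, 1:k + 1]   # skip trivial vector
    scores = np.zeros(X.shape[1])
    nnz = min(n_nonzero, X.shape[1])
    for c in range(emb.shape[1]):
        reg = Lars(n_nonzero_coefs=nnz)
        reg.fit(X, emb[:, c])
        scores = np.maximum(scores, np.abs(reg.coef_))
    return scores


def ndfs(X: np.ndarray, y: np.ndarray | None = None, n_clusters: int = 5,
         n_neighbors: int = 5, gamma: float = 1.0, beta: float = 1.0,
         alpha: float = 1e6, n_iter: int = 30) -> np.ndarray:
    """Nonnegative discriminative selection: alternating updates of a
    nonnegative spectral indicator F and an l2,1-regularized projection W;
    scores are row norms of W."""
    X = _standardize(X)
    n, p = X.shape
    A = _knn_heat_graph(X, n_neighbors)
    d = A.sum(axis=1)
    L = np.diag(d) - A
    k = min(n_clusters, n - 1)
    # init F from the smallest Laplacian eigenvectors, made nonnegative
    _, vecs = sla.eigh(L)
    F = np.abs(vecs[:, :k]) + 1e-3
    dvec = np.ones(p)
    for _ in range(n_iter):
        Minv = np.linalg.solve(X.T @ X + gamma * np.diag(dvec), X.T)
        W = Minv @ F
        dvec = 1.0 / (2.0 * np.maximum(_row_norm_weights(W), _EPS))
        M = L + beta * (np.eye(n) - X @ Minv)
        FF = F @ (F.T @ F)
        F = F * np.sqrt((alpha * F) / np.maximum(M @ F + alpha * FF, _EPS))
        F = np.maximum(F, _EPS)
    return _row_norm_weights(W)


def udfs(X: np.ndarray, y: np.ndarray | None = None, n_clusters: int = 5,
         n_neighbors: int = 5, gamma: float = 0.1,
         n_iter: int = 20) -> np.ndarray:
    """l2,1-regularized orthogonal projection minimizing local scatter
    (graph-Laplacian form): W = argmin tr(W'(X'LX + gamma*D)W), W'W = I,
    iterating the reweighting matrix D; scores are row norms of W."""
    X = _standardize(X)
    A = _knn_heat_graph(X, n_neighbors)
    L = np.diag(A.sum(axis=1)) - A
    M = X.T @ L @ X
    p = X.shape[1]
    k = min(n_clusters, p)
    dvec = np.ones(p)
    W = None
    for _ in range(n_iter):
        _, vecs = sla.eigh(M + gamma * np.diag(dvec))
        W = vecs[:, :k]
        dvec = 1.0 / (2.0 * np.maximum(_row_norm_weights(W), _EPS))
    return _row_norm_weights(W)


def trace_ratio(X: np.ndarray, y: np.ndarray, n_selected: int = 10,
                n_iter: int = 50) -> np.ndarray:
    """Iterative trace-ratio criterion on per-feature class scatters.

    a_f = between-class scatter, b_f = within-class scatter; iterates
    lambda = sum(a_S)/sum(b_S) over the current top set S and re-scores
    features by a_f - lambda*b_f until the selected set is stable.
    """
    m = X.mean(axis=0)
    a = np.zeros(X.shape[1])
    b = np.zeros(X.shape[1])
    for c in np.unique(y):
        Xc = X[y == c]
        nc = len(Xc)
        a += nc * (Xc.mean(axis=0) - m) ** 2
        b += nc * Xc.var(axis=0)
    b = np.maximum(b, _EPS)
    k = min(n_selected, X.shape[1])
    sel = top_k(a / b, k)
    for _ in range(n_iter):
        lam = a[sel].sum() / b[sel].sum()
        scores = a - lam * b
        new_sel = top_k(scores, k)
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel
    lam = a[sel].sum() / b[sel].sum()
    return a - lam * b


# ----------------------------------------------------------------- registry

SELECTORS: dict[str, callable] = {
    "F_score": f_score,
    "T_score": t_score,
    "DISR": disr,
    "Fisher": fisher_score,
    "ICAP": icap,
    "JMI": jmi,
    "Laplacian": laplacian_score,
    "LL_l21": ll_l21,
    "LS_l21": ls_l21,
    "MCFS": mcfs,
    "NDFS": ndfs,
    "reliefF": relieff,
    "TraceRatio": trace_ratio,
    "UDFS": udfs,
}

SELECTOR_IDS: list[str] = sorted(SELECTORS)

SUPERVISED_SELECTORS = {"F_score", "T_score", "DISR", "Fisher", "ICAP",
                        "JMI", "LL_l21", "LS_l21", "reliefF", "TraceRatio"}


def score_features(selector_id: str, X: np.ndarray, y: np.ndarray,
                   **hyper) -> np.ndarray:
    """Score all features on training data; higher = more relevant."""
    if selector_id not in SELECTORS:
        raise KeyError(f"unknown selector {selector_id!r}")
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("selectors require complete data; impute first")
    scores = np.asarray(SELECTORS[selector_id](X, np.asarray(y), **hyper),
                        dtype=float)
    if scores.shape != (X.shape[1],):
        raise RuntimeError(f"{selector_id} returned wrong score shape")
    return np.nan_to_num(scores, nan=0.0, posinf=1e300, neginf=-1e300)


def top_k(scores: np.ndarray, k: int = 10) -> np.ndarray:
    """Indices of the k largest scores, descending; ties broken by
    ascending feature index."""
    if k <= 0:
        raise ValueError("k must be positive")
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError("k exceeds number of features")
    order = np.argsort(-scores, kind="stable")
    return order[:k]
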