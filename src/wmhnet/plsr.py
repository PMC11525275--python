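"""Multivariate-outcome partial least squares regression on vectorized connectomes.

Predictors are the 30135 unique edges of a 246-node connectome; outcomes are
age, fluid cognition, and (log) global WMH jointly.  The fit is SIMPLS on
column-centered X and Y with no variance scaling (the plsregress convention),
component count is chosen by k-fold cross-validation minimising CV-MSEP, and
feature importance is the cross-validated mean absolute beta weight per edge,
summed over incident edges per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EdgeMap",
    "PLSRModel",
    "CVResult",
    "ImportanceTable",
    "fit_plsr",
    "predict",
    "select_components_cv",
    "fit_fold_models",
    "feature_importance",
    "per_outcome_r2",
]


class EdgeMap:
    """Canonical bijection between a symmetric matrix and its edge vector.

    Edges are the off-diagonal upper triangle in strictly lexicographic
    (row-major) order: (0,1), (0,2), ..., (n-2, n-1).
    """

    def __init__(self, n_nodes: int = 246):
        self.n_nodes = int(n_nodes)
        self.rows, self.cols = np.triu_indices(self.n_nodes, k=1)

    def __len__(self) -> int:
        return self.rows.size

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))

    def vectorize(self, matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(f"expected {(self.n_nodes, self.n_nodes)} matrix, got {matrix.shape}")
        if np.abs(matrix - matrix.T).max() > atol:
            raise ValueError("matrix is asymmetric beyond tolerance")
        return matrix[self.rows, self.cols]

    def devectorize(self, vector: np.ndarray) -> np.ndarray:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(self),):
            raise ValueError(f"expected vector of length {len(self)}, got {vector.shape}")
        M = np.zeros((self.n_nodes, self.n_nodes))
        M[self.rows, self.cols] = vector
        return M + M.T

    def stack(self, matrices: np.ndarray) -> np.ndarray:
        """Vectorize a (n, nodes, nodes) stack into an (n, m) predictor matrix."""
        return np.asarray(matrices)[:, self.rows, self.cols]


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray            # (m,)
    y_mean: np.ndarray            # (p,)
    x_weights: np.ndarray         # R: (m, A)
    x_loadings: np.ndarray        # P: (m, A)
    y_loadings: np.ndarray        # Q: (p, A)
    coef: np.ndarray = field(init=False)       # B: (m, p)
    intercept: np.ndarray = field(init=False)  # (p,)

    def __post_init__(self):
        self.coef = self.x_weights @ self.y_loadings.T
        self.intercept = self.y_mean - self.x_mean @ self.coef

    def coef_at(self, a: int) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients/intercept using only the first ``a`` components."""
        B = self.x_weights[:, :a] @ self.y_loadings[:, :a].T
        return B, self.y_mean - self.x_mean @ B

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        B, b0 = self.coef_at(a)
        return np.asarray(X, dtype=float) @ B + b0


def fit_plsr(
    X: np.ndarray, Y: np.ndarray, n_components: int, standardize_y: bool = False
) -> PLSRModel:
    """SIMPLS fit on column-centered X (n x m) and Y (n x p).

    X and Y are column-centered, never variance-scaled, matching the
    plsregress convention; ``standardize_y`` divides each outcome column by
    its sample SD first (useful when |beta| magnitudes must be comparable
    across outcomes on different scales), in which case the model predicts
    standardized outcomes.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if standardize_y:
        sd = Y.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant outcome column cannot be standardized")
        Y = Y / sd
    n, m = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported")
    A = int(n_components)
    if A < 1 or A > min(n - 1, m):
        raise ValueError(f"n_components must be in [1, min(n-1, m)] = [1, {min(n - 1, m)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean
    p = Y0.shape[1]

    S = X0.T @ Y0  # (m, p)
    R = np.zeros((m, A))
    P = np.zeros((m, A))
    Q = np.zeros((p, A))
    V = np.zeros((m, A))
    for a in range(A):
        # dominant right singular vector of S from the small p x p problem
        evals, evecs = np.linalg.eigh(S.T @ S)
        q = evecs[:, -1]
        r = S @ q
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValueError(
                f"requested {A} components but X/Y support at most {a} "
                "(score collapsed to zero)"
            )
        t /= normt
        r /= normt
        P[:, a] = X0.T @ t
        Q[:, a] = Y0.T @ t
        v = P[:, a].copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ v)
            v -= V[:, :a] @ (V[:, :a].T @ v)  # re-orthogonalize
        v /= np.linalg.norm(v)
        V[:, a] = v
        S = S - v[:, None] @ (v[None, :] @ S)
        R[:, a] = r
    return PLSRModel(A, x_mean, y_mean, R, P, Q)


def predict(model: PLSRModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    return model.predict(X, n_components)


@dataclass
class CVResult:
    k: int
    a_max: int
    fold_labels: np.ndarray          # (n,)
    cv_msep: np.ndarray              # (a_max,) summed over outcomes, per held-out obs
    cv_pctvar: np.ndarray            # (a_max,)
    baseline_mse: float              # sum of outcome sample variances
    chosen_a: int
    per_outcome_r2: np.ndarray       # (p,) at chosen_a, assembled held-out predictions
    y_hat_cv: np.ndarray             # (n, p) held-out predictions at chosen_a


def select_components_cv(
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 5,
    a_max: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Choose the PLSR component count by k-fold cross-validation.

    Folds are a seeded unstratified random partition of near-equal size.  For
    each candidate component count the held-out predictions are assembled
    across folds; CV-MSEP is the squared error summed over outcomes and
    averaged over observations, CV-PCTVAR = 100 * (1 - CV-MSEP / baseline)
    with baseline the sum of the raw outcome sample variances.  Ties in
    CV-MSEP resolve to the smaller component count.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    if n < 2 * k:
        raise ValueError(f"need n >= 2k observations for {k}-fold CV (n={n})")
    if rng is None:
        rng = np.random.default_rng(seed)
    fold_labels = rng.permutation(np.resize(np.arange(k), n))
    min_train = min(n - int((fold_labels == f).sum()) for f in range(k))
    a_max = int(min(a_max, min_train - 1, m))

    y_hat = np.zeros((a_max, n, Y.shape[1]))
    for f in range(k):
        test = fold_labels == f
        model = fit_plsr(X[~test], Y[~test], a_max)
        for a in range(1, a_max + 1):
            y_hat[a - 1][test] = model.predict(X[test], a)

    sse = ((Y[None, :, :] - y_hat) ** 2).sum(axis=(1, 2))
    cv_msep = sse / n
    baseline = float(Y.var(axis=0, ddof=1).sum())
    cv_pctvar = 100.0 * (1.0 - cv_msep / baseline)
    chosen = int(np.argmin(cv_msep)) + 1
    yh = y_hat[chosen - 1]
    r2 = per_outcome_r2(Y, yh)
    return CVResult(k, a_max, fold_labels, cv_msep, cv_pctvar, baseline, chosen, r2, yh)


def fit_fold_models(
    X: np.ndarray, Y: np.ndarray, n_components: int, fold_labels: np.ndarray
) -> list[PLSRModel]:
    """Refit one PLSR model per training fold at a fixed component count."""
    return [
        fit_plsr(X[fold_labels != f], np.asarray(Y)[fold_labels != f], n_components)
        for f in np.unique(fold_labels)
    ]


@dataclass
class ImportanceTable:
    edges: pd.DataFrame          # i, j, importance (mean |beta|), rank
    rois: pd.DataFrame           # node_id, name, importance (incident sum), rank
    per_outcome: np.ndarray      # (m, p) mean-over-folds |beta| per outcome

    def top_edges(self, fraction: float) -> pd.DataFrame:
        k = max(1, int(round(fraction * len(self.edges))))
        return self.edges.nsmallest(k, "rank")

    def top_rois(self, fraction: float) -> pd.DataFrame:
        k = max(1, int(round(fraction * len(self.rois))))
        return self.rois.nsmallest(k, "rank")


def feature_importance(
    models: list[PLSRModel], edge_map: EdgeMap, atlas: pd.DataFrame
) -> ImportanceTable:
    """Cross-validated edge and ROI importance from per-fold beta weights.

    Edge importance is the mean over folds of |B| averaged across outcome
    columns; ROI importance is the sum of importances over incident edges.
    """
    if not models:
        raise ValueError("empty model list")
    m = len(edge_map)
    for model in models:
        if model.coef.shape[0] != m:
            raise ValueError("model coefficient length does not match edge_map")
    abs_b = np.mean([np.abs(model.coef) for model in models], axis=0)  # (m, p)
    edge_imp = abs_b.mean(axis=1)

    roi_imp = np.zeros(edge_map.n_nodes)
    np.add.at(roi_imp, edge_map.rows, edge_imp)
    np.add.at(roi_imp, edge_map.cols, edge_imp)

    edges = pd.DataFrame({"i": edge_map.rows, "j": edge_map.cols, "importance": edge_imp})
    edges["rank"] = edges["importance"].rank(ascending=False, method="first").astype(int)
    atlas_sorted = atlas.sort_values("node_id")
    rois = pd.DataFrame(
        {
            "node_id": atlas_sorted["node_id"].to_numpy(),
            "name": atlas_sorted["name"].to_numpy(),
            "importance": roi_imp,
        }
    )
    rois["rank"] = rois["importance"].rank(ascending=False, method="first").astype(int)
    return ImportanceTable(edges, rois, abs_b)


def per_outcome_r2(Y: np.ndarray, Y_hat: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each outcome with its prediction."""
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.ndim == 1:
        Y, Y_hat = Y[:, None], Y_hat[:, None]
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch between Y and Y_hat")
    out = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        if np.ptp(Y[:, j]) == 0 or np.ptp(Y_hat[:, j]) == 0:
            raise ValueError(f"constant column {j}: correlation undefined")
        out[j] = np.corrcoef(Y[:, j], Y_hat[:, j])[0, 1] ** 2
    return out
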