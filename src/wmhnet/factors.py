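"""Principal-axis factor scores for the cognitive battery.

The fluid-cognition summary is the first unrotated factor of the 12-test
battery after residualizing every test on vocabulary and sex; domain scores
repeat the same algorithm on each 4-test domain.  Factor scores use the
regression (Thurstone) method by default, with Bartlett as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import DOMAINS, TEST_COLUMNS

__all__ = [
    "FactorResult",
    "ConvergenceError",
    "residualize",
    "principal_axis_factor",
    "domain_scores",
    "fluid_factor",
    "DEFAULT_DOMAIN_MAP",
]

DEFAULT_DOMAIN_MAP = {col: col[:-1] for col in TEST_COLUMNS}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FactorResult:
    loadings: np.ndarray       # (p,) first unrotated factor
    communalities: np.ndarray  # (p,)
    factor_scores: np.ndarray  # (n,) standardized, mean 0
    n_iter: int


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"col{i}" for i in range(arr.shape[1])]


def residualize(columns, covariates) -> np.ndarray:
    """OLS-residualize each column on [intercept, covariates].

    Residuals are exactly uncorrelated with every covariate.  Raises on
    rank-deficient covariate sets, naming the collinear columns.
    """
    Y, _ = _as_matrix(columns)
    C, cov_names = _as_matrix(covariates)
    n = Y.shape[0]
    if C.shape[0] != n:
        raise ValueError("columns and covariates must have the same number of rows")
    if np.isnan(Y).any() or np.isnan(C).any():
        raise ValueError("missing values are not supported")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending covariates by incremental rank
        bad = []
        kept = np.ones((n, 1))
        for k, name in enumerate(cov_names):
            cand = np.column_stack([kept, C[:, k]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"rank-deficient covariates (collinear with the rest): {bad}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def principal_axis_factor(
    scores,
    n_factors: int = 1,
    max_iter: int = 100,
    tol: float = 1e-6,
    score_method: str = "regression",
) -> FactorResult:
    """Iterated principal-axis factoring of a test battery.

    Communalities start at squared multiple correlations and are iterated by
    replacing the correlation-matrix diagonal until the largest communality
    change falls below ``tol``.  The returned factor is sign-oriented so the
    first test loads non-negatively; Heywood communalities (> 1) are clipped
    with a warning.
    """
    Z, _ = _as_matrix(scores)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need more observations than tests (n={n}, p={p})")
    sd = Z.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance column; correlation matrix undefined")
    Zs = (Z - Z.mean(axis=0)) / sd
    R = np.corrcoef(Zs, rowvar=False)

    Rinv = np.linalg.inv(R)
    h = 1.0 - 1.0 / np.diag(Rinv)  # squared multiple correlations
    last_delta = np.inf
    for it in range(1, max_iter + 1):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        evals, evecs = np.linalg.eigh(Rh)
        order = np.argsort(evals)[::-1][:n_factors]
        lam = np.clip(evals[order], 0.0, None)
        L = evecs[:, order] * np.sqrt(lam)
        h_new = (L**2).sum(axis=1)
        if (h_new > 1).any():
            warnings.warn("Heywood case: communality > 1 clipped", RuntimeWarning)
            h_new = np.minimum(h_new, 1 - 1e-6)
        last_delta = float(np.max(np.abs(h_new - h)))
        h = h_new
        if last_delta < tol:
            break
    else:
        raise ConvergenceError(
            f"principal-axis iteration did not converge in {max_iter} iterations "
            f"(last communality change {last_delta:.3g})"
        )

    loadings = L[:, 0]
    if loadings[0] < 0:
        L = -L
        loadings = L[:, 0]

    if score_method == "regression":
        F = Zs @ (np.linalg.solve(R, L))
    elif score_method == "bartlett":
        psi = np.clip(1.0 - h, 1e-8, None)
        Lp = L / psi[:, None]
        F = Zs @ Lp @ np.linalg.inv(L.T @ Lp)
    else:
        raise ValueError(f"unknown score_method {score_method!r}")
    scores1 = F[:, 0]
    scores1 = (scores1 - scores1.mean()) / scores1.std(ddof=1)
    return FactorResult(loadings, h, scores1, it)


def domain_scores(
    scores: pd.DataFrame,
    domain_map: dict[str, str] | None = None,
    score_method: str = "regression",
) -> pd.DataFrame:
    """First-factor score per cognitive domain (4 tests each, 3 domains)."""
    domain_map = domain_map or DEFAULT_DOMAIN_MAP
    domains: dict[str, list[str]] = {}
    for test, d in domain_map.items():
        domains.setdefault(d, []).append(test)
    if len(domains) != 3 or any(len(v) != 4 for v in domains.values()):
        raise ValueError(
            "domain_map must assign the 12 tests to exactly 3 domains of 4 tests each; "
            f"got {dict((k, len(v)) for k, v in domains.items())}"
        )
    out = {}
    for d, cols in domains.items():
        res = principal_axis_factor(scores[cols], score_method=score_method)
        out[d] = res.factor_scores
    return pd.DataFrame(out, index=scores.index)


def fluid_factor(
    phenotypes: pd.DataFrame,
    test_cols: tuple[str, ...] = TEST_COLUMNS,
    covariate_cols: tuple[str, ...] = ("vocabulary", "sex"),
    score_method: str = "regression",
) -> pd.DataFrame:
    """Fluid-cognition and domain factor scores, controlling for covariates.

    Test scores are residualized on [vocabulary, sex] before factoring; the
    general factor is the first unrotated principal-axis factor of all 12
    residualized tests.  Returns the phenotype table with ``fluid``, and
    per-domain score columns appended.
    """
    tests = pd.DataFrame(
        residualize(phenotypes[list(test_cols)], phenotypes[list(covariate_cols)]),
        columns=list(test_cols),
        index=phenotypes.index,
    )
    general = principal_axis_factor(tests, score_method=score_method)
    doms = domain_scores(tests, score_method=score_method)
    out = phenotypes.copy()
    out["fluid"] = general.factor_scores
    for d in DOMAINS:
        out[f"{d}_score"] = doms[d]
    return out
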