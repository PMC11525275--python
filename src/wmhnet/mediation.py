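"""Simple and parallel-mediator models with bootstrap confidence intervals.

Paths are estimated by OLS on unstandardized variables (age in years): each
mediator on [1, x]; the outcome on [1, x, mediators].  The indirect effect of
mediator i is a_i * b_i with percentile bootstrap CIs from case resampling.
An indirect effect is flagged significant when its CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MediationResult", "mediate", "bootstrap_ci"]


@dataclass
class MediationResult:
    mediator_names: list[str]
    direct: dict          # c': b, se, z, p
    total: dict           # c: b
    indirect: list[dict]  # per mediator: point, se, z, p, ci_low, ci_high, significant
    n_boot: int
    seed: int | None
    level: float

    @property
    def total_indirect(self) -> float:
        return float(sum(e["point"] for e in self.indirect))


def _paths(x: np.ndarray, M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Return (a, b, c_prime, c_total) OLS path coefficients."""
    n = x.size
    X1 = np.column_stack([np.ones(n), x])
    A = np.linalg.lstsq(X1, M, rcond=None)[0]  # (2, K)
    a = A[1]
    X2 = np.column_stack([np.ones(n), x, M])
    coef = np.linalg.lstsq(X2, y, rcond=None)[0]
    c_prime = coef[1]
    b = coef[2:]
    c_total = np.linalg.lstsq(X1, y, rcond=None)[0][1]
    return a, b, float(c_prime), float(c_total)


def _batched_paths(x, M, y, idx) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (a_i * b_i, c') over bootstrap index matrix idx (B, n)."""
    B, n = idx.shape
    K = M.shape[1]
    xb = x[idx]                      # (B, n)
    Mb = M[idx]                      # (B, n, K)
    yb = y[idx]                      # (B, n)
    ones = np.ones((B, n))
    X1 = np.stack([ones, xb], axis=2)                 # (B, n, 2)
    X2 = np.concatenate([X1, Mb], axis=2)             # (B, n, 2+K)

    G1 = np.einsum("bni,bnj->bij", X1, X1)
    a = np.linalg.solve(G1, np.einsum("bni,bnk->bik", X1, Mb))[:, 1, :]  # (B, K)
    G2 = np.einsum("bni,bnj->bij", X2, X2)
    coef = np.linalg.solve(G2, np.einsum("bni,bn->bi", X2, yb)[..., None])[..., 0]
    c_prime = coef[:, 1]
    b = coef[:, 2:]
    return a * b, c_prime


def mediate(
    x,
    mediators,
    y,
    n_boot: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
    mediator_names: list[str] | None = None,
) -> MediationResult:
    """Bootstrap mediation of x -> mediators -> y (parallel if K > 1).

    z-statistics are point / bootstrap-SE with two-sided normal p-values;
    confidence intervals are percentile (2.5/97.5 at level 0.95).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    M = np.asarray(mediators, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, K = M.shape
    if x.size != n or y.size != n:
        raise ValueError("x, mediators and y must share the number of rows")
    if np.isnan(x).any() or np.isnan(M).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if n <= K + 3:
        raise ValueError(f"need n > K + 3 observations (n={n}, K={K})")
    design = np.column_stack([np.ones(n), x, M])
    if np.ptp(x) == 0 or (np.ptp(M, axis=0) == 0).any() or np.ptp(y) == 0:
        raise ValueError("constant column in x, mediators or y")
    if np.linalg.cond(design) > 1e10:
        raise ValueError("collinear mediators (design condition number > 1e10)")
    if mediator_names is None:
        mediator_names = [f"m{i + 1}" for i in range(K)]

    a, b, c_prime, c_total = _paths(x, M, y)
    point = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_ind, boot_cprime = _batched_paths(x, M, y, idx)

    alpha = (1.0 - level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]

    def zp(pt: float, se: float) -> tuple[float, float]:
        if se == 0:
            return float("inf") if pt != 0 else 0.0, 0.0 if pt != 0 else 1.0
        z = pt / se
        return float(z), float(2 * stats.norm.sf(abs(z)))

    indirect = []
    for i in range(K):
        lo, hi = np.percentile(boot_ind[:, i], qs)
        se = float(boot_ind[:, i].std(ddof=1))
        z, p = zp(float(point[i]), se)
        indirect.append(
            {
                "name": mediator_names[i],
                "point": float(point[i]),
                "se": se,
                "z": z,
                "p": p,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    se_c = float(boot_cprime.std(ddof=1))
    zc, pc = zp(c_prime, se_c)
    direct = {"b": c_prime, "se": se_c, "z": zc, "p": pc}
    return MediationResult(mediator_names, direct, {"b": c_total}, indirect, n_boot, seed, level)


def bootstrap_ci(
    statistic,
    data,
    n_boot: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Seeded case-resampling percentile interval for an arbitrary statistic.

    ``data`` is indexed along its first axis.  A resample on which the
    statistic raises is redrawn; more than 1% failures aborts.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    failures = 0
    max_failures = max(1, int(0.01 * n_boot))
    i = 0
    while i < n_boot:
        sample = data[rng.integers(0, n, size=n)]
        try:
            draws[i] = statistic(sample)
        except Exception:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"statistic failed on more than 1% of resamples ({failures} failures)"
                )
            continue
        i += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), float(draws.std(ddof=1))
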