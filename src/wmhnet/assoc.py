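"""Zero-order / partial correlations, FDR control, and the power calculation.

All WMH volumes are natural-log transformed before correlation (the
age-related rise in WMH volume is multiplicative).  FDR families are always
explicit: every row of a correlation table carries its ``family_id`` and
adjustment happens strictly within family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_wmh",
    "pearson",
    "partial_correlation",
    "bh_fdr",
    "power_pearson",
    "correlation_table",
]


def log_wmh(volumes, offset: float = 0.0) -> np.ndarray:
    """Natural log of WMH volumes (mm^3); volumes must be strictly positive.

    Generated data are positive by construction; for real tables containing
    zeros pass an explicit ``offset`` to be added before the log.
    """
    v = np.asarray(volumes, dtype=float) + offset
    if (v <= 0).any():
        raise ValueError(
            "non-positive WMH volume; volumes from the generator are strictly "
            "positive — for external data pass an explicit offset"
        )
    return np.log(v)


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 4) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with the two-sided t-test p-value; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of the OLS residuals of x and y on the covariates.

    The p-value uses t with n - 2 - c degrees of freedom (c covariates).
    With no covariates this is the plain Pearson correlation.
    """
    from .factors import residualize  # late import to avoid cycle

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        r, p, _ = pearson(x, y)
        return r, p
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    c = C.shape[1]
    n = x.size
    if n <= c + 3:
        raise ValueError(f"need n > c + 3 observations (n={n}, c={c})")
    rx = residualize(x[:, None], C)[:, 0]
    ry = residualize(y[:, None], C)[:, 0]
    # a residual that is numerically zero (input in the covariate span) is a
    # degenerate contract violation, not a NaN
    if rx.std() <= 1e-10 * max(x.std(), 1e-300) or ry.std() <= 1e-10 * max(y.std(), 1e-300):
        raise ValueError("constant input: residual lies in the covariate span")
    _check_pair(rx, ry)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def power_pearson(r: float, n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Power to detect a Pearson correlation via the Fisher-z approximation.

    With lambda = atanh(r) * sqrt(n - 3) and z_c the critical value, the
    two-sided power is Phi(lambda - z_c) + Phi(-lambda - z_c).
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lam = np.arctanh(r) * np.sqrt(n - 3)
    if two_sided:
        zc = stats.norm.ppf(1 - alpha / 2)
        return float(stats.norm.cdf(lam - zc) + stats.norm.cdf(-lam - zc))
    zc = stats.norm.ppf(1 - alpha)
    return float(stats.norm.cdf(lam - zc))


def correlation_table(data: pd.DataFrame, pairs: list[dict]) -> pd.DataFrame:
    """Zero-order / partial correlation table with within-family FDR.

    ``pairs`` is a list of dicts with keys ``x``, ``y``, optional
    ``covariates`` (list of column names) and ``family`` (FDR family id;
    defaults to "default").  Returns rows of
    (x_name, y_name, n, r, p, p_fdr, family_id).
    """
    rows = []
    for pair in pairs:
        x = data[pair["x"]].to_numpy(dtype=float)
        y = data[pair["y"]].to_numpy(dtype=float)
        covs = pair.get("covariates") or []
        if covs:
            r, p = partial_correlation(x, y, data[list(covs)].to_numpy(dtype=float))
        else:
            r, p, _ = pearson(x, y)
        rows.append(
            {
                "x_name": pair["x"],
                "y_name": pair["y"],
                "n": len(x),
                "r": r,
                "p": p,
                "family_id": pair.get("family", "default"),
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for fam, idx in table.groupby("family_id").groups.items():
        table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    return table[["x_name", "y_name", "n", "r", "p", "p_fdr", "family_id"]]
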