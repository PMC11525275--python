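"""Subnetwork edge masks and the 80/20 resampling framework with permuted nulls.

Each subnetwork model restricts the predictors to one edge mask (within the
subcortical network, or between it and one of the seven cortical intrinsic
networks).  Model significance is judged against an empirical null built by
jointly permuting the outcome rows on every iteration, summarised by the
two-sample Kolmogorov-Smirnov statistic and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plsr import EdgeMap, fit_plsr, select_components_cv

__all__ = [
    "build_masks",
    "ResampleResult",
    "resample_evaluate",
    "effect_size",
    "summarize",
    "CORTICAL_NETWORKS",
]

CORTICAL_NETWORKS = ("DMN", "DAN", "FPN", "LN", "SMN", "VAN", "VIS")


def build_masks(atlas: pd.DataFrame, edge_map: EdgeMap) -> dict[str, np.ndarray]:
    """SUB-SUB plus the seven SUB-to-cortical-network boolean edge masks."""
    network = atlas.sort_values("node_id")["network"].to_numpy()
    if len(network) != edge_map.n_nodes:
        raise ValueError("atlas node count does not match edge map")
    is_sub = network == "SUB"
    if not is_sub.any():
        raise ValueError("atlas contains no SUB (subcortical) nodes")
    i, j = edge_map.rows, edge_map.cols
    masks: dict[str, np.ndarray] = {"SUB-SUB": is_sub[i] & is_sub[j]}
    sub_cortical = is_sub[i] ^ is_sub[j]
    for net in CORTICAL_NETWORKS:
        in_net = network == net
        masks[f"SUB-{net}"] = sub_cortical & (in_net[i] | in_net[j])
    return masks


@dataclass
class ResampleResult:
    name: str
    true_perf: np.ndarray
    null_perf: np.ndarray
    ks_stat: float
    ks_p: float
    cohens_d: float
    median_true: float
    pi_low: float
    pi_high: float
    n_iter: int
    seed: int | None

    def summary(self) -> dict:
        return {
            "name": self.name,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
            "cohens_d": self.cohens_d,
            "median_true": self.median_true,
            "pi_low": self.pi_low,
            "pi_high": self.pi_high,
            "n_iter": self.n_iter,
        }


def _split_fit_score(
    X: np.ndarray,
    Y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    inner_k: int,
    a_max: int,
    rng: np.random.Generator,
) -> float:
    cv = select_components_cv(X[train], Y[train], k=inner_k, a_max=a_max, rng=rng)
    model = fit_plsr(X[train], Y[train], cv.chosen_a)
    y_hat = model.predict(X[test])
    rs = []
    for jcol in range(Y.shape[1]):
        y, yh = Y[test, jcol], y_hat[:, jcol]
        if np.ptp(y) == 0 or np.ptp(yh) == 0:
            rs.append(0.0)
        else:
            rs.append(np.corrcoef(y, yh)[0, 1])
    return float(np.mean(rs))


def resample_evaluate(
    X: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    n_iter: int = 5000,
    train_frac: float = 0.8,
    inner_k: int = 5,
    a_max: int = 10,
    seed: int | None = None,
    name: str = "mask",
) -> ResampleResult:
    """80/20 train/test resampling of a masked PLSR model with permuted nulls.

    Per iteration: random split; inner k-fold CV on the training set selects
    the component count; performance on the test set is the mean over
    outcomes of Pearson r(y, y_hat).  The null twin repeats the whole
    procedure with the outcome rows jointly permuted (a fresh permutation
    each iteration), preserving the outcome inter-correlations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty edge mask")
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    Xm = X[:, mask]
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)

    true_perf = np.empty(n_iter)
    null_perf = np.empty(n_iter)
    for it in range(n_iter):
        order = rng.permutation(n)
        train, test = order[:n_train], order[n_train:]
        true_perf[it] = _split_fit_score(Xm, Y, train, test, inner_k, a_max, rng)
        Y_null = Y[rng.permutation(n)]
        null_perf[it] = _split_fit_score(Xm, Y_null, train, test, inner_k, a_max, rng)

    ks_stat, ks_p, d = effect_size(true_perf, null_perf)
    med, lo, hi = summarize(true_perf, min_size=min(40, n_iter))
    return ResampleResult(
        name, true_perf, null_perf, ks_stat, ks_p, d, med, lo, hi, n_iter, seed
    )


def effect_size(true_perf, null_perf) -> tuple[float, float, float]:
    """Two-sample KS statistic/p and Cohen's d between true and null draws."""
    a = np.asarray(true_perf, dtype=float)
    b = np.asarray(null_perf, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 draws per sample")
    ks = stats.ks_2samp(a, b, method="asymp")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return float(ks.statistic), float(ks.pvalue), 0.0
        raise ValueError("zero pooled SD with unequal means: Cohen's d undefined")
    d = (a.mean() - b.mean()) / pooled
    return float(ks.statistic), float(ks.pvalue), float(d)


def summarize(true_perf, min_size: int = 40) -> tuple[float, float, float]:
    """Median and empirical 95% prediction interval (2.5/97.5 percentiles).

    Percentiles use linear interpolation between order statistics.
    """
    a = np.asarray(true_perf, dtype=float)
    if a.size < min_size:
        raise ValueError(f"need at least {min_size} draws for a stable interval")
    lo, med, hi = np.percentile(a, [2.5, 50, 97.5])
    return float(med), float(lo), float(hi)
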