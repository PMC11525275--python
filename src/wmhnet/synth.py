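"""Synthetic cohort generator.

Emulates the joint statistical structure of a healthy-aging connectome study:
three age cohorts, a general fluid-cognition factor declining with age,
log-normal white-matter-hyperintensity (WMH) volumes rising with age, a
12-test cognitive battery organised in three correlated domains, tract-level
WMH covariates, and per-subject 246-node streamline-count connectomes in
which WMH burden attenuates subcortical-subcortical and subcortical-cortical
connections.

The generative model is a single-latent-exposure design.  With ``z`` the
standardized age, the fluid factor is ``g = rho_ag*z + sqrt(1-rho_ag^2)*eps``
and the WMH exposure is ``w = alpha*z + beta*(-g) + gamma*e`` with
``(alpha, beta)`` solved in closed form so that corr(z, w) and corr(g, w) hit
their targets and ``gamma`` normalising var(w) = 1.  Domain factors load on
``g`` with loadings recovered from the three pairwise domain correlations via
the triad identities ``a_i * a_j = r_ij``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimConfig",
    "Loadings",
    "CalibrationError",
    "ConnectomeSet",
    "make_atlas",
    "solve_latent_loadings",
    "simulate_phenotypes",
    "simulate_connectomes",
    "apply_streamline_threshold",
    "write_dataset",
    "LOBES",
    "NETWORKS",
    "DOMAINS",
    "TEST_COLUMNS",
    "TRACTS",
]


class CalibrationError(ValueError):
    """Raised when the requested correlation targets are unattainable."""


LOBES = ("Frontal", "Temporal", "Parietal", "Insular", "Limbic", "Occipital", "Subcortical")
LOBE_SIZES = {
    "Frontal": 70,
    "Temporal": 40,
    "Parietal": 38,
    "Insular": 12,
    "Limbic": 14,
    "Occipital": 36,
    "Subcortical": 36,
}
NETWORKS = ("DMN", "DAN", "FPN", "LN", "SMN", "VAN", "VIS", "SUB")

# Cortical lobe -> {network: node count}.  Each of the 7 cortical networks
# receives exactly 30 of the 210 cortical nodes, with lobe assignments chosen
# to mirror the anatomical concentration of the intrinsic networks (visual in
# occipital cortex, limbic network in the cingulate "limbic lobe", etc.).
_LOBE_NETWORK_COUNTS = {
    "Occipital": {"VIS": 30, "DAN": 6},
    "Limbic": {"LN": 14},
    "Insular": {"VAN": 12},
    "Temporal": {"LN": 10, "DMN": 12, "VAN": 6, "DAN": 8, "SMN": 4},
    "Parietal": {"DAN": 12, "FPN": 10, "SMN": 8, "DMN": 8},
    "Frontal": {"FPN": 20, "SMN": 18, "DMN": 10, "VAN": 12, "DAN": 4, "LN": 6},
}

DOMAINS = ("ef", "ps", "mem")
TEST_COLUMNS = tuple(f"{d}{i}" for d in DOMAINS for i in range(1, 5))
TRACTS = ("uncinate", "forceps_major", "cing1", "atr")

# Log-scale location/scale for the four tract-level WMH volumes (mm^3).  The
# per-tract totals are not printed in the main text; the ordering (anterior
# thalamic radiations carry the heaviest load) follows the reported ranking.
_TRACT_LOG_PARAMS = {
    "uncinate": (4.0, 1.2),
    "forceps_major": (4.6, 1.2),
    "cing1": (3.8, 1.2),
    "atr": (5.2, 1.2),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    cohort_sizes: tuple[int, ...] = (28, 20, 20)
    cohort_age_means: tuple[float, ...] = (28.04, 48.75, 69.15)
    cohort_age_sds: tuple[float, ...] = (5.27, 5.80, 4.61)
    cohort_age_ranges: tuple[tuple[float, float], ...] = ((18, 39), (40, 59), (60, 78))
    rho_age_g: float = -0.859
    rho_age_wmh: float = 0.68
    rho_g_wmh: float = -0.68
    wmh_log_mean: float = 6.11
    wmh_log_sd: float = 1.40
    domain_pair_corrs: tuple[float, float, float] = (0.846, 0.604, 0.557)
    test_loading: float = 0.8
    rho_global_pv: float = 0.99
    rho_global_deep: float = 0.64
    rho_global_k05: float = 0.99
    tract_wmh_loading: float = 0.8
    signal_edge_decay: float = 0.6
    signal_cortical_frac: float = 0.5
    base_density_target: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != len(self.cohort_age_means) or len(
            self.cohort_sizes
        ) != len(self.cohort_age_sds) or len(self.cohort_sizes) != len(self.cohort_age_ranges):
            raise ValueError("cohort parameter tuples must have equal length")
        for name in ("rho_age_g", "rho_age_wmh", "rho_g_wmh"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise CalibrationError(f"{name}={v} must lie in (-1, 1)")
        for v in self.domain_pair_corrs:
            if not -1 < v < 1:
                raise CalibrationError(f"domain pair correlation {v} must lie in (-1, 1)")
        # Fails loudly (never clips) if the implied latent covariance is not PD.
        solve_latent_loadings(self)

    @property
    def n(self) -> int:
        return int(sum(self.cohort_sizes))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Loadings:
    """Closed-form latent loadings implied by a :class:`SimConfig`."""

    alpha: float  # age -> WMH exposure
    beta: float   # (-g) -> WMH exposure
    gamma: float  # residual WMH noise scale
    a_ef: float   # g -> executive-function domain factor
    a_ps: float   # g -> perceptual-speed domain factor
    a_mem: float  # g -> memory domain factor

    @property
    def domain(self) -> dict[str, float]:
        return {"ef": self.a_ef, "ps": self.a_ps, "mem": self.a_mem}


def solve_latent_loadings(config: SimConfig) -> Loadings:
    """Solve the latent loading system implied by the correlation targets.

    With g = r_ag*z + sqrt(1-r_ag^2)*eps and w = alpha*z + beta*(-g) + gamma*e
    the two WMH targets give a 2x2 linear system::

        corr(w, z) = alpha - beta*r_ag      = rho_age_wmh
        corr(w, g) = alpha*r_ag - beta      = rho_g_wmh

    and gamma normalises var(w) = 1.  Domain loadings come from the triad
    identities a_i*a_j = r_ij.
    """
    r_ag = config.rho_age_g
    A = np.array([[1.0, -r_ag], [r_ag, -1.0]])
    rhs = np.array([config.rho_age_wmh, config.rho_g_wmh])
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        raise CalibrationError(
            "degenerate system: rho_age_g = +-1 leaves (rho_age_wmh, rho_g_wmh) unidentified"
        )
    alpha, beta = np.linalg.solve(A, rhs)
    var_struct = alpha**2 + beta**2 - 2 * alpha * beta * r_ag
    if var_struct >= 1.0:
        raise CalibrationError(
            "targets (rho_age_g, rho_age_wmh, rho_g_wmh) = "
            f"({r_ag}, {config.rho_age_wmh}, {config.rho_g_wmh}) imply a "
            "non-positive-definite latent covariance (WMH residual variance <= 0)"
        )
    gamma = float(np.sqrt(1.0 - var_struct))

    r_efps, r_efm, r_psm = config.domain_pair_corrs
    prods = {"ef-ps": r_efps, "ef-mem": r_efm, "ps-mem": r_psm}
    if r_efps * r_efm * r_psm <= 0:
        raise CalibrationError(
            f"domain triad {tuple(prods.values())} has non-positive product; "
            "loadings a_d are not identifiable as reals"
        )
    a_ef = float(np.sqrt(r_efps * r_efm / r_psm))
    a_ps = r_efps / a_ef
    a_mem = r_efm / a_ef
    for name, a in (("ef", a_ef), ("ps", a_ps), ("mem", a_mem)):
        if not abs(a) < 1.0:
            raise CalibrationError(
                f"domain triad {tuple(prods.values())} implies |a_{name}| = {abs(a):.3f} >= 1 "
                "(non-positive-definite domain covariance)"
            )
    return Loadings(float(alpha), float(beta), gamma, a_ef, float(a_ps), float(a_mem))


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def make_atlas(seed: int = 0) -> pd.DataFrame:
    """Seeded fixture atlas: 246 nodes (210 cortical + 36 subcortical).

    Lobe counts are fixed at (Frontal 70, Temporal 40, Parietal 38, Insular
    12, Limbic 14, Occipital 36, Subcortical 36); the seven cortical intrinsic
    networks receive 30 nodes each, subcortical nodes form the SUB network.
    Only node volumes depend on the seed.  A user-supplied atlas TSV with the
    same columns can stand in for this fixture throughout the package.
    """
    rng = np.random.default_rng(seed)
    rows = []
    node_id = 0
    for lobe in LOBES:
        if lobe == "Subcortical":
            labels = ["SUB"] * LOBE_SIZES[lobe]
        else:
            labels = []
            for network, count in _LOBE_NETWORK_COUNTS[lobe].items():
                labels.extend([network] * count)
        for k, network in enumerate(labels):
            hemi = "L" if k % 2 == 0 else "R"
            rows.append(
                {
                    "node_id": node_id,
                    "name": f"{lobe[:3].upper()}_{k:03d}_{hemi}",
                    "hemisphere": hemi,
                    "lobe": lobe,
                    "network": network,
                    "volume_mm3": float(np.exp(rng.normal(7.8, 0.3))),
                }
            )
            node_id += 1
    atlas = pd.DataFrame(rows)
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: pd.DataFrame) -> None:
    required = {"node_id", "name", "hemisphere", "lobe", "network", "volume_mm3"}
    missing = required - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas missing columns: {sorted(missing)}")
    ids = atlas["node_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(len(atlas))):
        raise ValueError("atlas node_ids must be unique and contiguous from 0")
    sub_lobe = atlas["lobe"] == "Subcortical"
    sub_net = atlas["network"] == "SUB"
    if not (sub_lobe == sub_net).all():
        raise ValueError("network must be SUB exactly when lobe is Subcortical")
    if (atlas["volume_mm3"] <= 0).any():
        raise ValueError("node volumes must be positive")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _truncated_ages(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    parts = []
    for size, mu, sd, (lo, hi) in zip(
        config.cohort_sizes, config.cohort_age_means, config.cohort_age_sds, config.cohort_age_ranges
    ):
        if size < 2:
            raise ValueError("each cohort needs at least 2 participants (correlations undefined)")
        a, b = (lo - mu) / sd, (hi - mu) / sd
        parts.append(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng))
    return np.concatenate(parts)


def simulate_phenotypes(config: SimConfig | None = None) -> pd.DataFrame:
    """Draw one cohort-structured phenotype table.

    Returns a DataFrame with demographics, the 12-test battery, global /
    periventricular / deep WMH volumes at both classification thresholds
    (mm^3, strictly positive), tract-level WMH volumes, and the simulation
    ground-truth latents (``latent_g``, ``latent_w``, ``latent_<domain>``),
    which exist only for recovery tests.
    """
    config = config or SimConfig()
    load = solve_latent_loadings(config)
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = _truncated_ages(config, rng)
    z_age = (age - age.mean()) / age.std()

    g = config.rho_age_g * z_age + np.sqrt(1 - config.rho_age_g**2) * rng.standard_normal(n)
    w = load.alpha * z_age - load.beta * g + load.gamma * rng.standard_normal(n)

    data: dict[str, np.ndarray] = {
        "participant_id": np.array([f"sub-{i:03d}" for i in range(n)]),
        "age_years": age,
        "sex": rng.integers(0, 2, size=n),
        "vocabulary": 58.53 + 4.53 * rng.standard_normal(n),
    }

    lam = config.test_loading
    noise_sd = float(np.sqrt(1 - lam**2))
    latents = {}
    for d in DOMAINS:
        a_d = load.domain[d]
        f_d = a_d * g + np.sqrt(1 - a_d**2) * rng.standard_normal(n)
        latents[d] = f_d
        for i in range(1, 5):
            data[f"{d}{i}"] = lam * f_d + noise_sd * rng.standard_normal(n)

    def correlated(rho: float) -> np.ndarray:
        return rho * w + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    data["wmh_global_k07"] = np.exp(config.wmh_log_mean + config.wmh_log_sd * w)
    data["wmh_pv_k07"] = np.exp(5.89 + 1.39 * correlated(config.rho_global_pv))
    data["wmh_deep_k07"] = np.exp(3.52 + 2.30 * correlated(config.rho_global_deep))
    data["wmh_global_k05"] = np.exp(6.82 + 1.03 * correlated(config.rho_global_k05))

    delta = config.tract_wmh_loading
    for tract in TRACTS:
        mu_t, sd_t = _TRACT_LOG_PARAMS[tract]
        t = delta * w + np.sqrt(1 - delta**2) * rng.standard_normal(n)
        data[f"tract_{tract}"] = np.exp(mu_t + sd_t * t)

    data["latent_g"] = g
    data["latent_w"] = w
    for d in DOMAINS:
        data[f"latent_{d}"] = latents[d]

    pheno = pd.DataFrame(data)
    if pheno.isna().any().any():
        raise AssertionError("generated phenotypes contain missing values")
    return pheno


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------

@dataclass
class ConnectomeSet:
    """Stack of symmetric non-negative connectivity matrices.

    ``signal_mask`` marks the edges on which the generator planted the WMH
    exposure effect (ground truth, simulation-only).
    """

    participant_ids: list[str]
    matrices: np.ndarray  # (n, nodes, nodes)
    signal_mask: np.ndarray | None = None  # (nodes, nodes) bool
    min_count: int = 3

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def validate(self) -> None:
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be a stack of square matrices")
        if len(self.participant_ids) != self.matrices.shape[0]:
            raise ValueError("participant_ids length does not match matrix stack")
        W = self.matrices
        if not np.allclose(W, np.swapaxes(W, 1, 2)):
            raise ValueError("matrices must be symmetric to machine precision")
        if (np.abs(np.diagonal(W, axis1=1, axis2=2)) > 0).any():
            raise ValueError("matrices must have zero diagonal")
        if (W < 0).any():
            raise ValueError("matrices must be non-negative")
        nz = W[W > 0]
        if nz.size and nz.min() < self.min_count:
            raise ValueError(f"thresholded matrices may not contain entries in (0, {self.min_count})")
        if self.signal_mask is not None:
            if self.signal_mask.shape != W.shape[1:]:
                raise ValueError("signal_mask shape mismatch")
            if not np.array_equal(self.signal_mask, self.signal_mask.T):
                raise ValueError("signal_mask must be symmetric")


def apply_streamline_threshold(matrix: np.ndarray, min_count: int = 3) -> np.ndarray:
    """Zero all cells with fewer than ``min_count`` streamlines."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    out = matrix.copy()
    out[out < min_count] = 0.0
    return out


# Baseline edge classes: (presence probability, relative weight multiplier).
# Within-network and within-lobe edges are enriched (community structure and
# spatial proximity); the subcortical-to-DMN/FPN blocks carry the major
# projection systems (thalamo-/striato-cortical) and are enriched without
# turning subcortical nodes into dominant strength hubs, so that aging-related
# loss on those blocks increases modular segregation while reducing
# communication capacity.
_EDGE_CLASSES = {
    "within_network": (0.8, 2.0),
    "sub_sub": (0.7, 0.5),
    "within_lobe": (0.5, 1.5),
    "sub_dmn_fpn": (0.9, 0.7),
    "sub_cortical_other": (0.15, 0.5),
    "between_other": (0.3, 0.8),
}


def _edge_structure(atlas: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Baseline edge presence/weight and the planted signal mask (upper triangle)."""
    n_nodes = len(atlas)
    iu, ju = np.triu_indices(n_nodes, k=1)
    lobe = atlas.sort_values("node_id")["lobe"].to_numpy()
    network = atlas.sort_values("node_id")["network"].to_numpy()
    is_sub = network == "SUB"

    within_lobe = lobe[iu] == lobe[ju]
    within_network = network[iu] == network[ju]
    sub_cortical = is_sub[iu] ^ is_sub[ju]
    sub_sub = is_sub[iu] & is_sub[ju]
    dmn_fpn = np.isin(network, ("DMN", "FPN"))
    sub_proj = sub_cortical & (dmn_fpn[iu] | dmn_fpn[ju])

    presence = np.full(iu.size, _EDGE_CLASSES["between_other"][0])
    mult = np.full(iu.size, _EDGE_CLASSES["between_other"][1])
    for name, mask in (
        ("sub_cortical_other", sub_cortical),
        ("sub_dmn_fpn", sub_proj),
        ("within_lobe", within_lobe),
        ("within_network", within_network & ~sub_sub),
        ("sub_sub", sub_sub),
    ):
        p, w = _EDGE_CLASSES[name]
        presence[mask] = p
        mult[mask] = w

    present = rng.random(iu.size) < presence
    lam = np.exp(rng.normal(0.0, 0.75, size=iu.size)) * mult * present

    # Signal: every SUB-SUB edge plus a seeded fraction of SUB-DMN / SUB-FPN.
    signal = sub_sub.copy()
    for net in ("DMN", "FPN"):
        in_net = network == net
        block = sub_cortical & (in_net[iu] | in_net[ju])
        idx = np.flatnonzero(block)
        take = rng.choice(idx, size=int(round(config.signal_cortical_frac * idx.size)), replace=False)
        signal[take] = True
    return iu, ju, lam, signal


def simulate_connectomes(
    phenotypes: pd.DataFrame, atlas: pd.DataFrame, config: SimConfig | None = None
) -> ConnectomeSet:
    """Draw per-subject streamline-count matrices.

    Expected counts on planted signal edges are modulated by
    ``exp(-kappa * b)`` where ``b`` is the subject's standardized WMH latent,
    so high-WMH (older) subjects lose subcortical connectivity.  Observed
    counts are Poisson draws, symmetrized, and streamline-thresholded.  The
    baseline scale is calibrated so the expected post-threshold density hits
    ``base_density_target``.
    """
    config = config or SimConfig()
    validate_atlas(atlas)
    if "latent_w" not in phenotypes.columns:
        raise KeyError(
            "phenotype table lacks the generator latent column 'latent_w'; "
            "simulate_connectomes requires tables from simulate_phenotypes"
        )
    n = len(phenotypes)
    if n != config.n:
        # allowed: any phenotype table drawn from a compatible config
        pass
    n_nodes = len(atlas)
    rng = np.random.default_rng([int(config.seed), 0x5EED])

    iu, ju, lam, signal = _edge_structure(atlas, config, rng)

    w = phenotypes["latent_w"].to_numpy(dtype=float)
    b = (w - w.mean()) / w.std()
    kappa = config.signal_edge_decay
    subj_factor = np.exp(-kappa * b)  # (n,)

    # Calibrate the global count scale so that the mean (over edges and the
    # subject modulation) probability of surviving the streamline threshold
    # equals the density target.
    mean_factor = np.where(signal, subj_factor.mean(), 1.0)
    lam_eff = lam * mean_factor

    def expected_density(log_c: float) -> float:
        mu = np.exp(log_c) * lam_eff
        return float(stats.poisson.sf(2, mu).mean()) - config.base_density_target

    max_attainable = float((lam_eff > 0).mean())
    if max_attainable <= config.base_density_target:
        raise CalibrationError(
            f"base_density_target={config.base_density_target} exceeds attainable "
            f"edge presence {max_attainable:.3f}"
        )
    log_c = optimize.brentq(expected_density, np.log(1e-3), np.log(1e5), xtol=1e-6)
    lam = np.exp(log_c) * lam

    matrices = np.zeros((n, n_nodes, n_nodes))
    min_count = 3
    for s in range(n):
        mu = np.where(signal, lam * subj_factor[s], lam)
        counts = rng.poisson(mu).astype(float)
        counts[counts < min_count] = 0.0
        M = np.zeros((n_nodes, n_nodes))
        M[iu, ju] = counts
        M += M.T
        matrices[s] = M

    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    mask[iu, ju] = signal
    mask |= mask.T

    cs = ConnectomeSet(
        participant_ids=list(phenotypes["participant_id"]),
        matrices=matrices,
        signal_mask=mask,
        min_count=min_count,
    )
    cs.validate()
    return cs


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    phenotypes: pd.DataFrame,
    atlas: pd.DataFrame,
    connectomes: ConnectomeSet | None = None,
    config: SimConfig | None = None,
) -> None:
    """Write phenotypes.csv, atlas.tsv, connectomes/<id>.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    atlas.to_csv(outdir / "atlas.tsv", sep="\t", index=False)
    truth: dict = {}
    if config is not None:
        load = solve_latent_loadings(config)
        truth["seed"] = config.seed
        truth["loadings"] = dataclasses.asdict(load)
    if connectomes is not None:
        cdir = outdir / "connectomes"
        cdir.mkdir(exist_ok=True)
        for pid, M in zip(connectomes.participant_ids, connectomes.matrices):
            np.savetxt(cdir / f"{pid}.tsv", M, fmt="%.10g", delimiter="\t")
        if connectomes.signal_mask is not None:
            i, j = np.nonzero(np.triu(connectomes.signal_mask, k=1))
            truth["signal_edges"] = [[int(a), int(b)] for a, b in zip(i, j)]
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
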