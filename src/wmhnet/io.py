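"""Readers and writers for the on-disk dataset layout.

phenotypes.csv (one row per participant), atlas.tsv (node table),
connectomes/<participant_id>.tsv (full square tab-separated matrix, no
header).  Readers validate shapes, symmetry and non-negativity and report the
offending file and cell on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ConnectomeSet, validate_atlas

__all__ = [
    "read_phenotypes",
    "read_atlas",
    "read_connectome_dir",
    "write_connectome_dir",
]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table lacks a participant_id column")
    if df["participant_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate participant ids")
    return df


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    validate_atlas(atlas)
    return atlas


def read_connectome_dir(
    directory: str | Path,
    participant_ids: list[str],
    n_nodes: int = 246,
    min_count: int = 3,
) -> ConnectomeSet:
    """Load <id>.tsv matrices for every participant, validating each file."""
    directory = Path(directory)
    missing = [pid for pid in participant_ids if not (directory / f"{pid}.tsv").exists()]
    if missing:
        raise FileNotFoundError(f"connectome files missing for participants: {missing}")
    matrices = np.zeros((len(participant_ids), n_nodes, n_nodes))
    for k, pid in enumerate(participant_ids):
        fname = directory / f"{pid}.tsv"
        M = np.loadtxt(fname, delimiter="\t")
        if M.shape != (n_nodes, n_nodes):
            raise ValueError(f"{fname}: expected {n_nodes}x{n_nodes} matrix, got {M.shape}")
        asym = np.abs(M - M.T)
        if asym.max() > 1e-8:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(f"{fname}: asymmetric at cell ({i}, {j}): {M[i, j]} vs {M[j, i]}")
        if (M < 0).any():
            i, j = np.unravel_index(np.argmin(M), M.shape)
            raise ValueError(f"{fname}: negative weight at cell ({i}, {j})")
        matrices[k] = M
    cs = ConnectomeSet(list(participant_ids), matrices, min_count=min_count)
    cs.validate()
    return cs


def write_connectome_dir(directory: str | Path, connectomes: ConnectomeSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pid, M in zip(connectomes.participant_ids, connectomes.matrices):
        np.savetxt(directory / f"{pid}.tsv", M, fmt="%.10g", delimiter="\t")
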