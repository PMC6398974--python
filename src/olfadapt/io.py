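"""Readers and writers for the labeled CSV formats.

Sensing matrices are CSV with odorant labels in the header row and receptor
labels in the first column (receptors as rows).  Covariance matrices are
square CSV with the same labels on rows and columns; they are symmetrized on
read with a relative asymmetry check.  Comment lines start with ``#``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import NoiseProfile, OdorEnvironment, SensingMatrix
from .optimize import OptimizationResult

__all__ = [
    "read_sensing_matrix",
    "write_sensing_matrix",
    "read_covariance",
    "write_covariance",
    "read_noise_profile",
    "read_distribution",
    "write_distribution",
]

_ASYM_RTOL = 1e-8


def _read_labeled(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0, comment="#", float_precision="round_trip")
    except Exception as exc:  # ragged rows, bad encoding, ...
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column label {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return df


def read_sensing_matrix(path) -> SensingMatrix:
    """Read a labeled receptor x odorant sensing matrix."""
    df = _read_labeled(path)
    return SensingMatrix(
        df.to_numpy(dtype=float),
        tuple(str(x) for x in df.index),
        tuple(str(x) for x in df.columns),
    )


def write_sensing_matrix(S: SensingMatrix, path) -> None:
    pd.DataFrame(
        S.S, index=list(S.receptor_labels), columns=list(S.odorant_labels)
    ).to_csv(path, float_format="%.17g")


def read_covariance(path, mean_path=None) -> OdorEnvironment:
    """Read a labeled square covariance CSV (optionally with a mean side file)."""
    df = _read_labeled(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: covariance must be square, got shape {df.shape}")
    gamma = df.to_numpy(dtype=float)
    scale = np.abs(gamma).max() or 1.0
    asym = np.abs(gamma - gamma.T).max()
    if asym > _ASYM_RTOL * scale:
        raise ValueError(f"{path}: asymmetry {asym:.3e} exceeds tolerance {_ASYM_RTOL * scale:.3e}")
    gamma = 0.5 * (gamma + gamma.T)
    c0 = None
    if mean_path is not None:
        c0 = pd.read_csv(mean_path, index_col=0, comment="#").iloc[:, 0].to_numpy(dtype=float)
    labels = tuple(str(x) for x in df.index)
    return OdorEnvironment(c0, gamma, labels)


def write_covariance(env: OdorEnvironment, path) -> None:
    labels = list(env.odorant_labels)
    pd.DataFrame(env.gamma, index=labels, columns=labels).to_csv(path, float_format="%.17g")


def read_noise_profile(path) -> NoiseProfile:
    """Read per-receptor noise variances from a (label, sigma2) CSV."""
    df = _read_labeled(path)
    return NoiseProfile(df.iloc[:, 0].to_numpy(dtype=float))


def write_distribution(
    result: OptimizationResult,
    path,
    *,
    receptor_labels=None,
    seed=None,
    config_hash=None,
) -> None:
    """Write an optimized allocation with provenance header comments."""
    K = result.K
    m = K.size
    labels = list(receptor_labels) if receptor_labels is not None else [
        f"receptor_{i}" for i in range(m)
    ]
    header = [
        f"# seed={seed}",
        f"# config_hash={config_hash}",
        f"# info_nats={result.info!r}",
        f"# kkt_residual={result.kkt_residual!r}",
        f"# Ktot={result.distribution.Ktot!r}",
    ]
    df = pd.DataFrame(
        {
            "receptor": labels,
            "K": K,
            "fraction": result.distribution.fractions,
            "gradient": result.gradient,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_distribution(path) -> pd.DataFrame:
    """Read back a distribution CSV written by :func:`write_distribution`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
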