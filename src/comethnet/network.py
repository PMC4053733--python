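"""Signed weighted networks, topological overlap and the consensus TOM.

For each dataset a signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^b
maps the probe-probe correlation to [0, 1]; the soft-threshold power b
(default 12) suppresses weak and negative correlations.  The adjacency
is transformed into the topological overlap matrix

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu   (u != i, j),

a similarity that also credits shared neighbors.  Per-dataset TOMs are
calibrated onto a common scale by raising each to the power that equates
a chosen off-diagonal quantile (default the 95th percentile) with a
reference, and the consensus TOM is the entrywise low quantile (default
lower quartile) of the calibrated TOMs — large only where the connection
is strong in most datasets.  DissCTOM = 1 - CTOM feeds the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import bicor_matrix

__all__ = [
    "NetworkConfig",
    "correlation_matrix",
    "signed_adjacency",
    "tom",
    "calibrate_toms",
    "calibrate_toms_with_exponents",
    "calibration_exponents",
    "consensus_tom",
    "offdiag_quantile",
]


@dataclass(frozen=True)
class NetworkConfig:
    power: float = 12.0
    calibration_quantile: float = 0.95
    consensus_quantile: float = 0.25
    correlation: str = "bicor"  # or "pearson"
    calibration_reference: str = "first"  # or "median"

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        if not (0.0 < self.calibration_quantile < 1.0):
            raise ValueError("calibration_quantile must be in (0, 1)")
        if not (0.0 <= self.consensus_quantile <= 0.5):
            raise ValueError("consensus_quantile must be in [0, 0.5]")
        if self.correlation not in ("bicor", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.calibration_reference not in ("first", "median"):
            raise ValueError("calibration_reference must be 'first' or 'median'")


def correlation_matrix(beta: pd.DataFrame, cfg: NetworkConfig) -> np.ndarray:
    """Probe x probe correlations; zero-variance probes get correlation 0
    against everything (flagged by the caller)."""
    X = beta.to_numpy(dtype=float)
    if np.isnan(X).any():
        # impute by probe mean; network construction needs complete data
        means = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = means[idx[0]]
    if cfg.correlation == "bicor":
        r = bicor_matrix(X)
    else:
        sd = X.std(axis=1)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r


def signed_adjacency(beta: pd.DataFrame, cfg: NetworkConfig = NetworkConfig()) -> np.ndarray:
    """Signed weighted adjacency ((1 + cor) / 2) ** power, diagonal 1."""
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    r = correlation_matrix(beta, cfg)
    a = ((1.0 + r) / 2.0) ** cfg.power
    np.fill_diagonal(a, 1.0)
    return a


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a  # L_ij = sum_{u != i,j} a_iu a_uj (diagonal of a is zero)
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (L + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def offdiag_quantile(matrix: np.ndarray, q: float) -> float:
    """Quantile (linear interpolation) of the upper-triangle entries."""
    iu = np.triu_indices_from(matrix, k=1)
    return float(np.quantile(matrix[iu], q))


def calibration_exponents(toms: list[np.ndarray], cfg: NetworkConfig) -> np.ndarray:
    """Per-dataset powers equating each TOM's calibration quantile with the
    reference (first dataset's quantile, or the median across datasets)."""
    if len(toms) < 2:
        raise ValueError("need at least two TOMs to calibrate")
    qs = np.array([offdiag_quantile(t, cfg.calibration_quantile) for t in toms])
    if np.any((qs <= 0.0) | (qs >= 1.0)):
        raise ValueError("degenerate network: calibration quantile at 0 or 1")
    q_ref = qs[0] if cfg.calibration_reference == "first" else float(np.median(qs))
    return np.log(q_ref) / np.log(qs)


def calibrate_toms_with_exponents(
    toms: list[np.ndarray],
    cfg: NetworkConfig = NetworkConfig(),
    tol: float = 1e-12,
    max_refine: int = 6,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Raise each TOM entrywise to its calibration exponent.

    A power transform is monotone, so within-dataset entry ordering is
    preserved.  Because the sample quantile interpolates between order
    statistics, the closed-form exponent leaves a residual mismatch of
    order 1e-9; a few fixed-point refinements push the agreement of the
    calibration quantiles below ``tol``.  Returns (calibrated TOMs,
    total exponents applied).
    """
    powers = calibration_exponents(toms, cfg)
    qs0 = np.array([offdiag_quantile(t, cfg.calibration_quantile) for t in toms])
    q_ref = qs0[0] if cfg.calibration_reference == "first" else float(np.median(qs0))
    cal = [t**p for t, p in zip(toms, powers)]
    for _ in range(max_refine):
        qs = np.array([offdiag_quantile(c, cfg.calibration_quantile) for c in cal])
        if np.max(np.abs(qs - q_ref)) < tol:
            break
        adjust = np.log(q_ref) / np.log(qs)
        cal = [c**a for c, a in zip(cal, adjust)]
        powers = powers * adjust
    return cal, powers


def calibrate_toms(toms: list[np.ndarray], cfg: NetworkConfig = NetworkConfig()) -> list[np.ndarray]:
    """Calibrated TOMs (see :func:`calibrate_toms_with_exponents`)."""
    return calibrate_toms_with_exponents(toms, cfg)[0]


def consensus_tom(toms: list[np.ndarray], cfg: NetworkConfig = NetworkConfig()) -> np.ndarray:
    """Entrywise low quantile of calibrated TOMs (lower quartile by default)."""
    shapes = {t.shape for t in toms}
    if len(shapes) != 1:
        raise ValueError("TOMs must share probe set and order")
    stack = np.stack(toms)
    ctom = np.quantile(stack, cfg.consensus_quantile, axis=0)
    np.fill_diagonal(ctom, 1.0)
    return ctom
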