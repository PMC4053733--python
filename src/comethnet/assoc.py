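"""Probe-level age association and Stouffer meta-analysis across datasets.

Per dataset, every probe is correlated with age using the biweight
midcorrelation (a robust alternative to Pearson) or plain Pearson.  The
correlation is converted to a two-sided p-value via the Student-t
transform t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom, to a
standard-normal equivalent Z = Phi^-1(1 - p/2) * sign(r), and to the
signed log p-value -log10(p) * sign(r), so probes gaining methylation
with age score positive.  Per-dataset Z statistics are combined with
Stouffer's weighted method,

    metaZ = sum(w_s * Z_s) / sqrt(sum(w_s^2)),

with equal weights by default, giving a meta p-value and (BH) q-values.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bicor",
    "bicor_matrix",
    "cor_test_age",
    "stouffer_meta",
    "meta_by_selection",
    "adjust_q",
    "cross_dataset_concordance",
]

P_FLOOR = 1e-300  # underflow cap before taking log10
MAX_LOG_P = -np.log10(P_FLOOR)


def _biweight_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise robustly weighted, centered, unit-norm vectors.

    Rows where the median absolute deviation is zero fall back to plain
    standardization (Pearson behavior), as is conventional for the
    biweight midcorrelation.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad == 0.0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
        inside = np.abs(u) < 1.0
        w = np.where(inside, (1.0 - np.clip(u, -1.0, 1.0) ** 2) ** 2, 0.0)
    g = w * (X - med)
    if fallback.any():
        centered = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
        g[fallback] = centered
    # rescale rows to unit max first: avoids under/overflow in the norm
    scale = np.max(np.abs(g), axis=1, keepdims=True)
    g = np.divide(g, scale, out=np.zeros_like(g), where=scale > 0)
    norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
    zero = (norm == 0.0).ravel()
    norm[zero] = 1.0
    g = g / norm
    g[zero] = np.nan  # zero-variance rows have no defined correlation
    return g


def bicor(x: Sequence[float], y: Sequence[float]) -> float:
    """Biweight midcorrelation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    g = _biweight_transform(np.vstack([x[keep], y[keep]]))
    r = float(np.clip(g[0] @ g[1], -1.0, 1.0))
    return r


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise biweight midcorrelations of the rows of X."""
    g = _biweight_transform(X)
    r = np.clip(g @ g.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _r_to_stats(r: np.ndarray, n: np.ndarray):
    """Student-t p-value, normal-equivalent Z and signed log p from r."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)), 0.0)
    p = np.clip(p, P_FLOOR, 1.0)
    undefined = np.isnan(r)
    p[undefined] = 1.0
    sign = np.sign(np.nan_to_num(r))
    z = stats.norm.isf(p / 2.0) * sign
    slp = -np.log10(p) * sign
    return p, z, np.clip(slp, -MAX_LOG_P, MAX_LOG_P)


def cor_test_age(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    method: str = "bicor",
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate every probe with age in one dataset.

    Returns a frame indexed by probe with columns r, n, p, z,
    signed_log_p.  Probes with zero variance (or fewer than ``min_n``
    complete pairs) get r = NaN, p = 1.  Missing betas are handled
    pairwise-complete per probe.
    """
    if method not in ("bicor", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if beta.shape[1] < min_n:
        raise ValueError(f"fewer than {min_n} samples")
    table = samples.set_index("sample_id").loc[list(beta.columns)]
    age = table["age"].to_numpy(dtype=float)
    if np.isnan(age).any():
        raise ValueError("age missing for some samples")
    X = beta.to_numpy(dtype=float)
    n_probes = X.shape[0]
    r = np.full(n_probes, np.nan)
    n_used = np.full(n_probes, X.shape[1])

    complete = ~np.isnan(X).any(axis=1)
    if complete.any():
        Xc = X[complete]
        if method == "bicor":
            g = _biweight_transform(Xc)
            ga = _biweight_transform(age[None, :])[0]
        else:
            g = Xc - Xc.mean(axis=1, keepdims=True)
            norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
            zero = (norm == 0.0).ravel()
            norm[zero] = 1.0
            g = g / norm
            g[zero] = np.nan
            a = age - age.mean()
            ga = a / np.sqrt((a**2).sum())
        r[complete] = np.clip(g @ ga, -1.0, 1.0)
    for i in np.where(~complete)[0]:
        x = X[i]
        keep = ~np.isnan(x)
        n_used[i] = int(keep.sum())
        if n_used[i] < min_n or np.nanstd(x) == 0:
            continue
        if method == "bicor":
            r[i] = bicor(x[keep], age[keep])
        else:
            r[i] = float(np.corrcoef(x[keep], age[keep])[0, 1])

    p, z, slp = _r_to_stats(r, n_used)
    return pd.DataFrame(
        {"r": r, "n": n_used, "p": p, "z": z, "signed_log_p": slp},
        index=beta.index.rename("probe_id"),
    )


def adjust_q(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-value stand-in)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stouffer_meta(
    results: Mapping[str, pd.DataFrame],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Combine per-dataset correlation results into one meta table.

    Probes present in every dataset are combined; weights default to 1
    per dataset.  Returns metaZ, meta_p, q, signed_log_p plus the
    per-dataset r and n columns.
    """
    if not results:
        raise ValueError("no datasets to combine")
    names = list(results)
    if weights is None:
        w = np.ones(len(names))
    else:
        w = np.array([weights[name] for name in names], dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    shared = results[names[0]].index
    for name in names[1:]:
        shared = shared.intersection(results[name].index)
    if len(shared) == 0:
        raise ValueError("no overlapping probes across datasets")
    shared = results[names[0]].index[results[names[0]].index.isin(shared)]

    Z = np.column_stack([results[name].loc[shared, "z"].to_numpy() for name in names])
    meta_z = (Z * w).sum(axis=1) / np.sqrt((w**2).sum())
    meta_p = np.clip(2.0 * stats.norm.sf(np.abs(meta_z)), P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "metaZ": meta_z,
            "meta_p": meta_p,
            "q": adjust_q(meta_p),
            "signed_log_p": np.clip(
                -np.log10(meta_p) * np.sign(meta_z), -MAX_LOG_P, MAX_LOG_P
            ),
        },
        index=shared,
    )
    for name in names:
        out[f"r_{name}"] = results[name].loc[shared, "r"].to_numpy()
        out[f"n_{name}"] = results[name].loc[shared, "n"].to_numpy()
    return out


def meta_by_selection(
    results: Mapping[str, pd.DataFrame],
    selections: Mapping[str, Sequence[str]],
    weights: Mapping[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the meta-analysis on named dataset groups (e.g. blood / brain / all)."""
    out = {}
    for sel_name, dataset_names in selections.items():
        missing = [d for d in dataset_names if d not in results]
        if missing:
            raise KeyError(f"selection {sel_name!r} references unknown datasets {missing}")
        sub = {d: results[d] for d in dataset_names}
        out[sel_name] = stouffer_meta(sub, weights)
    return out


def cross_dataset_concordance(
    a: pd.Series, b: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Correlation of two per-probe summaries (means or signed log p)
    over their shared probes, plus the paired table for plotting."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared probes")
    table = pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]}).dropna()
    r = float(np.corrcoef(table["a"], table["b"])[0, 1])
    return r, table
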