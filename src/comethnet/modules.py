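"""Consensus module detection, eigengenes, kME and module-trait tables.

The consensus dissimilarity DissCTOM = 1 - CTOM is clustered with
average-linkage (UPGMA) hierarchical clustering; branches of the tree
below a cut height, of at least ``min_module_size`` probes, become
modules.  Probes in no admissible branch are left unassigned ("grey").
Each module is summarized per dataset by its eigengene — the first
principal component of the standardized module submatrix, oriented so
the mean correlation with member probes is positive — and every probe's
module membership kME is its correlation with the eigengene.  The
consensus kME is the average of per-dataset kMEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .assoc import _r_to_stats

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "ModuleSet",
    "cluster_dissimilarity",
    "cut_tree_adaptive",
    "module_eigengene",
    "eigengene_set",
    "kme",
    "consensus_kme",
    "module_trait_table",
    "top_module_probes",
]

GREY = "grey"
# WGCNA-style display names; label 1 = largest module
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def color_name(label: int) -> str:
    if label == 0:
        return GREY
    if label <= len(MODULE_COLORS):
        return MODULE_COLORS[label - 1]
    return f"module{label}"


@dataclass
class ModuleSet:
    """Probe -> module assignment plus the dendrogram it came from."""

    labels: pd.Series  # probe_id -> int label, 0 = grey
    linkage_matrix: np.ndarray
    cut_height: float
    min_module_size: int

    @property
    def colors(self) -> pd.Series:
        return self.labels.map(color_name)

    def module_probes(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def module_labels(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.labels, "color": self.colors},
            index=self.labels.index.rename("probe_id"),
        )


def cluster_dissimilarity(diss: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree of a symmetric dissimilarity matrix.

    Returns a scipy linkage matrix; deterministic for a given input
    (scipy's nearest-neighbor chain breaks ties by lower index).
    """
    diss = np.asarray(diss, dtype=float)
    if not np.allclose(diss, diss.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if (diss < 0).any():
        raise ValueError("dissimilarity must be non-negative")
    d = diss.copy()
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def cut_tree_adaptive(
    link: np.ndarray,
    probe_ids,
    min_module_size: int = 30,
    cut_height: float | None = None,
    deep_split: int = 1,
) -> ModuleSet:
    """Static branch cut with minimum-size pruning.

    The tree is cut at ``cut_height`` (default: a fraction of the top
    merge height that shrinks as ``deep_split`` grows, 0.99 at the
    default split level); connected branches below the cut of at least
    ``min_module_size`` probes become modules, all other probes are
    grey.  Labels are ordered by decreasing module size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be at least 2")
    if not 0 <= deep_split <= 3:
        raise ValueError("deep_split must be in 0..3")
    heights = link[:, 2]
    if cut_height is None:
        frac = {0: 0.995, 1: 0.99, 2: 0.97, 3: 0.94}[deep_split]
        cut_height = frac * float(heights.max())
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    admissible = sizes[sizes >= min_module_size]
    # order by decreasing size; ties by lower raw cluster id for determinism
    order = sorted(admissible.index, key=lambda c: (-admissible[c], c))
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return ModuleSet(
        labels=pd.Series(labels, index=pd.Index(probe_ids, name="probe_id")),
        linkage_matrix=link,
        cut_height=float(cut_height),
        min_module_size=min_module_size,
    )


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = (sd != 0).ravel()
    Z = np.zeros_like(X)
    Z[keep] = (X[keep] - mean[keep]) / sd[keep]
    return Z[keep], keep


def module_eigengene(beta: pd.DataFrame, member_probes) -> tuple[pd.Series, float]:
    """First principal component of the standardized module submatrix.

    Returns (eigengene sample scores with unit norm, proportion of
    variance explained).  Sign is oriented so the average correlation
    with member probes is non-negative.  Constant probes are excluded;
    missing values are imputed by the probe mean first.
    """
    member_probes = [p for p in member_probes if p in beta.index]
    if len(member_probes) < 2:
        raise ValueError("need at least 2 member probes")
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = beta.loc[member_probes].to_numpy(dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = means[idx[0]]
    Z, keep = _standardize_rows(X)
    if Z.shape[0] < 2:
        raise ValueError("fewer than 2 usable (non-constant) member probes")
    # SVD of probes x samples: right singular vector = sample scores
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    prop_var = float(s[0] ** 2 / (s**2).sum())
    # orient: mean correlation with member profiles >= 0
    zc = Z - Z.mean(axis=1, keepdims=True)
    sc = scores - scores.mean()
    member_cor = (zc @ sc) / (
        np.linalg.norm(zc, axis=1) * np.linalg.norm(sc) + 1e-300
    )
    if member_cor.mean() < 0:
        scores = -scores
    return pd.Series(scores, index=beta.columns, name="eigengene"), prop_var


def eigengene_set(
    betas: dict[str, pd.DataFrame], modules: ModuleSet
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-dataset eigengenes for every module.

    Returns ({dataset: samples x module frame}, propVarExplained frame
    indexed by module label with one column per dataset).
    """
    eigengenes: dict[str, pd.DataFrame] = {}
    pve = {}
    for name, beta in betas.items():
        cols = {}
        pv = {}
        for label in modules.module_labels:
            eg, p = module_eigengene(beta, modules.module_probes(label))
            cols[label] = eg
            pv[label] = p
        eigengenes[name] = pd.DataFrame(cols)
        pve[name] = pd.Series(pv)
    return eigengenes, pd.DataFrame(pve)


def kme(beta: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Correlation of every probe with every module eigengene (one dataset).

    Returns probes x modules kME values; degenerate (constant) probes get
    NaN.
    """
    if list(beta.columns) != list(eigengenes.index):
        raise ValueError("samples misaligned between beta matrix and eigengenes")
    X = beta.to_numpy(dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = means[idx[0]]
    E = eigengenes.to_numpy(dtype=float)
    if np.any(E.std(axis=0) == 0):
        raise ValueError("degenerate eigengene")
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    en = np.linalg.norm(Ec, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Ec) / np.outer(xn, en)
    r[xn == 0] = np.nan
    return pd.DataFrame(
        np.clip(r, -1, 1), index=beta.index.rename("probe_id"), columns=eigengenes.columns
    )


def consensus_kme(
    kmes: dict[str, pd.DataFrame], n_samples: dict[str, int] | None = None
) -> pd.DataFrame:
    """Average kME across datasets, optionally with meta membership p.

    Returns a frame indexed by probe with, per module label L, the
    consensus column ``kME{L}`` (arithmetic mean over non-missing
    datasets) and per-dataset columns ``kME{L}_{dataset}``.  When
    ``n_samples`` gives the per-dataset sample counts, an equal-weight
    Stouffer combination of the per-dataset membership tests is added as
    ``metaZ_kME{L}`` and ``p_kME{L}``.
    """
    names = list(kmes)
    modules = kmes[names[0]].columns
    index = kmes[names[0]].index
    out = pd.DataFrame(index=index)
    for label in modules:
        per = pd.DataFrame({name: kmes[name][label] for name in names})
        out[f"kME{label}"] = per.mean(axis=1)
        for name in names:
            out[f"kME{label}_{name}"] = per[name]
        if n_samples is not None:
            zs = []
            for name in names:
                r = per[name].to_numpy()
                n = np.full(len(r), n_samples[name])
                _, z, _ = _r_to_stats(r, n)
                zs.append(z)
            Z = np.column_stack(zs)
            meta_z = Z.sum(axis=1) / np.sqrt(Z.shape[1])
            out[f"metaZ_kME{label}"] = meta_z
            out[f"p_kME{label}"] = np.clip(
                2.0 * stats.norm.sf(np.abs(meta_z)), 1e-300, 1.0
            )
    return out


def module_trait_table(
    eigengenes: dict[str, pd.DataFrame],
    sample_tables: dict[str, pd.DataFrame],
    trait: str = "age",
) -> pd.DataFrame:
    """Module x dataset grid of (eigengene, trait) correlations and p-values."""
    rows = []
    for name, eg in eigengenes.items():
        table = sample_tables[name].set_index("sample_id").loc[list(eg.index)]
        if trait not in table.columns:
            raise KeyError(f"trait {trait!r} missing from sample table {name!r}")
        y = table[trait].to_numpy(dtype=float)
        for label in eg.columns:
            x = eg[label].to_numpy()
            r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
            p, _, _ = _r_to_stats(np.array([r]), np.array([len(y)]))
            rows.append(
                {
                    "module": label,
                    "color": color_name(label),
                    "dataset": name,
                    "r": r,
                    "p": float(p[0]),
                    "p_one_sided": float(p[0]) / 2.0,
                    "n": len(y),
                }
            )
    return pd.DataFrame(rows)


def top_module_probes(consensus_kme_table: pd.DataFrame, label: int, k: int) -> pd.DataFrame:
    """The k probes with highest consensus kME for a module (ties by probe id)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    col = f"kME{label}"
    if col not in consensus_kme_table.columns:
        raise KeyError(f"module {label} not in consensus kME table")
    ranked = consensus_kme_table.copy()
    ranked["_pid"] = ranked.index.astype(str)
    ranked = ranked.sort_values([col, "_pid"], ascending=[False, True], kind="mergesort")
    ranked = ranked.drop(columns="_pid")
    return ranked.head(min(k, len(ranked)))
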