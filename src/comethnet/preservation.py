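"""Permutation module-preservation statistics (Zdensity, medianRank).

Whether a module defined in reference data is "preserved" in a test
dataset is judged by four density statistics evaluated on the test data:

* mean sign-aware within-module correlation (signs taken from the
  reference set, so coherent anti-correlation counts against),
* mean within-module signed adjacency,
* proportion of variance explained by the module eigengene,
* mean sign-aware kME (probe-eigengene correlation, reference signs).

Each statistic is compared against a permutation null built from random
probe sets of the same size (drawn without replacement from non-module
probes); Z = (observed - null mean) / null SD, and Zdensity is the
median of the four Zs.  Conventional thresholds: Zdensity < 2 no
evidence, 2-10 weak to moderate, > 10 strong preservation.  When modules
come from a consensus analysis over several reference sets, Zdensity(k)
is computed against each reference set k and averaged.

Connectivity-based statistics (correlation of reference vs test kME and
of the intramodular correlation patterns, summarized by Zconnectivity,
with Zsummary the mean of the density and connectivity composites) are
computed and reported separately; density is the primary criterion.

medianRank compares relative preservation between modules: each observed
statistic is ranked across modules (rank 1 = strongest) and the median
rank is reported; it is far less dependent on module size than the
permutation Zs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkConfig, correlation_matrix

__all__ = [
    "DENSITY_STATS",
    "PreservationReport",
    "density_stats",
    "permutation_z",
    "median_rank",
    "multi_reference_preservation",
    "preservation_call",
]

DENSITY_STATS = ("mean_signed_cor", "mean_adjacency", "prop_var_explained", "mean_signed_kme")
CONNECTIVITY_STATS = ("cor_kme", "cor_cor")


def preservation_call(z: float) -> str:
    if z < 2:
        return "none"
    if z <= 10:
        return "weak-moderate"
    return "strong"


class _DatasetCache:
    """Correlation and adjacency matrices of one dataset, computed once."""

    def __init__(self, beta: pd.DataFrame, cfg: NetworkConfig):
        self.probe_ids = list(beta.index)
        self.index = {p: i for i, p in enumerate(self.probe_ids)}
        X = beta.to_numpy(dtype=float)
        if np.isnan(X).any():
            means = np.nanmean(X, axis=1)
            ij = np.where(np.isnan(X))
            X = X.copy()
            X[ij] = means[ij[0]]
        self.X = X
        self.corr = correlation_matrix(beta, cfg)
        self.adj = ((1.0 + self.corr) / 2.0) ** cfg.power

    def eigen_kme(self, ix: np.ndarray) -> tuple[np.ndarray, float]:
        """kME of member probes vs the submatrix eigengene + propVar."""
        Z = self.X[ix]
        Z = Z - Z.mean(axis=1, keepdims=True)
        sd = Z.std(axis=1)
        sd[sd == 0] = 1.0
        Z = Z / sd[:, None]
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        scores = vt[0]
        prop = float(s[0] ** 2 / (s**2).sum())
        sc = scores - scores.mean()
        kme = (Z @ sc) / (np.linalg.norm(Z, axis=1) * np.linalg.norm(sc) + 1e-300)
        if kme.mean() < 0:  # orient eigengene toward members
            kme = -kme
        return np.clip(kme, -1, 1), prop


def _stats_for(
    test: _DatasetCache, ref: _DatasetCache | None, ix: np.ndarray
) -> dict[str, float]:
    iu = np.triu_indices(len(ix), k=1)
    r_test = test.corr[np.ix_(ix, ix)][iu]
    signs = np.sign(ref.corr[np.ix_(ix, ix)][iu]) if ref is not None else 1.0
    kme_test, prop = test.eigen_kme(ix)
    out = {
        "mean_signed_cor": float(np.mean(signs * r_test)),
        "mean_adjacency": float(np.mean(test.adj[np.ix_(ix, ix)][iu])),
        "prop_var_explained": prop,
    }
    if ref is not None:
        kme_ref, _ = ref.eigen_kme(ix)
        out["mean_signed_kme"] = float(np.mean(np.sign(kme_ref) * kme_test))
        out["cor_kme"] = float(np.corrcoef(kme_ref, kme_test)[0, 1])
        r_ref = ref.corr[np.ix_(ix, ix)][iu]
        out["cor_cor"] = float(np.corrcoef(r_ref, r_test)[0, 1])
    else:
        out["mean_signed_kme"] = float(np.mean(kme_test))
    return out


def density_stats(
    test_beta: pd.DataFrame,
    module_probes,
    cfg: NetworkConfig = NetworkConfig(),
    reference_beta: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Observed density (and, with a reference, connectivity) statistics
    of one probe set in the test data.  Module probes missing from the
    test data are dropped."""
    test = _DatasetCache(test_beta, cfg)
    present = [p for p in module_probes if p in test.index]
    if len(present) < 3:
        raise ValueError("fewer than 3 module probes present in test data")
    ref = _DatasetCache(reference_beta, cfg) if reference_beta is not None else None
    ix = np.array([test.index[p] for p in present])
    return _stats_for(test, ref, ix)


def permutation_z(
    test_beta: pd.DataFrame,
    module_probes,
    n_perm: int = 200,
    seed: int = 0,
    cfg: NetworkConfig = NetworkConfig(),
    reference_beta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation Z scores for one module in one test dataset.

    Returns a frame indexed by statistic with columns observed,
    null_mean, null_sd, Z; the composite rows ``Zdensity`` (median of
    the four density Zs) and, when a reference is given,
    ``Zconnectivity`` and ``Zsummary``.
    """
    test = _DatasetCache(test_beta, cfg)
    ref = _DatasetCache(reference_beta, cfg) if reference_beta is not None else None
    return _permutation_z_cached(test, ref, module_probes, n_perm, seed)


def _permutation_z_cached(
    test: _DatasetCache,
    ref: _DatasetCache | None,
    module_probes,
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    if n_perm < 50:
        raise ValueError("n_perm must be at least 50")
    present = [p for p in module_probes if p in test.index]
    if len(present) < 3:
        raise ValueError("fewer than 3 module probes present in test data")
    ix = np.array([test.index[p] for p in present])
    observed = _stats_for(test, ref, ix)

    pool = np.array([i for p, i in test.index.items() if p not in set(module_probes)])
    if len(pool) < len(ix):
        raise ValueError("not enough non-module probes for the permutation null")
    rng = np.random.default_rng(seed)
    null = {k: np.empty(n_perm) for k in observed}
    for b in range(n_perm):
        rix = rng.choice(pool, size=len(ix), replace=False)
        st = _stats_for(test, ref, rix)
        for k, v in st.items():
            null[k][b] = v

    rows = []
    zvals = {}
    for k, obs in observed.items():
        mu = float(np.mean(null[k]))
        sd = float(np.std(null[k], ddof=1))
        if sd == 0.0:
            warnings.warn(f"degenerate permutation null for {k}; Z set to +inf")
            z = np.inf if obs > mu else 0.0
        else:
            z = (obs - mu) / sd
        zvals[k] = z
        rows.append({"statistic": k, "observed": obs, "null_mean": mu, "null_sd": sd, "Z": z})
    zdensity = float(np.median([zvals[k] for k in DENSITY_STATS]))
    rows.append({"statistic": "Zdensity", "observed": np.nan, "null_mean": np.nan,
                 "null_sd": np.nan, "Z": zdensity})
    if ref is not None:
        zconn = float(np.median([zvals[k] for k in CONNECTIVITY_STATS]))
        rows.append({"statistic": "Zconnectivity", "observed": np.nan, "null_mean": np.nan,
                     "null_sd": np.nan, "Z": zconn})
        rows.append({"statistic": "Zsummary", "observed": np.nan, "null_mean": np.nan,
                     "null_sd": np.nan, "Z": (zdensity + zconn) / 2.0})
    return pd.DataFrame(rows).set_index("statistic")


def median_rank(observed: pd.DataFrame) -> pd.Series:
    """Median across statistics of the per-statistic module ranks.

    ``observed`` is modules x statistics; higher statistic = stronger
    preservation, so rank 1 goes to the largest value; ties get average
    ranks."""
    if observed.shape[0] < 1:
        raise ValueError("no modules")
    ranks = observed.rank(axis=0, ascending=False, method="average")
    return ranks.median(axis=1).rename("medianRank")


@dataclass
class PreservationReport:
    """Zdensity(k) per module and reference set, their average, and calls."""

    per_reference: pd.DataFrame  # rows: (module, reference) with Zdensity etc.
    summary: pd.DataFrame  # per module: mean Zdensity, call, medianRank
    n_permutations: int
    seed: int


def multi_reference_preservation(
    reference_betas: dict[str, pd.DataFrame],
    module_probes: dict,
    test_beta: pd.DataFrame,
    cfg: NetworkConfig = NetworkConfig(),
    n_perm: int = 200,
    seed: int = 0,
) -> PreservationReport:
    """Average the per-reference-set preservation of each module.

    ``module_probes`` maps module label -> probe list (consensus modules
    defined on the shared probe set).  For each reference set k and
    module, Zdensity(k) is computed in the test data, then averaged over
    k; medianRank is computed per reference set from the observed
    density statistics and likewise averaged.
    """
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(reference_betas) * len(module_probes)))
    test = _DatasetCache(test_beta, cfg)
    rows = []
    observed_by_ref: dict[str, pd.DataFrame] = {}
    for ref_name, ref_beta in reference_betas.items():
        ref = _DatasetCache(ref_beta, cfg)
        obs_rows = {}
        for label, probes in module_probes.items():
            stream_seed = next(streams)
            table = _permutation_z_cached(
                test, ref, probes, n_perm,
                seed=int(stream_seed.generate_state(1)[0] % (2**31)),
            )
            obs_rows[label] = table.loc[list(DENSITY_STATS), "observed"]
            rows.append(
                {
                    "module": label,
                    "reference": ref_name,
                    "Zdensity": table.loc["Zdensity", "Z"],
                    "Zconnectivity": table.loc["Zconnectivity", "Z"],
                    "Zsummary": table.loc["Zsummary", "Z"],
                }
            )
        observed_by_ref[ref_name] = pd.DataFrame(obs_rows).T

    per_reference = pd.DataFrame(rows)
    mean_z = per_reference.groupby("module")["Zdensity"].mean()
    mean_zconn = per_reference.groupby("module")["Zconnectivity"].mean()
    ranks = pd.DataFrame({k: median_rank(v) for k, v in observed_by_ref.items()})
    summary = pd.DataFrame(
        {
            "Zdensity": mean_z,
            "Zconnectivity": mean_zconn,
            "medianRank": ranks.mean(axis=1),
            "call": mean_z.map(preservation_call),
        }
    )
    return PreservationReport(
        per_reference=per_reference, summary=summary, n_permutations=n_perm, seed=seed
    )
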