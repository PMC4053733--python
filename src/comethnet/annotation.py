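"""Relating module membership to probe annotations.

Covers the characterization of an aging module's membership measure
(consensus kME, or the signed log meta p-value) against probe-level
annotations: grouped means with standard errors, Kruskal-Wallis tests,
a sequential (type-I) ANOVA variance decomposition, and hypergeometric
gene-list enrichment with Bonferroni correction, plus bookkeeping for
polymorphic / cross-reactive probe flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "grouped_membership_summary",
    "kruskal_wallis",
    "anova_decomposition",
    "hypergeometric_enrichment",
    "flag_filter_probes",
    "read_gene_lists",
]


def grouped_membership_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean and standard error (SD / sqrt(n)), ordered by level."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    if df.empty:
        raise ValueError("no observations")
    out = (
        df.groupby("group", observed=True)["value"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 1).any():
        raise ValueError("empty group")
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out


def kruskal_wallis(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df.

    All-identical values give (0, 1) rather than an error."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    samples = [g["value"].to_numpy() for _, g in df.groupby("group", observed=True)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if sum(len(s) for s in samples) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(df["value"].to_numpy()) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def anova_decomposition(
    response: pd.Series,
    factors: pd.DataFrame,
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of a membership measure on annotations.

    Factors enter in the column order of ``factors``; those named in
    ``categorical`` are treated as multi-level factors (dummy coded),
    the rest as single-df continuous covariates.  The sums of squares
    are computed from nested least-squares fits, so the decomposition
    follows the stated entry order exactly.  Returns the classical
    table (df, sum of squares, proportion of total variance, F, p) plus
    residual and total rows; proportions sum to one.
    """
    data = factors.copy()
    data["_y"] = response
    data = data.dropna()
    if data.empty:
        raise ValueError("no complete observations")
    y = data["_y"].to_numpy(dtype=float)
    n = len(y)

    blocks = []
    for col in factors.columns:
        if col in categorical:
            levels = sorted(data[col].astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {col!r} is degenerate (one level)")
            dummies = pd.get_dummies(
                pd.Categorical(data[col].astype(str), categories=levels),
                drop_first=True,
            ).to_numpy(dtype=float)
            blocks.append((col, dummies))
        else:
            blocks.append((col, data[col].to_numpy(dtype=float)[:, None]))

    def rss_and_rank(X):
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid), rank

    X = np.ones((n, 1))
    prev_rss, prev_rank = rss_and_rank(X)
    total_ss = prev_rss  # SS around the mean
    rows = []
    for col, block in blocks:
        X = np.hstack([X, block])
        rss, rank = rss_and_rank(X)
        df_k = rank - prev_rank
        if df_k == 0:
            raise ValueError(f"factor {col!r} is collinear with earlier terms (df = 0)")
        rows.append({"source": col, "df": df_k, "sum_sq": prev_rss - rss})
        prev_rss, prev_rank = rss, rank

    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = prev_rss / df_res
    out = pd.DataFrame(rows).set_index("source")
    out["prop_var"] = out["sum_sq"] / total_ss
    with np.errstate(divide="ignore", invalid="ignore"):
        out["F"] = (out["sum_sq"] / out["df"]) / ms_res
    out["p"] = stats.f.sf(out["F"], out["df"], df_res)
    out.loc["residual"] = [df_res, prev_rss, prev_rss / total_ss, np.nan, np.nan]
    out.loc["total"] = [n - 1, total_ss, 1.0, np.nan, np.nan]
    out["df"] = out["df"].astype(int)
    out.index.name = None
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    list_name: str
    overlap: int
    list_size: int
    module_size: int
    universe_size: int
    tail: str
    p: float
    p_bonferroni: float


def hypergeometric_enrichment(
    module_genes: set,
    lists: Mapping[str, set],
    universe: set,
    tail: str = "over",
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of each gene list.

    Drawing ``n = |module|`` genes from a universe of ``N`` containing
    ``K`` list members, the over tail is P[X >= x] and the under tail
    P[X <= x] for the observed overlap x.  Bonferroni multiplies by the
    number of tested lists (capped at 1).  Lists disjoint from the
    universe are skipped with a warning.
    """
    if not universe:
        raise ValueError("empty universe")
    if tail not in ("over", "under"):
        raise ValueError("tail must be 'over' or 'under'")
    module = set(module_genes) & set(universe)
    if module != set(module_genes):
        raise ValueError("module genes must be a subset of the universe")
    results = []
    tested = []
    for name, genes in lists.items():
        K = len(set(genes) & set(universe))
        if K == 0:
            import warnings

            warnings.warn(f"gene list {name!r} is disjoint from the universe; skipped")
            continue
        tested.append((name, K))
    m = len(tested)
    N, n = len(universe), len(module)
    for name, K in tested:
        x = len(set(lists[name]) & module)
        if tail == "over":
            p = float(stats.hypergeom.sf(x - 1, N, K, n))
        else:
            p = float(stats.hypergeom.cdf(x, N, K, n))
        p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(
                list_name=name, overlap=x, list_size=K, module_size=n,
                universe_size=N, tail=tail, p=p, p_bonferroni=min(1.0, p * m),
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])


def flag_filter_probes(
    probes: pd.DataFrame,
    module_probes,
    flags: Sequence[str] = ("polymorphic", "cross_reactive"),
) -> tuple[pd.DataFrame, list[str]]:
    """Counts of flagged probes in the module and universe, plus the
    module probe list with flagged probes removed.

    The counts are the inputs to :func:`hypergeometric_enrichment` when
    testing whether a module is under-enriched for problematic probes.
    """
    table = probes.set_index("probe_id")
    unknown = [f for f in flags if f not in table.columns]
    if unknown:
        raise KeyError(f"unknown flags: {unknown}")
    module_probes = list(module_probes)
    sub = table.loc[module_probes]
    rows = []
    for f in flags:
        rows.append(
            {
                "flag": f,
                "module_flagged": int(sub[f].sum()),
                "module_size": len(module_probes),
                "universe_flagged": int(table[f].sum()),
                "universe_size": len(table),
            }
        )
    any_flag = sub[list(flags)].any(axis=1)
    filtered = list(sub.index[~any_flag])
    return pd.DataFrame(rows), filtered


def read_gene_lists(path, sep: str = "\t") -> dict[str, set]:
    """Read named gene sets from a two-column (list_name, gene) file."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("gene list file needs columns (list_name, gene)")
    name_col, gene_col = df.columns[:2]
    return {
        str(name): set(g.astype(str)) for name, g in df.groupby(name_col)[gene_col]
    }
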