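"""Sample quality control by inter-array connectivity.

A sample's connectivity is its mean Pearson correlation with all other
samples (over probes, pairwise-complete).  Samples whose connectivity
falls at or below ``mean - sd_multiplier * SD`` are removed, and the
procedure iterates on the reduced matrix until no sample qualifies or
``max_iter`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCReport", "remove_outlier_samples", "mean_interarray_correlation"]


@dataclass
class QCReport:
    sd_multiplier: float
    removed_per_iteration: list[list[str]] = field(default_factory=list)
    connectivity_per_iteration: list[pd.Series] = field(default_factory=list)

    @property
    def removed_sample_ids(self) -> list[str]:
        return [s for it in self.removed_per_iteration for s in it]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, conn in enumerate(self.connectivity_per_iteration):
            removed = set(self.removed_per_iteration[i]) if i < len(self.removed_per_iteration) else set()
            for sample, value in conn.items():
                rows.append(
                    {
                        "iteration": i + 1,
                        "sample_id": sample,
                        "mean_interarray_cor": value,
                        "removed": sample in removed,
                    }
                )
        return pd.DataFrame(rows)


def mean_interarray_correlation(beta: pd.DataFrame) -> pd.Series:
    """Mean correlation of each sample with every other sample."""
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    values = beta.to_numpy(dtype=float)
    if np.isnan(values).any():
        corr = beta.corr().to_numpy()  # pairwise-complete
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    return pd.Series(np.nanmean(corr, axis=1), index=beta.columns)


def remove_outlier_samples(
    beta: pd.DataFrame, sd_multiplier: float = 2.0, max_iter: int = 2
) -> tuple[pd.DataFrame, QCReport]:
    """Iteratively drop low-connectivity samples; returns (matrix, report).

    Removal is inclusive at the threshold.  A zero standard deviation
    (all samples equally connected) removes nothing.
    """
    report = QCReport(sd_multiplier=sd_multiplier)
    current = beta
    for _ in range(max_iter):
        conn = mean_interarray_correlation(current)
        report.connectivity_per_iteration.append(conn)
        sd = float(conn.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            report.removed_per_iteration.append([])
            break
        threshold = float(conn.mean()) - sd_multiplier * sd
        drop = list(conn.index[conn <= threshold])
        report.removed_per_iteration.append(drop)
        if not drop:
            break
        current = current.drop(columns=drop)
        if current.shape[1] < 3:
            raise ValueError("outlier removal left fewer than 3 samples")
    return current, report
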