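"""R_o/e: observed/expected enrichment of cell clusters across phenotypes.

Given a clusters x groups contingency table of cell counts, the expected
count under the chi-square independence model is

    expected[c, g] = rowsum[c] * colsum[g] / total

and R_o/e = observed / expected.  A value above 1 marks enrichment of
the cluster in that phenotype, below 1 depletion; exactly 1 is labelled
neutral (the boundary case is not defined by the >1 / <1 convention).
No p-value is attached — the ratio itself is the statistic reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ConfigError


@dataclass
class RoeTable:
    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame
    label: pd.DataFrame  # enriched / depleted / neutral / missing


def roe(counts: pd.DataFrame) -> RoeTable:
    """R_o/e for a nonnegative-integer clusters x groups table.

    Columns with zero total have no defined expectation; their ratios are
    reported missing (NaN) rather than raising.
    """
    obs = counts.astype(float)
    vals = obs.to_numpy()
    if (vals < 0).any():
        raise ConfigError("contingency table must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ConfigError("contingency table is empty")
    rowsum = vals.sum(axis=1, keepdims=True)
    colsum = vals.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / total
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(expected > 0, vals / np.where(expected > 0, expected, 1.0), np.nan)
    exp_df = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    ratio_df = pd.DataFrame(ratio, index=obs.index, columns=obs.columns)
    label = ratio_df.map(
        lambda r: "missing"
        if np.isnan(r)
        else ("enriched" if r > 1 else ("depleted" if r < 1 else "neutral"))
    )
    return RoeTable(observed=obs, expected=exp_df, ratio=ratio_df, label=label)


def roe_from_cells(cell_meta: pd.DataFrame, cluster_col: str = "celltype",
                   group_col: str = "group") -> RoeTable:
    """Convenience: build the contingency table from per-cell metadata."""
    for col in (cluster_col, group_col):
        if col not in cell_meta.columns:
            raise ConfigError(f"unknown metadata column {col!r}")
    table = pd.crosstab(cell_meta[cluster_col], cell_meta[group_col])
    return roe(table)
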