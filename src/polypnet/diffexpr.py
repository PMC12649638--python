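"""Differential expression screening.

The statistic is a deliberately simple, documented stand-in: per-gene
log2 fold change as the difference of group means on the log2(CPM+1)
scale, a two-sided Welch t-test per gene, and Benjamini--Hochberg
adjustment over all tested genes.  The selection rule is applied with
strict inequalities: a gene is a DEG iff |log2FC| > 1 AND q < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import benjamini_hochberg

__all__ = ["normalize_counts", "de_table", "screen"]


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) normalisation of a genes x samples count matrix."""
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    library = values.sum(axis=0)
    zero = np.flatnonzero(library == 0)
    if zero.size:
        names = [str(counts.columns[i]) for i in zero]
        raise ValueError(f"zero library size in sample(s): {names}")
    cpm = values / library * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def de_table(
    norm_matrix: pd.DataFrame,
    groups: pd.Series,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene fold change, Welch-t p, BH q and the DEG selection flag.

    ``groups`` maps sample id to {control, feeding}.  log2FC is oriented
    Feeding/Control: positive = up in the feeding group.  A gene with zero
    variance in both groups gets p = 1 when the means are equal (no
    evidence) and p = 0 when they differ (infinite separation).
    """
    groups = groups.reindex(norm_matrix.columns)
    if groups.isna().any():
        missing = list(norm_matrix.columns[groups.isna()])
        raise ValueError(f"samples missing a group label: {missing}")
    control = norm_matrix.loc[:, (groups == "control").to_numpy()]
    feeding = norm_matrix.loc[:, (groups == "feeding").to_numpy()]
    if control.shape[1] < 2 or feeding.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")

    c = control.to_numpy(dtype=float)
    f = feeding.to_numpy(dtype=float)
    log2fc = f.mean(axis=1) - c.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes produce degenerate t statistics; they are given
        # explicit conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(f, c, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    both_zero_var = (c.var(axis=1) == 0) & (f.var(axis=1) == 0)
    p[both_zero_var & (log2fc == 0)] = 1.0
    p[both_zero_var & (log2fc != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)  # any residual degenerate case: no evidence

    q = benjamini_hochberg(p)
    selected = (np.abs(log2fc) > lfc_threshold) & (q < q_threshold)
    direction = np.where(log2fc > 0, "feeding_up", "control_up")
    return pd.DataFrame(
        {
            "gene": norm_matrix.index,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "selected": selected,
            "direction": direction,
        }
    ).set_index("gene")


def screen(results: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Selected DEG subset plus directional counts.

    The two counts partition the selected set: ``feeding_up`` genes have
    log2FC > 0, ``control_up`` genes log2FC < 0 (a selected gene always has
    |log2FC| > 1, so the sign is never zero).
    """
    if results.empty:
        return results.copy(), {"feeding_up": 0, "control_up": 0}
    selected = results[results["selected"]].copy()
    counts = {
        "feeding_up": int((selected["direction"] == "feeding_up").sum()),
        "control_up": int((selected["direction"] == "control_up").sum()),
    }
    return selected, counts
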