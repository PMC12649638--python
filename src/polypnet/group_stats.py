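"""Two-group inference with assumption-routed test selection, BH FDR, PCA.

The routing rule: each physiological variable is checked per group with
Shapiro--Wilk (normality) and across groups with Levene's test
(homogeneity of variance).  If every assumption p-value is at or above the
assumption alpha, a two-sided pooled-variance Student's t-test is run;
otherwise the two-sided Mann--Whitney U test (exact enumeration for small
tie-free samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "PcaResult",
    "compare_groups",
    "compare_all_traits",
    "benjamini_hochberg",
    "pca",
    "significance_stars",
]


@dataclass
class GroupTestResult:
    trait: str
    route: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    significant: bool
    shapiro_p_a: float
    shapiro_p_b: float
    levene_p: float
    stars: str


@dataclass
class PcaResult:
    variance_explained: np.ndarray  # percent per component, sums to 100
    loadings: pd.DataFrame  # variable x component, unit columns
    scores: pd.DataFrame  # sample x component


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _shapiro_p(x: np.ndarray) -> float:
    # Shapiro-Wilk is undefined for a constant vector; treat it as giving
    # no evidence against normality so routing falls through to the t-test
    # conventions (which handle zero variance explicitly).
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    alpha_assumptions: float = 0.05,
    trait: str = "",
    median_center_levene: bool = False,
) -> GroupTestResult:
    """Assumption-routed two-group comparison of one variable.

    ``a`` is the control-side sample, ``b`` the treatment side.  The route
    is a deterministic function of the data and ``alpha_assumptions``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")

    sp_a, sp_b = _shapiro_p(a), _shapiro_p(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        levene_p = 1.0
    else:
        center = "median" if median_center_levene else "mean"
        levene_p = float(stats.levene(a, b, center=center).pvalue)

    assumptions_met = min(sp_a, sp_b, levene_p) >= alpha_assumptions
    if assumptions_met:
        route = "student_t"
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(p):  # zero pooled variance
                stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        route = "mann_whitney"
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)

    return GroupTestResult(
        trait=trait,
        route=route,
        statistic=stat,
        p_value=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        significant=bool(p < alpha),
        shapiro_p_a=sp_a,
        shapiro_p_b=sp_b,
        levene_p=levene_p,
        stars=significance_stars(p),
    )


def compare_all_traits(
    physio: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
    alpha_assumptions: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`compare_groups` on every numeric column of a trait table.

    Group a = control, group b = feeding.  Returns one row per trait with
    significance stars matching the conventional figure legend
    (* p<0.05, ** p<0.01, *** p<0.001).
    """
    groups = physio[group_col]
    traits = [c for c in physio.columns if c != group_col and pd.api.types.is_numeric_dtype(physio[c])]
    rows = []
    for trait in traits:
        res = compare_groups(
            physio.loc[groups == "control", trait],
            physio.loc[groups == "feeding", trait],
            alpha=alpha,
            alpha_assumptions=alpha_assumptions,
            trait=trait,
        )
        rows.append(vars(res))
    out = pd.DataFrame(rows)
    return out.rename(
        columns={
            "mean_a": "mean_control", "sd_a": "sd_control", "n_a": "n_control",
            "mean_b": "mean_feeding", "sd_b": "sd_feeding", "n_b": "n_feeding",
            "shapiro_p_a": "shapiro_p_control", "shapiro_p_b": "shapiro_p_feeding",
        }
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pca(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Principal component analysis of a samples x variables table.

    Columns are centred (and scaled to unit SD when ``standardize``), the
    SVD taken, and each loading column's sign fixed so its largest-magnitude
    entry is positive -- the convention that makes biplots reproducible
    across linear-algebra backends.
    """
    data = table.dropna()
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            names = [str(data.columns[i]) for i in constant]
            raise ValueError(f"constant variable(s) cannot be standardized: {names}")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive per component
    for k in range(vt.shape[0]):
        idx = int(np.argmax(np.abs(vt[k])))
        if vt[k, idx] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total = float((s**2).sum())
    variance_explained = s**2 / total * 100.0 if total > 0 else np.zeros_like(s)
    comps = [f"PC{k + 1}" for k in range(s.size)]
    return PcaResult(
        variance_explained=variance_explained,
        loadings=pd.DataFrame(vt.T, index=data.columns, columns=comps),
        scores=pd.DataFrame(u * s, index=data.index, columns=comps),
    )
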