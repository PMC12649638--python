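"""Correlation-network module detection and module--trait inference.

The procedure, end to end:

1. filter genes (mean floor, then top-N by variance; default N = 5000);
2. pairwise Pearson correlation R and unsigned distance D = 1 - |r|;
3. agglomerative clustering of D with Ward's minimum-variance criterion in
   its "Ward.D2" reading: the Lance--Williams recurrence applied to
   *squared* input distances, merge heights reported unsquared;
4. a simplified dynamic tree cut: static cut height (default the 0.99
   quantile of merge heights), minimum module size (default 30, branches
   below it left unassigned/"grey"), then a recursive refinement that
   splits a cluster at its top merge whenever both children meet the
   minimum size.  The refinement deliberately over-fragments;
5. module eigengenes (first principal component of the module's
   standardized expression, unit variance, sign aligned with the module
   mean profile) and iterative merging of module pairs whose eigengenes
   correlate above r = 0.75, which re-assembles the fragments into
   coherent modules;
6. kME (gene--eigengene correlation), module--trait Pearson tests with
   Benjamini--Hochberg adjustment (significant iff q < 0.05), and
   node/edge table export.

Modules are named by the conventional size-ranked colour palette
(turquoise, blue, brown, yellow, ...); "grey" marks unassigned genes.

Every tie is broken deterministically (lowest index), so identical inputs
and parameters give byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import benjamini_hochberg

__all__ = [
    "MODULE_COLORS",
    "Linkage",
    "EigengeneTable",
    "filter_genes",
    "correlation_and_distance",
    "ward_linkage",
    "cut_dendrogram",
    "module_eigengene",
    "merge_modules",
    "kme",
    "module_trait",
    "export_network",
    "color_names",
]

logger = logging.getLogger(__name__)

#: Size-rank colour palette; index 0 names the largest module.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass(frozen=True)
class Linkage:
    """Agglomerative merge sequence over ``n_leaves`` leaves.

    ``merges`` has one row per merge: (child_i, child_j, height, new_size),
    children identified as leaves 0..n-1 and internal clusters n..2n-2 in
    merge order, child_i < child_j.
    """

    merges: np.ndarray
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class EigengeneTable:
    """Module eigengenes (module x sample) with variance-explained fractions."""

    eigengenes: pd.DataFrame
    variance_explained: pd.Series


def color_names(labels: np.ndarray) -> np.ndarray:
    """Map integer module labels (0 = unassigned) to colour names."""
    labels = np.asarray(labels)
    out = np.empty(labels.shape, dtype=object)
    for lab in np.unique(labels):
        if lab == 0:
            name = "grey"
        elif lab <= len(MODULE_COLORS):
            name = MODULE_COLORS[lab - 1]
        else:
            name = f"module{lab}"
        out[labels == lab] = name
    return out


def filter_genes(
    norm_matrix: pd.DataFrame,
    min_mean: float | None = 0.0,
    top_n: int = 5000,
) -> pd.DataFrame:
    """Drop low-expression genes, keep the ``top_n`` most variable.

    ``min_mean`` is a floor on the gene's mean (log-scale) expression;
    pass ``None`` to skip the mean filter.  If fewer than ``top_n`` genes
    survive, all are kept with a warning.  Original row order is preserved.
    """
    kept = norm_matrix
    if min_mean is not None:
        kept = kept.loc[kept.mean(axis=1) >= min_mean]
    if kept.empty:
        raise ValueError("no genes survive the mean-expression filter")
    if top_n < len(kept):
        variances = kept.var(axis=1, ddof=1).to_numpy()
        order = np.argsort(-variances, kind="stable")[:top_n]
        kept = kept.iloc[np.sort(order)]
    else:
        if top_n > len(kept):
            warnings.warn(
                f"top_n={top_n} exceeds the {len(kept)} genes available; keeping all",
                stacklevel=2,
            )
    return kept


def correlation_and_distance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene--gene Pearson correlation R and unsigned distance D = 1 - |R|."""
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=1)
    zero = np.flatnonzero(variances == 0)
    if zero.size:
        names = [str(matrix.index[i]) for i in zero[:5]]
        raise ValueError(f"zero-variance gene(s) must be filtered first: {names}")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    idx = matrix.index
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(d, index=idx, columns=idx),
    )


def _validate_distance(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")


def ward_linkage(D) -> Linkage:
    """Ward.D2 agglomerative linkage of a distance matrix.

    At every step the minimum-distance active pair is merged (ties broken
    by the lowest index pair, leaves keeping their positions and a merged
    cluster taking its smaller constituent's position) and distances to the
    new cluster updated with the Lance--Williams recurrence on squared
    distances:

        d(k, i+j)^2 = ((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2)
                      / (n_i + n_j + n_k)

    Heights are reported unsquared.  Ward heights are non-decreasing; an
    inversion indicates a malformed input and is logged as an error.
    """
    if isinstance(D, pd.DataFrame):
        D = D.to_numpy()
    D = np.asarray(D, dtype=float)
    _validate_distance(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")

    d2 = D.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    ids = np.arange(n)
    # nearest-neighbour bookkeeping: nn[i] is the first argmin of row i
    nn = np.argmin(d2, axis=1)
    nnd = d2[np.arange(n), nn]

    merges = np.empty((n - 1, 4))
    last_height = -np.inf
    for step in range(n - 1):
        masked = np.where(active, nnd, np.inf)
        i = int(np.argmin(masked))
        j = int(nn[i])
        if j < i:
            i, j = j, i
        h2 = d2[i, j]
        height = float(np.sqrt(max(h2, 0.0)))
        if height < last_height - 1e-12:
            logger.error(
                "non-monotone merge height %.6g after %.6g at step %d",
                height, last_height, step,
            )
        last_height = max(last_height, height)

        ci, cj = int(ids[i]), int(ids[j])
        merges[step] = (min(ci, cj), max(ci, cj), height, sizes[i] + sizes[j])
        if step == n - 2:
            break

        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        si, sj = sizes[i], sizes[j]
        sk = sizes[others]
        dnew = ((si + sk) * d2[i, others] + (sj + sk) * d2[j, others] - sk * h2) / (
            si + sj + sk
        )
        d2[i, others] = dnew
        d2[others, i] = dnew
        d2[i, i] = np.inf
        active[j] = False
        d2[j, :] = np.inf
        d2[:, j] = np.inf
        sizes[i] = si + sj
        ids[i] = n + step
        nnd[j] = np.inf

        # repair nearest neighbours: the new cluster may be closer, and rows
        # that pointed at i or j are stale
        better = dnew < nnd[others]
        nn[others[better]] = i
        nnd[others[better]] = dnew[better]
        stale = others[~better]
        stale = stale[(nn[stale] == i) | (nn[stale] == j)]
        for k in stale:
            nn[k] = int(np.argmin(d2[k]))
            nnd[k] = d2[k, nn[k]]
        nn[i] = int(np.argmin(d2[i]))
        nnd[i] = d2[i, nn[i]]

    return Linkage(merges=merges, n_leaves=n)


def _subtree_leaves(linkage: Linkage) -> list[np.ndarray]:
    """Leaf index sets for every node (leaves then internal, merge order)."""
    n = linkage.n_leaves
    leaves: list[np.ndarray] = [np.array([i]) for i in range(n)]
    for a, b, _h, _s in linkage.merges:
        leaves.append(np.concatenate([leaves[int(a)], leaves[int(b)]]))
    return leaves


def _rank_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel non-zero modules 1..k by decreasing size (ties: smallest member)."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    info = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = np.flatnonzero(labels == lab)
        info.append((-members.size, int(members[0]), lab))
    for rank, (_neg, _first, lab) in enumerate(sorted(info), start=1):
        out[labels == lab] = rank
    return out


def cut_dendrogram(linkage: Linkage, cut_height: float | None = None, min_size: int = 30) -> np.ndarray:
    """Cut a dendrogram into raw modules (0 = unassigned).

    Initial clusters are the maximal subtrees whose merges all lie below
    ``cut_height`` (default: the 0.99 quantile of merge heights).  Clusters
    below ``min_size`` become unassigned.  A recursive refinement then
    splits every kept cluster at its top merge whenever both children meet
    ``min_size``, repeating until stable -- by design this over-fragments
    large branches; :func:`merge_modules` re-assembles fragments whose
    eigengenes agree.  Surviving clusters are labelled by size rank.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    heights = linkage.heights
    if cut_height is None:
        cut_height = float(np.quantile(heights, 0.99))
    elif cut_height <= 0:
        raise ValueError("cut_height must be positive")

    n = linkage.n_leaves
    parent = np.full(2 * n - 1, -1)
    node_size = np.ones(2 * n - 1)
    for t in range(n - 1):
        a, b = int(linkage.merges[t, 0]), int(linkage.merges[t, 1])
        parent[a] = parent[b] = n + t
        node_size[n + t] = linkage.merges[t, 3]

    def node_height(node: int) -> float:
        return 0.0 if node < n else float(heights[node - n])

    roots = []
    for node in range(2 * n - 1):
        below = node_height(node) < cut_height
        par = parent[node]
        parent_above = par == -1 or node_height(int(par)) >= cut_height
        if below and parent_above:
            roots.append(node)

    leaves = _subtree_leaves(linkage)
    children = linkage.merges[:, :2].astype(int)

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for root in roots:
        if node_size[root] < min_size:
            continue  # grey
        stack = [root]
        while stack:
            node = stack.pop()
            if node >= n:
                c1, c2 = children[node - n]
                if node_size[c1] >= min_size and node_size[c2] >= min_size:
                    stack.extend((int(c2), int(c1)))
                    continue
            labels[leaves[node]] = next_label
            next_label += 1
    return _rank_labels(labels)


def module_eigengene(matrix: pd.DataFrame, labels: np.ndarray) -> EigengeneTable:
    """First-PC eigengene per module over samples.

    Genes are z-scored across samples (ddof=1); the eigengene is the first
    right singular vector of the module's z-matrix, scaled to unit variance
    and signed to correlate non-negatively with the module's mean z-profile.
    The variance-explained fraction is s1^2 / sum(s^2).  A single-gene
    module degenerates to that gene's z-profile (with a warning).
    """
    labels = np.asarray(labels)
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(matrix.index[i]) for i in zero[:5]]
        raise ValueError(f"zero-variance gene(s) in eigengene computation: {names}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]

    module_labels = [int(m) for m in np.unique(labels) if m != 0]
    rows, fracs = [], []
    for m in module_labels:
        zm = z[labels == m]
        if zm.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene; eigengene is its z-profile", stacklevel=2)
            e, frac = zm[0].copy(), 1.0
        else:
            _u, s, vt = np.linalg.svd(zm, full_matrices=False)
            e = vt[0]
            frac = float(s[0] ** 2 / (s**2).sum())
        mean_profile = zm.mean(axis=0)
        if np.dot(e - e.mean(), mean_profile - mean_profile.mean()) < 0:
            e = -e
        e_sd = e.std(ddof=1)
        if e_sd > 0:
            e = e / e_sd
        rows.append(e)
        fracs.append(frac)

    eig = pd.DataFrame(rows, index=pd.Index(module_labels, name="module"), columns=matrix.columns)
    return EigengeneTable(
        eigengenes=eig,
        variance_explained=pd.Series(fracs, index=eig.index, name="variance_explained"),
    )


def merge_modules(
    matrix: pd.DataFrame, labels: np.ndarray, r_threshold: float = 0.75
) -> np.ndarray:
    """Iteratively merge the module pair with the most similar eigengenes.

    While the maximal pairwise eigengene Pearson r exceeds ``r_threshold``
    the corresponding pair (lowest label pair on ties) is merged and
    eigengenes recomputed.  Unassigned genes never merge.  The result is
    relabelled by size rank, and the stopping rule guarantees no remaining
    eigengene pair correlates above the threshold.
    """
    labels = np.asarray(labels).copy()
    while True:
        module_labels = [int(m) for m in np.unique(labels) if m != 0]
        if len(module_labels) < 2:
            break
        table = module_eigengene(matrix, labels)
        corr = np.corrcoef(table.eigengenes.to_numpy())
        iu = np.triu_indices(len(module_labels), k=1)
        pair_r = corr[iu]
        best = int(np.argmax(pair_r))
        if pair_r[best] <= r_threshold:
            break
        a = module_labels[iu[0][best]]
        b = module_labels[iu[1][best]]
        labels[labels == b] = a
    return _rank_labels(labels)


def kme(matrix: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Gene x module table of gene--eigengene Pearson correlations."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(matrix.index[i]) for i in zero[:5]]
        raise ValueError(f"zero-variance gene(s): {names}")
    me = eigengenes.to_numpy(dtype=float)
    zm = (me - me.mean(axis=1, keepdims=True)) / me.std(axis=1, ddof=0)[:, None]
    n = values.shape[1]
    zg = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=0)[:, None]
    table = zg @ zm.T / n
    return pd.DataFrame(
        np.clip(table, -1.0, 1.0), index=matrix.index, columns=eigengenes.index
    )


def module_trait(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson module--trait association with BH adjustment.

    ``traits`` is a samples x traits numeric table (the group indicator is
    conventionally coded 0 = control, 1 = feeding).  For each pair the
    Pearson r and its two-sided p-value from the t-transform
    t = r sqrt(n-2)/sqrt(1-r^2) are computed; q-values are BH-adjusted over
    all module x trait pairs and significance means q < alpha.  Shapiro--Wilk
    normality checks on each eigengene and trait are recorded as warning
    flags, not gates.
    """
    traits = traits.loc[eigengenes.columns]
    n = eigengenes.shape[1]
    if n < 4:
        raise ValueError("module--trait inference needs at least 4 samples")
    constant = [c for c in traits.columns if np.ptp(traits[c].to_numpy(dtype=float)) == 0]
    if constant:
        raise ValueError(f"constant trait(s): {constant}")

    def shapiro_p(x: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    me_shapiro = {m: shapiro_p(eigengenes.loc[m].to_numpy()) for m in eigengenes.index}
    trait_shapiro = {t: shapiro_p(traits[t].to_numpy(dtype=float)) for t in traits.columns}

    rows = []
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        for t in traits.columns:
            x = traits[t].to_numpy(dtype=float)
            r = float(np.corrcoef(e, x)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
                p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            rows.append(
                {
                    "module": m,
                    "trait": t,
                    "pearson_r": r,
                    "p_value": p,
                    "me_shapiro_p": me_shapiro[m],
                    "trait_shapiro_p": trait_shapiro[t],
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    out["normality_warning"] = (out["me_shapiro_p"] < alpha) | (out["trait_shapiro_p"] < alpha)
    return out


def export_network(
    R: pd.DataFrame,
    labels: np.ndarray,
    kme_table: pd.DataFrame,
    edge_min_abs_r: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the within-module correlation network.

    Nodes: every assigned gene with its module colour and own-module kME.
    Edges: same-module gene pairs with |r| >= ``edge_min_abs_r``, weighted
    by |r|.  Rows are ordered by module size rank then gene index, which
    makes the export deterministic.
    """
    labels = np.asarray(labels)
    colors = color_names(labels)
    genes = R.index.to_numpy()

    node_rows, edge_rows = [], []
    for lab in sorted(int(m) for m in np.unique(labels) if m != 0):
        members = np.flatnonzero(labels == lab)
        color = colors[members[0]]
        for g in members:
            node_rows.append(
                {
                    "gene": genes[g],
                    "module": color,
                    "kme": float(kme_table.iloc[g][lab]) if lab in kme_table.columns else np.nan,
                }
            )
        sub = np.abs(R.iloc[members, members].to_numpy())
        ii, jj = np.triu_indices(len(members), k=1)
        keep = sub[ii, jj] >= edge_min_abs_r
        for a, b, w in zip(ii[keep], jj[keep], sub[ii, jj][keep]):
            edge_rows.append(
                {
                    "gene_a": genes[members[a]],
                    "gene_b": genes[members[b]],
                    "module": color,
                    "weight": float(w),
                }
            )
    nodes = pd.DataFrame(node_rows, columns=["gene", "module", "kme"])
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "module", "weight"])
    return nodes, edges
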