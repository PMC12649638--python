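"""Hypergeometric over-representation analysis of gene sets.

For a query of ``n`` genes drawn from a universe of ``N`` annotatable
genes, a term annotating ``K`` genes with ``k`` of them in the query gets
the upper-tail probability P(X >= k) of the hypergeometric distribution.
Benjamini--Hochberg q-values are reported alongside; the conventional
significance call for term enrichment uses the raw p at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .group_stats import benjamini_hochberg

__all__ = ["AnnotationMap", "enrich"]


@dataclass
class AnnotationMap:
    """Term -> gene-set mapping over a gene universe."""

    terms: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items() if g}
        self.universe = frozenset(self.universe)
        stray = {t for t, g in self.terms.items() if not g <= self.universe}
        if stray:
            raise ValueError(f"terms annotate genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_pairs(cls, pairs, universe=None) -> "AnnotationMap":
        """Build from (gene, term) pairs; universe defaults to all genes seen."""
        terms: dict[str, set] = {}
        genes = set()
        for gene, term in pairs:
            terms.setdefault(str(term), set()).add(str(gene))
            genes.add(str(gene))
        return cls(terms=terms, universe=frozenset(universe) if universe else frozenset(genes))

    @classmethod
    def from_tsv(cls, path, universe=None) -> "AnnotationMap":
        """Two-column TSV: gene, term (header optional rows starting with #)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "term"])
        return cls.from_pairs(df.itertuples(index=False), universe=universe)

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationMap":
        """GMT format: term <tab> description <tab> gene1 <tab> gene2 ..."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                term = fields[0]
                pairs.extend((g, term) for g in fields[2:] if g)
        return cls.from_pairs(pairs, universe=universe)


def enrich(
    query_genes,
    annotation: AnnotationMap,
    universe_override=None,
) -> pd.DataFrame:
    """Over-representation test of a query against every annotated term.

    Returns a table (term, k, K, n, N, p_value, q_value) sorted by p
    ascending, ties broken by term id.  Query genes outside the universe
    are dropped with a warning; an empty intersection is an error.
    """
    universe = frozenset(universe_override) if universe_override else annotation.universe
    query = {str(g) for g in query_genes}
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    rows = []
    for term, genes in annotation.terms.items():
        term_genes = genes & universe
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if out.empty:
        return out.assign(q_value=[])
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
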