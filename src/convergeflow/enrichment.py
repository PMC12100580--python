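"""Flat-set GO over-representation tests and enriched-term overlap.

Terms are treated as flat gene sets (annotation inputs may already carry
propagated ancestors; no ontology graph is consulted here). For a study
set of n genes drawn from a universe of N, a term annotating K universe
genes and k study genes gets the upper-tail hypergeometric probability of
drawing >= k annotated genes; BH FDR across terms. "Enriched" requires
both padj below the threshold and over-representation (k/n > K/N).

Because small intersection sets are often too small to test directly, the
overlap strategy runs enrichment separately per comparison and intersects
the enriched term sets afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .de_convergence import bh_fdr

ANNOTATION_SCHEMA = {"gene": str, "term": str}


@dataclass(frozen=True)
class AnnotationMap:
    gene_terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.gene_terms) - set(self.universe)
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_table(cls, df: pd.DataFrame, universe=None) -> "AnnotationMap":
        gt: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            gt.setdefault(str(row.gene), set()).add(str(row.term))
        uni = frozenset(universe) if universe is not None else frozenset(gt)
        return cls({g: frozenset(t) for g, t in gt.items()}, uni)

    def term_genes(self) -> dict[str, frozenset[str]]:
        tg: dict[str, set[str]] = {}
        for g, terms in self.gene_terms.items():
            for t in terms:
                tg.setdefault(t, set()).add(g)
        return {t: frozenset(g) for t, g in tg.items()}


def hypergeom_enrich(study: set[str], annotations: AnnotationMap,
                     alpha_fdr: float = 0.05, min_term_size: int = 2) -> pd.DataFrame:
    """Per-term over-representation of a study set within the universe.

    Terms annotating fewer than ``min_term_size`` universe genes are
    untestable and skipped. Returns term, k, n, K, N, pvalue, padj and the
    ``enriched`` flag.
    """
    study = set(study)
    if not study:
        raise ValueError("empty study set")
    if not study <= set(annotations.universe):
        stray = study - set(annotations.universe)
        raise ValueError(f"study genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(annotations.universe)
    n_study = len(study)
    rows = []
    for term, genes in sorted(annotations.term_genes().items()):
        big_k = len(genes)
        if big_k < min_term_size:
            continue
        k = len(genes & study)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) includes k
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_study))
        rows.append({"term": term, "k": k, "n": n_study, "K": big_k,
                     "N": n_universe, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "pvalue", "padj", "enriched"])
    out["padj"] = bh_fdr(out["pvalue"])
    out["enriched"] = (out["padj"] < alpha_fdr) & (
        out["k"] / out["n"] > out["K"] / out["N"]
    )
    return out


def overlap_enriched_terms(rows_a: pd.DataFrame, rows_b: pd.DataFrame) -> list[str]:
    """Terms enriched in both analyses, lexicographically ordered."""

    def enriched(df: pd.DataFrame) -> set[str]:
        if df.empty:
            return set()
        return set(df.loc[df["enriched"].astype(bool), "term"])

    return sorted(enriched(rows_a) & enriched(rows_b))
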