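"""Generic term-enrichment over a user-supplied gene -> terms annotation.

A hypergeometric upper-tail test per term: given a background of N genes
of which K carry the term, the probability of observing at least k
term-carrying genes in a selection of n is

    p = sum_{i >= k} C(K, i) C(N - K, n - i) / C(N, n)

with optional Benjamini-Hochberg correction across terms.  This is a
plain stand-in for dedicated ontology tooling: it takes any mapping, no
ontology files.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Set

import pandas as pd
from scipy import stats

__all__ = ["enrichment"]


def _bh_adjust(pvals: pd.Series) -> pd.Series:
    n = len(pvals)
    order = pvals.sort_values().index
    adjusted = {}
    prev = 1.0
    for rank, term in zip(range(n, 0, -1), reversed(order)):
        p = pvals[term] * n / rank
        prev = min(prev, p)
        adjusted[term] = min(prev, 1.0)
    return pd.Series(adjusted)


def enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Set[str] | Iterable[str]],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment p-values, sorted ascending.

    ``gene_set`` must be a subset of ``background``; annotation maps
    background genes to their terms (genes without annotation are
    allowed and simply carry no terms).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    gene_set = set(gene_set)
    stray = gene_set - background
    if stray:
        raise ValueError(f"genes not in background: {sorted(stray)[:5]}")

    term_background: Dict[str, int] = {}
    term_hits: Dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):  # type: ignore[arg-type]
            term_background[term] = term_background.get(term, 0) + 1
            if gene in gene_set:
                term_hits[term] = term_hits.get(term, 0) + 1

    N, n = len(background), len(gene_set)
    rows = []
    for term, K in term_background.items():
        k = term_hits.get(term, 0)
        # upper tail including k itself; k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term, "hits": k, "set_size": n,
            "term_size": K, "background": N, "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bh_correction:
        df["p_adjusted"] = _bh_adjust(
            df.set_index("term")["p_value"]
        ).reindex(df["term"]).to_numpy()
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
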