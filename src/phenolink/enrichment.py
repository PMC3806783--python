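"""Hypergeometric gene-set enrichment of ranked candidate genes.

The query is the head of a ranked gene list, truncated to the collection's
mean set size (so the query and the annotated sets are comparable in
scale), and each set is tested with the upper-tail hypergeometric
probability of the observed overlap. Raw p-values are reported by default;
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .iodata import GeneId, GeneSetCollection

__all__ = ["EnrichmentResult", "truncate_query", "hypergeom_test", "enrich"]


@dataclass
class EnrichmentResult:
    set_name: str
    p_value: float
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    q_value: float | None = None  # BH-adjusted, when requested


def _identifiers(genes) -> list[str]:
    return [g.identifier if isinstance(g, GeneId) else str(g) for g in genes]


def truncate_query(
    ranked_genes,
    collection: GeneSetCollection,
    override_n: int | None = None,
) -> list:
    """Head of the ranked list, cut at the collection's rounded mean set
    size (or at ``override_n``); shorter lists pass through whole."""
    n = override_n if override_n is not None else round(collection.mean_set_size())
    return list(ranked_genes)[:n]


def hypergeom_test(query, gene_set, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= overlap).

    With M = |universe|, K = |gene_set|, n = |query ∩ universe| and
    k = |query ∩ gene_set|, the p-value is
    sum_{i=k}^{min(K,n)} C(K,i) C(M-K, n-i) / C(M,n).
    """
    universe = set(_identifiers(universe))
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(_identifiers(gene_set))
    if not gene_set <= universe:
        raise ValueError("gene set not contained in the universe")
    query = set(_identifiers(query)) & universe
    k = len(query & gene_set)
    M, K, n = len(universe), len(gene_set), len(query)
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return EnrichmentResult(
        set_name="", p_value=min(1.0, max(p, 0.0)), overlap=k,
        set_size=K, query_size=n, universe_size=M,
    )


def enrich(
    ranked_genes,
    collection: GeneSetCollection,
    override_n: int | None = None,
    universe=None,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Test every set in the collection against the truncated query.

    The background universe defaults to the union of the collection's
    members. Results are sorted ascending by p-value, ties by set name.
    """
    query = truncate_query(ranked_genes, collection, override_n)
    if universe is None:
        universe = collection.universe
    universe_ids = set(_identifiers(universe))
    results = []
    for name in collection.names():
        desc, members = collection.sets[name]
        r = hypergeom_test(query, set(members) & universe_ids, universe_ids)
        r.set_name = name
        results.append(r)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if adjust and results:
        q = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results
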