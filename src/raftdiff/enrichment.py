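"""Gene-set over-representation and target-list overlap statistics.

The over-representation test is the one-sided hypergeometric upper tail
(Fisher exact): with a population of N genes of which K carry a term, the
p-value for a query of n genes containing k term genes is P(X >= k) for
X ~ Hypergeom(N, K, n).  Fold enrichment is the query fraction over the
background fraction, (k/n)/(K/N).  Bonferroni and Benjamini-Hochberg
corrections are applied within each GO namespace (BP/CC/MF) separately.
The EASE-style penalized variant (scoring k-1 successes) used by some
annotation servers is available as an option.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    MISSING,
    EnrichmentRow,
    GeneSetCollection,
    OverlapSummary,
    normalize_symbol,
)
from .io import ValidationError

log = logging.getLogger("raftdiff")

__all__ = [
    "ora_test",
    "fold_enrichment",
    "bonferroni_adjust",
    "bh_adjust",
    "enrich",
    "overlap_stats",
]


def ora_test(query: set[str], term_genes: set[str], population: set[str],
             ease: bool = False) -> tuple[int, float]:
    """Hypergeometric upper-tail over-representation test.

    Returns ``(k, p)`` with k the query/term intersection size and p the
    probability of drawing >= k term genes when sampling |query| genes
    without replacement from the population.  ``ease=True`` scores k-1
    successes (more conservative for small k).
    """
    offenders = query - population
    if offenders:
        raise ValidationError(
            "query genes outside the population: " + ", ".join(sorted(offenders))
        )
    if not term_genes <= population:
        raise ValidationError("term genes outside the population")
    k = len(query & term_genes)
    k_eff = max(k - 1, 0) if ease else k
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k_eff - 1, len(population), len(term_genes),
                                 len(query)))
    return k, min(p, 1.0)


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): query fraction over background fraction in the term."""
    if n <= 0 or N <= 0 or K <= 0:
        raise ValueError("n, K and N must be positive")
    if k == 0:
        return MISSING
    return (k / n) / (K / N)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m*p) for a family of m tests."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(query: set[str], collection: GeneSetCollection,
           ease: bool = False, sort: bool = True) -> list[EnrichmentRow]:
    """Over-representation analysis of a query against a gene-set collection.

    Gene symbols are case-normalized before any set operation.  Returns one
    row per term with count, percent of query, raw p, fold enrichment, and
    Bonferroni/BH corrections computed within each namespace.
    """
    query = {normalize_symbol(g) for g in query}
    population = collection.population
    n, N = len(query), len(population)
    rows: list[EnrichmentRow] = []
    for entry in collection.entries:
        k, p = ora_test(query, set(entry.genes), set(population), ease=ease)
        rows.append(EnrichmentRow(
            term_id=entry.term_id, namespace=entry.namespace,
            term_name=entry.term_name, count=k,
            percent=100.0 * k / n if n else 0.0, p_value=p,
            fold_enrichment=fold_enrichment(k, n, len(entry.genes), N)
            if k else MISSING,
            bonferroni=MISSING, benjamini=MISSING,
        ))
    for ns in {r.namespace for r in rows}:
        ns_rows = [r for r in rows if r.namespace == ns]
        m = len(ns_rows)
        adjusted = bh_adjust([r.p_value for r in ns_rows])
        for r, q in zip(ns_rows, adjusted):
            r.bonferroni = bonferroni_adjust(r.p_value, m)
            r.benjamini = float(q)
    if sort:
        rows.sort(key=lambda r: (r.namespace, r.p_value, r.term_id))
    return rows


def overlap_stats(query, targets, denominator: int | None = None) -> OverlapSummary:
    """Overlap of a query gene set with a target list.

    Symbols are case-normalized first.  ``percent_of_query`` uses
    ``denominator`` when given (e.g. the size of a published parent list),
    otherwise the query size.  Near-synonym symbols that differ after
    normalization (e.g. paralog mixups in printed tables) are not resolved;
    unmatched target symbols are logged to surface such discrepancies.
    """
    qset = {normalize_symbol(g) for g in query}
    tset = {normalize_symbol(g) for g in targets}
    if denominator is None:
        denominator = len(qset)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    overlap = qset & tset
    unmatched = tset - qset
    if unmatched:
        log.info("overlap_stats: %d target symbol(s) not found in query: %s",
                 len(unmatched), ", ".join(sorted(unmatched)))
    return OverlapSummary(
        query_size=len(qset), target_list_size=len(tset),
        overlap=frozenset(overlap), overlap_count=len(overlap),
        percent_of_query=100.0 * len(overlap) / denominator,
    )
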