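"""One-sided Fisher's exact over-representation analysis.

For a study list of n genes drawn from a universe of N, and a term annotated
to K universe genes of which k are in the study list, the over-representation
p-value is the upper hypergeometric tail

    p = P(X >= k),   X ~ Hypergeom(N, K, n)

computed in log space (scipy's hypergeometric survival function), so it is
stable for universes up to ~1e5 genes.  Bonferroni correction multiplies by
the number of terms actually tested; ranks are assigned ascending by raw
p-value with lexicographic term-id tie-breaks so orderings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap: study ∩ term
    K: int  # term set size in universe
    n: int  # study size in universe
    N: int  # universe size
    p_raw: float
    p_adjusted: float
    rank: int


@dataclass(frozen=True)
class TermReportRow:
    term_id: str
    status: str  # tested | filtered_by_size | absent_from_snapshot
    rank: int | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None


def fisher_pvalue(k: int, K: int, n: int, N: int, two_sided: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Arguments are the 2×2 table margins: overlap ``k``, term size ``K``,
    study size ``n``, universe size ``N``.  ``two_sided=True`` instead
    returns the two-sided Fisher exact p-value.
    """
    if not (0 <= k <= min(n, K) and k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid table: k={k}, K={K}, n={n}, N={N}")
    if n - k > N - K:
        raise ValueError(
            f"invalid table: {n - k} study genes outside a term covering "
            f"{N - K} non-term genes (k={k}, K={K}, n={n}, N={N})"
        )
    if two_sided:
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def adjust_bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni correction: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def enrich(
    study_genes: Iterable[str],
    collection: GeneSetCollection,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Test every term in a (size-filtered) collection for over-representation.

    Study genes outside the universe are ignored (``n`` counts universe
    members only; the tally of outsiders is ``len(study) - n``).  Results are
    sorted ascending by raw p, ties broken by term id, and ranked 1..m.
    An empty study∩universe is legal: every k is 0 and every p is 1.
    """
    if not collection.sets:
        raise ValueError("collection has no terms to test")
    if not collection.universe:
        raise ValueError("collection has an empty universe")
    study = frozenset(study_genes) & collection.universe
    N = len(collection.universe)
    n = len(study)
    m = len(collection.sets)

    scored = []
    for term_id, genes in collection.sets.items():
        k = len(study & genes)
        K = len(genes)
        p = fisher_pvalue(k, K, n, N, two_sided=two_sided)
        scored.append((p, term_id, k, K))
    scored.sort(key=lambda item: (item[0], item[1]))

    return [
        EnrichmentResult(
            term_id=term_id,
            term_name=collection.names.get(term_id, ""),
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adjusted=adjust_bonferroni(p, m),
            rank=rank,
        )
        for rank, (p, term_id, k, K) in enumerate(scored, start=1)
    ]


def term_report(
    results: Sequence[EnrichmentResult],
    terms_of_interest: Iterable[str],
    unfiltered_terms: Iterable[str] | None = None,
) -> list[TermReportRow]:
    """Rank/p lookup for requested terms, with explicit absence statuses.

    A requested term missing from ``results`` is ``filtered_by_size`` when it
    appears in ``unfiltered_terms`` (the term ids present before the size
    filter), else ``absent_from_snapshot``.
    """
    by_id = {r.term_id: r for r in results}
    unfiltered = frozenset(unfiltered_terms) if unfiltered_terms is not None else frozenset()
    rows = []
    for term_id in terms_of_interest:
        if term_id in by_id:
            r = by_id[term_id]
            rows.append(TermReportRow(term_id, "tested", r.rank, r.p_raw, r.p_adjusted))
        elif term_id in unfiltered:
            rows.append(TermReportRow(term_id, "filtered_by_size"))
        else:
            rows.append(TermReportRow(term_id, "absent_from_snapshot"))
    return rows


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_adjusted,
                "rank": r.rank,
            }
            for r in results
        ]
    )


def write_results_tsv(results: Sequence[EnrichmentResult], stream: TextIO) -> None:
    results_to_frame(results).to_csv(stream, sep="\t", index=False)
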