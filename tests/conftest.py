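"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths: ancestor
reachability is recomputed by naive recursive edge-following (no
memoization), gene sets by per-gene graph walks, and hypergeometric tails by
exhaustive enumeration with exact integer binomials.
"""

from __future__ import annotations

import io
from math import comb

import pytest

from gochron.annotations import parse_gaf
from gochron.ontology import parse_obo

FOUR_STANZA_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child via is_a
namespace: biological_process
alt_id: GO:0009999
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: child via part_of
namespace: biological_process
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: retired process
namespace: biological_process
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


def _gaf_line(gene, symbol, qualifier, term, evidence, aspect, date):
    cols = ["UniProtKB", gene, symbol, qualifier, term, "PMID:1", evidence,
            "", aspect, "", "", "protein", "taxon:9606", date, "GOC", "", ""]
    return "\t".join(cols)


THREE_LINE_GAF = "\n".join(
    [
        "!gaf-version: 2.1",
        _gaf_line("P00001", "GENEA", "", "GO:0000002", "IDA", "P", "20050101"),
        _gaf_line("P00002", "GENEB", "", "GO:0000001", "IEA", "P", "20100315"),
        _gaf_line("P00003", "GENEC", "", "GO:0000003", "TAS", "P", "20111231"),
    ]
) + "\n"


@pytest.fixture
def four_stanza_graph():
    return parse_obo(io.StringIO(FOUR_STANZA_OBO))


@pytest.fixture
def three_line_annotations():
    return parse_gaf(io.StringIO(THREE_LINE_GAF))


def make_gaf_line(gene, term, evidence="IDA", qualifier="", aspect="P",
                  date="20100101", symbol=None):
    return _gaf_line(gene, symbol or gene, qualifier, term, evidence, aspect, date)


# ---------------------------------------------------------------- oracles


def naive_ancestors(graph, term_id, relations) -> frozenset[str]:
    """Reflexive reachability by plain recursion — no memoization."""

    def walk(tid):
        out = {tid}
        for parent in graph.terms[tid].parents(relations):
            out |= walk(parent)
        return out

    return frozenset(walk(term_id))


def naive_gene_sets(graph, annos, relations) -> dict[str, set[str]]:
    """For each gene, for each directly annotated term, mark every reachable
    ancestor by an independent graph walk."""
    sets: dict[str, set[str]] = {}
    for gene_id, term_id in {(r.gene_id, r.term_id) for r in annos.records}:
        if term_id not in graph.terms or graph.terms[term_id].obsolete:
            continue
        for ancestor in naive_ancestors(graph, term_id, relations):
            sets.setdefault(ancestor, set()).add(gene_id)
    return sets


def hypergeom_tail_by_enumeration(k, K, n, N) -> float:
    """P(X >= k) by exact integer enumeration over the support."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1)) / total
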