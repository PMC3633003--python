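"""Propagated term → gene sets (true-path rule) and term-size filtering.

A direct annotation (gene g, term T) places g in the gene set of T and of
every ancestor of T over the chosen relation set, so parent sets always
contain their children's sets.  Annotations whose term cannot be resolved in
the given ontology snapshot (unknown id, obsolete term, wrong namespace) are
skipped and tallied — essential bookkeeping when pairing annotation files
with ontology versions from a different era.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .annotations import AnnotationSet
from .ontology import (
    DEFAULT_RELATIONS,
    ObsoleteTermError,
    OntologyGraph,
    UnknownTermError,
)


@dataclass
class SkipReport:
    """Counts of direct annotations excluded during gene-set construction."""

    unresolved: int = 0
    obsolete: int = 0
    wrong_namespace: int = 0
    negated: int = 0

    @property
    def total(self) -> int:
        return self.unresolved + self.obsolete + self.wrong_namespace + self.negated


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    namespace: str = "biological_process"
    provenance: tuple[str, str] = ("", "")
    names: dict[str, str] = field(default_factory=dict)
    skip_report: SkipReport = field(default_factory=SkipReport)
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets

    def size(self, term_id: str) -> int:
        return len(self.sets[term_id])


def build_gene_sets(
    graph: OntologyGraph,
    annos: AnnotationSet,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    namespace: str | None = None,
    include_negated: bool = False,
) -> GeneSetCollection:
    """Propagate direct annotations up the ontology into term gene sets.

    Each distinct (gene, term) pair counts once regardless of how many
    evidence lines assert it.  ``namespace`` restricts the build to one
    ontology branch (default: infer nothing, keep all branches represented
    among resolvable terms — pass e.g. ``"biological_process"`` for a
    BP-only collection).  NOT-qualified annotations are skipped unless
    ``include_negated`` — a negated annotation is evidence *against*
    membership.  Terms with empty sets never appear in the map.
    """
    relations = frozenset(relations)
    sets: dict[str, set[str]] = {}
    skip = SkipReport()
    anc_cache: dict[str, frozenset[str]] = {}

    # a pair counts once; it is negated only if *every* asserting line is NOT
    has_plain: dict[tuple[str, str], bool] = {}
    for r in annos.records:
        key = (r.gene_id, r.term_id)
        has_plain[key] = has_plain.get(key, False) or not r.qualifier_negated

    for gene_id, term_id in sorted(has_plain):
        if not include_negated and not has_plain[(gene_id, term_id)]:
            skip.negated += 1
            continue
        try:
            canonical = graph.resolve_term(term_id)
        except ObsoleteTermError:
            skip.obsolete += 1
            continue
        except UnknownTermError:
            skip.unresolved += 1
            continue
        if namespace is not None and graph.terms[canonical].namespace != namespace:
            skip.wrong_namespace += 1
            continue
        if canonical not in anc_cache:
            anc_cache[canonical] = graph.ancestors(canonical, relations)
        for ancestor in anc_cache[canonical]:
            sets.setdefault(ancestor, set()).add(gene_id)

    frozen = {t: frozenset(g) for t, g in sets.items()}
    universe = frozenset().union(*frozen.values()) if frozen else frozenset()
    names = {t: graph.terms[t].name for t in frozen}
    return GeneSetCollection(
        sets=frozen,
        universe=universe,
        namespace=namespace or "all",
        provenance=(graph.snapshot_label, annos.snapshot_label),
        names=names,
        skip_report=skip,
    )


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 500,
    restrict_to: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Keep terms annotated to between ``min_size`` and ``max_size`` genes.

    Bounds are inclusive on both ends.  When ``restrict_to`` is given (e.g.
    the genes measurable on the expression platform), every set and the
    universe are intersected with it *before* the size thresholds apply, so
    sizes are counted within the analysis universe.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")

    if restrict_to is not None:
        restrict = frozenset(restrict_to)
        sets = {t: s & restrict for t, s in collection.sets.items()}
        universe = collection.universe & restrict
    else:
        sets = dict(collection.sets)
        universe = collection.universe

    kept = {t: s for t, s in sets.items() if min_size <= len(s) <= max_size}
    warnings = collection.warnings
    if not kept:
        warnings = warnings + ("size filter removed every term",)
    return GeneSetCollection(
        sets=kept,
        universe=universe,
        namespace=collection.namespace,
        provenance=collection.provenance,
        names={t: collection.names.get(t, "") for t in kept},
        skip_report=collection.skip_report,
        warnings=warnings,
    )


def write_gmt(collection: GeneSetCollection, stream: TextIO) -> None:
    """Write as GMT: term id, term name, then tab-separated gene ids."""
    for term_id in sorted(collection.sets):
        genes = "\t".join(sorted(collection.sets[term_id]))
        name = collection.names.get(term_id, "")
        stream.write(f"{term_id}\t{name}\t{genes}\n")


def read_gmt(stream: Iterable[str]) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"GMT line needs id, name and >=1 gene: {line!r}")
        sets[cols[0]] = frozenset(cols[2:])
        names[cols[0]] = cols[1]
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=universe, names=names)
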