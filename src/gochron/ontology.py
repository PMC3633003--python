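"""Gene Ontology structure: OBO parsing, DAG validation, ancestor queries.

A snapshot of the ontology is held as an :class:`OntologyGraph` — a map from
term id to :class:`OntologyTerm` plus an alt-id resolution table.  Edges point
child → parent (``is_a``, ``part_of`` and, from 2008 on, ``regulates``).
Obsolete terms are retained and flagged, but carry no edges, so that a term
that disappears from the live graph in one snapshot can still be diagnosed
rather than silently vanishing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

ISA = "is_a"
PART_OF = "part_of"
REGULATES = "regulates"

#: The classical true-path relation set: is_a + part_of.
DEFAULT_RELATIONS = frozenset({ISA, PART_OF})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(ValueError):
    """Structural problem in an ontology file or query."""


class UnknownTermError(OntologyError):
    """Identifier absent from both canonical ids and alt_ids."""


class ObsoleteTermError(OntologyError):
    """Identifier resolves to an obsolete term."""

    def __init__(self, term_id: str):
        super().__init__(f"term {term_id} is obsolete")
        self.term_id = term_id


class CyclicOntologyError(OntologyError):
    """The parent-edge set contains a cycle."""


@dataclass
class OntologyTerm:
    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    isa_parents: frozenset[str] = frozenset()
    partof_parents: frozenset[str] = frozenset()
    regulates_parents: frozenset[str] = frozenset()
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False

    def parents(self, relations: Iterable[str]) -> frozenset[str]:
        """Union of parent ids over the selected relation types."""
        out: set[str] = set()
        for rel in relations:
            if rel == ISA:
                out |= self.isa_parents
            elif rel == PART_OF:
                out |= self.partof_parents
            elif rel == REGULATES:
                out |= self.regulates_parents
            else:
                raise ValueError(f"unknown relation type {rel!r}")
        return frozenset(out)


@dataclass
class OntologyGraph:
    """A validated ontology snapshot.

    ``terms`` maps canonical id → term.  ``alt_ids`` (built at construction)
    maps each alternate id to its unique canonical id.
    """

    terms: dict[str, OntologyTerm]
    snapshot_label: str = ""
    alt_ids: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.alt_ids:
            alt: dict[str, str] = {}
            for term in self.terms.values():
                for a in term.alt_ids:
                    if a in self.terms:
                        raise OntologyError(
                            f"alt_id {a} collides with a canonical term id"
                        )
                    if a in alt and alt[a] != term.term_id:
                        raise OntologyError(
                            f"alt_id {a} maps to both {alt[a]} and {term.term_id}"
                        )
                    alt[a] = term.term_id
            self.alt_ids = alt

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def resolve_term(self, query_id: str) -> str:
        """Map a possibly-alternate id to its canonical id.

        Raises :class:`UnknownTermError` for ids absent from the snapshot and
        :class:`ObsoleteTermError` when the canonical term is obsolete.
        """
        if query_id in self.terms:
            canonical = query_id
        elif query_id in self.alt_ids:
            canonical = self.alt_ids[query_id]
        else:
            raise UnknownTermError(f"unknown term {query_id}")
        if self.terms[canonical].obsolete:
            raise ObsoleteTermError(canonical)
        return canonical

    def ancestors(
        self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """Reflexive transitive closure over the selected relation types.

        The term itself is always a member.  Unknown or obsolete ids raise.
        """
        canonical = self.resolve_term(term_id)
        relations = frozenset(relations)
        seen: set[str] = set()
        stack = [canonical]
        while stack:
            tid = stack.pop()
            if tid in seen:
                continue
            seen.add(tid)
            stack.extend(self.terms[tid].parents(relations) - seen)
        return frozenset(seen)

    def to_obo(self, stream: TextIO) -> None:
        """Serialize as OBO 1.2 text, terms in sorted id order (deterministic)."""
        stream.write("format-version: 1.2\n")
        if self.snapshot_label:
            stream.write(f"data-version: {self.snapshot_label}\n")
        for tid in sorted(self.terms):
            term = self.terms[tid]
            stream.write("\n[Term]\n")
            stream.write(f"id: {term.term_id}\n")
            stream.write(f"name: {term.name}\n")
            stream.write(f"namespace: {term.namespace}\n")
            for a in sorted(term.alt_ids):
                stream.write(f"alt_id: {a}\n")
            if term.obsolete:
                stream.write("is_obsolete: true\n")
                continue
            for p in sorted(term.isa_parents):
                stream.write(f"is_a: {p}\n")
            for p in sorted(term.partof_parents):
                stream.write(f"relationship: part_of {p}\n")
            for p in sorted(term.regulates_parents):
                stream.write(f"relationship: regulates {p}\n")


def _strip_comment(line: str) -> str:
    # "!" starts a comment to end-of-line in OBO tag lines
    idx = line.find("!")
    return line if idx < 0 else line[:idx]


def parse_obo(stream: Iterable[str], snapshot_label: str = "") -> OntologyGraph:
    """Parse an OBO 1.2 flat file into a validated :class:`OntologyGraph`.

    Recognized tags: id, name, namespace, is_a, relationship (part_of and
    regulates), alt_id, is_obsolete.  Non-[Term] stanzas are ignored.
    Obsolete terms are kept in the map but contribute no edges.

    Raises :class:`OntologyError` on a missing id (with line number), a
    dangling or cross-namespace parent reference, an alt-id collision, or
    :class:`CyclicOntologyError` naming one cycle.
    """
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    stanza_line = 0

    def close() -> None:
        nonlocal current
        if in_term and current is not None:
            if "id" not in current:
                raise OntologyError(
                    f"[Term] stanza starting at line {stanza_line} has no id"
                )
            stanzas.append(current)
        current = None

    for lineno, raw in enumerate(stream, start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            close()
            in_term = line == "[Term]"
            if in_term:
                current = {
                    "line": lineno,
                    "isa": set(),
                    "partof": set(),
                    "regulates": set(),
                    "alt": set(),
                }
                stanza_line = lineno
            continue
        if not in_term or current is None:
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "is_a":
            current["isa"].add(value)
        elif tag == "alt_id":
            current["alt"].add(value)
        elif tag == "is_obsolete":
            current["obsolete"] = value.lower() == "true"
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2:
                rel, target = parts[0], parts[1]
                if rel == PART_OF:
                    current["partof"].add(target)
                elif rel == REGULATES:
                    current["regulates"].add(target)
                # other relationship types are outside the propagation model
    close()

    terms: dict[str, OntologyTerm] = {}
    for st in stanzas:
        tid = st["id"]
        if tid in terms:
            raise OntologyError(f"duplicate term id {tid} (line {st['line']})")
        obsolete = st.get("obsolete", False)
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=st.get("name", ""),
            namespace=st.get("namespace", "biological_process"),
            isa_parents=frozenset() if obsolete else frozenset(st["isa"]),
            partof_parents=frozenset() if obsolete else frozenset(st["partof"]),
            regulates_parents=frozenset() if obsolete else frozenset(st["regulates"]),
            alt_ids=frozenset(st["alt"]),
            obsolete=obsolete,
        )

    _validate_edges(terms)
    return OntologyGraph(terms=terms, snapshot_label=snapshot_label)


def _validate_edges(terms: dict[str, OntologyTerm]) -> None:
    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for term in terms.values():
        for parent in term.parents((ISA, PART_OF, REGULATES)):
            if parent not in terms:
                raise OntologyError(
                    f"term {term.term_id} references dangling parent {parent}"
                )
            if terms[parent].obsolete:
                raise OntologyError(
                    f"term {term.term_id} has obsolete parent {parent}"
                )
            if terms[parent].namespace != term.namespace:
                raise OntologyError(
                    f"cross-namespace edge {term.term_id} -> {parent} "
                    f"({term.namespace} -> {terms[parent].namespace})"
                )
            dag.add_edge(term.term_id, parent)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
    raise CyclicOntologyError(f"ontology contains a cycle: {path}")


def ancestors(
    graph: OntologyGraph, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id, relations)


def resolve_term(graph: OntologyGraph, query_id: str) -> str:
    """Functional alias for :meth:`OntologyGraph.resolve_term`."""
    return graph.resolve_term(query_id)
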