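"""Temporal evaluation: snapshot series, trajectories, and decoupling.

A *snapshot* pairs one ontology version with one annotation version — the
knowledgebase as a user would have seen it at one time point.  Running the
same fixed study gene list through a series of snapshots yields a
:class:`TrajectoryTable`: for each term of interest, its enrichment p-value,
rank and gene-set size at every snapshot, with explicit reasons whenever a
cell is absent (term filtered by size, missing from that snapshot, p-value
of 1, or too few genes).

The *decoupling* experiment attributes trajectory changes to one component:
freezing the annotations at a reference snapshot while the structure varies
isolates structural effects, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .annotations import AnnotationSet, read_gaf
from .enrichment import EnrichmentResult, enrich, term_report
from .genesets import GeneSetCollection, build_gene_sets, filter_by_size
from .ontology import (
    DEFAULT_RELATIONS,
    ObsoleteTermError,
    OntologyGraph,
    UnknownTermError,
    parse_obo,
)

ABSENCE_REASONS = (
    "p_equals_1",
    "fewer_than_min_genes",
    "filtered_by_size",
    "absent_from_snapshot",
)


@dataclass
class Snapshot:
    label: str
    graph: OntologyGraph
    annos: AnnotationSet


@dataclass
class AnalysisConfig:
    """Settings shared by every snapshot of a series run."""

    relations: frozenset[str] = DEFAULT_RELATIONS
    namespace: str = "biological_process"
    min_term_size: int = 3
    max_term_size: int = 500
    restrict_universe: frozenset[str] | None = None
    two_sided: bool = False


@dataclass(frozen=True)
class TrajectoryCell:
    status: str  # "tested" or one of ABSENCE_REASONS
    p_raw: float | None = None
    p_adjusted: float | None = None
    rank: int | None = None
    set_size: int | None = None

    @property
    def tested(self) -> bool:
        return self.status == "tested"


@dataclass
class TrajectoryTable:
    snapshot_labels: list[str]
    term_ids: list[str]
    cells: dict[tuple[str, str], TrajectoryCell]  # (term_id, snapshot_label)
    warnings: list[str] = field(default_factory=list)

    def cell(self, term_id: str, snapshot_label: str) -> TrajectoryCell:
        return self.cells[(term_id, snapshot_label)]

    def trajectory(self, term_id: str) -> list[TrajectoryCell]:
        return [self.cells[(term_id, s)] for s in self.snapshot_labels]

    def to_tsv(self, stream: TextIO) -> None:
        stream.write("term_id\tsnapshot\tstatus\tp_raw\tp_adjusted\trank\tset_size\n")
        for term_id in self.term_ids:
            for label in self.snapshot_labels:
                c = self.cells[(term_id, label)]
                stream.write(
                    "\t".join(
                        [
                            term_id,
                            label,
                            c.status,
                            "" if c.p_raw is None else repr(c.p_raw),
                            "" if c.p_adjusted is None else repr(c.p_adjusted),
                            "" if c.rank is None else str(c.rank),
                            "" if c.set_size is None else str(c.set_size),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, stream: Iterable[str]) -> "TrajectoryTable":
        lines = iter(stream)
        header = next(lines).rstrip("\n").split("\t")
        expected = ["term_id", "snapshot", "status", "p_raw", "p_adjusted",
                    "rank", "set_size"]
        if header != expected:
            raise ValueError(f"unexpected trajectory header {header}")
        labels: list[str] = []
        terms: list[str] = []
        cells: dict[tuple[str, str], TrajectoryCell] = {}
        for raw in lines:
            if not raw.strip():
                continue
            term_id, label, status, p_raw, p_adj, rank, size = raw.rstrip(
                "\n"
            ).split("\t")
            if label not in labels:
                labels.append(label)
            if term_id not in terms:
                terms.append(term_id)
            cells[(term_id, label)] = TrajectoryCell(
                status=status,
                p_raw=float(p_raw) if p_raw else None,
                p_adjusted=float(p_adj) if p_adj else None,
                rank=int(rank) if rank else None,
                set_size=int(size) if size else None,
            )
        return cls(snapshot_labels=labels, term_ids=terms, cells=cells)


def snapshot_gene_sets(
    snapshot: Snapshot, config: AnalysisConfig
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Build (unfiltered, size-filtered) collections for one snapshot."""
    unfiltered = build_gene_sets(
        snapshot.graph, snapshot.annos, relations=config.relations,
        namespace=config.namespace,
    )
    filtered = filter_by_size(
        unfiltered,
        min_size=config.min_term_size,
        max_size=config.max_term_size,
        restrict_to=config.restrict_universe,
    )
    return unfiltered, filtered


def run_series(
    snapshots: Sequence[Snapshot],
    study_genes: Iterable[str],
    terms_of_interest: Sequence[str],
    config: AnalysisConfig | None = None,
) -> TrajectoryTable:
    """Enrich a fixed study gene list against every snapshot of a series.

    The study list is computed once, upstream, and reused: the series
    evaluates the knowledgebase, not the differential-expression call.
    Requested term ids are resolved per snapshot (alt-id aware), so a term
    keeps one row even as its id drifts across versions; a term that cannot
    be resolved in a snapshot becomes an ``absent_from_snapshot`` cell.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    labels = [s.label for s in snapshots]
    if len(set(labels)) != len(labels):
        raise ValueError("snapshot labels must be unique within a series")
    config = config or AnalysisConfig()
    study = frozenset(study_genes)
    terms_of_interest = list(terms_of_interest)

    cells: dict[tuple[str, str], TrajectoryCell] = {}
    warnings: list[str] = []
    for snap in snapshots:
        unfiltered, filtered = snapshot_gene_sets(snap, config)

        resolved: dict[str, str | None] = {}
        for t in terms_of_interest:
            try:
                resolved[t] = snap.graph.resolve_term(t)
            except (UnknownTermError, ObsoleteTermError):
                resolved[t] = None

        if not filtered.sets or not filtered.universe or not (
            study & filtered.universe
        ):
            warnings.append(
                f"snapshot {snap.label}: no overlap between study list and "
                f"gene sets; recording an all-absent column"
            )
            for t in terms_of_interest:
                rt = resolved[t]
                if rt is None:
                    status = "absent_from_snapshot"
                elif rt in filtered.sets:
                    status = "p_equals_1"
                elif rt in unfiltered.sets:
                    status = "filtered_by_size"
                else:
                    status = "absent_from_snapshot"
                cells[(t, snap.label)] = TrajectoryCell(status=status)
            continue

        results = enrich(study, filtered, two_sided=config.two_sided)
        requested = [resolved[t] for t in terms_of_interest]
        rows = term_report(
            results,
            [r if r is not None else "<unresolved>" for r in requested],
            unfiltered_terms=unfiltered.sets.keys(),
        )
        for t, rt, row in zip(terms_of_interest, requested, rows):
            if rt is None:
                cells[(t, snap.label)] = TrajectoryCell(status="absent_from_snapshot")
            elif row.status == "tested":
                cells[(t, snap.label)] = TrajectoryCell(
                    status="tested",
                    p_raw=row.p_raw,
                    p_adjusted=row.p_adjusted,
                    rank=row.rank,
                    set_size=len(filtered.sets[rt]),
                )
            else:
                cells[(t, snap.label)] = TrajectoryCell(status=row.status)

    return TrajectoryTable(
        snapshot_labels=labels,
        term_ids=terms_of_interest,
        cells=cells,
        warnings=warnings,
    )


def decouple(
    snapshots: Sequence[Snapshot], mode: str, reference_label: str
) -> list[Snapshot]:
    """Freeze one knowledgebase component at a reference snapshot.

    ``fix_annotations`` keeps each snapshot's ontology structure but swaps in
    the reference annotations (isolates structural change); ``fix_structure``
    keeps each snapshot's annotations under the reference structure (isolates
    annotation change).  The returned series feeds :func:`run_series`
    unchanged.
    """
    mode = mode.replace("-", "_")
    if mode not in ("fix_annotations", "fix_structure"):
        raise ValueError(f"mode must be fix_annotations or fix_structure, got {mode!r}")
    by_label = {s.label: s for s in snapshots}
    if reference_label not in by_label:
        raise ValueError(f"unknown reference snapshot {reference_label!r}")
    ref = by_label[reference_label]
    if mode == "fix_annotations":
        return [Snapshot(s.label, s.graph, ref.annos) for s in snapshots]
    return [Snapshot(s.label, ref.graph, s.annos) for s in snapshots]


def top_terms(results: Sequence[EnrichmentResult], k: int = 10) -> list[str]:
    """Ids of the k most significant terms (ascending p, term-id tie-break)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(results, key=lambda r: (r.p_raw, r.term_id))
    return [r.term_id for r in ordered[:k]]


def track_terms(table: TrajectoryTable, min_genes: int = 3) -> TrajectoryTable:
    """Apply the trajectory omission rule.

    Tested cells with too few genes become ``fewer_than_min_genes`` absences;
    tested cells with p = 1 become ``p_equals_1`` absences.  Terms left with
    no tested cell at any snapshot are dropped from the table.
    """
    cells: dict[tuple[str, str], TrajectoryCell] = {}
    for key, c in table.cells.items():
        if c.tested and c.set_size is not None and c.set_size < min_genes:
            cells[key] = TrajectoryCell(status="fewer_than_min_genes")
        elif c.tested and c.p_raw is not None and c.p_raw == 1.0:
            cells[key] = TrajectoryCell(status="p_equals_1")
        else:
            cells[key] = c
    kept_terms = [
        t
        for t in table.term_ids
        if any(cells[(t, s)].tested for s in table.snapshot_labels)
    ]
    kept_cells = {
        (t, s): cells[(t, s)]
        for t in kept_terms
        for s in table.snapshot_labels
    }
    return TrajectoryTable(
        snapshot_labels=list(table.snapshot_labels),
        term_ids=kept_terms,
        cells=kept_cells,
        warnings=list(table.warnings),
    )


def read_manifest(path: str | Path) -> list[Snapshot]:
    """Load a snapshot series from a TSV manifest (label, obo_path, gaf_path).

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    snapshots: list[Snapshot] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["label", "obo_path", "gaf_path"]:
            raise ValueError(f"manifest must start label/obo_path/gaf_path, got {header}")
        for raw in fh:
            if not raw.strip():
                continue
            label, obo_path, gaf_path = raw.rstrip("\n").split("\t")[:3]
            obo = base / obo_path
            with open(obo, encoding="utf-8") as obo_fh:
                graph = parse_obo(obo_fh, snapshot_label=label)
            annos = read_gaf(base / gaf_path, snapshot_label=label)
            snapshots.append(Snapshot(label=label, graph=graph, annos=annos))
    return snapshots
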