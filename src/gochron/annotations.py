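"""GAF annotation parsing and filtering.

One :class:`AnnotationSet` is one snapshot of a gene-association corpus.
The date column (GAF column 14) is the authority for reconstructing historical
snapshots from a later file: filtering to ``date <= cutoff`` rebuilds the
corpus as it stood at that cutoff, and cutoffs that grow monotonically yield
nested, monotonically growing annotation sets.
"""

from __future__ import annotations

import datetime as _dt
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .ontology import GO_ID_PATTERN

ASPECTS = ("P", "F", "C")

#: aspect letter (GAF column 9) → ontology namespace
ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
NAMESPACE_TO_ASPECT = {v: k for k, v in ASPECT_TO_NAMESPACE.items()}


class GafFormatError(ValueError):
    pass


def _as_date(value) -> _dt.date:
    """Accept a date, an int/str YYYYMMDD, or an ISO string."""
    if isinstance(value, _dt.date):
        return value
    s = str(value)
    if "-" in s:
        return _dt.date.fromisoformat(s)
    if len(s) != 8 or not s.isdigit():
        raise GafFormatError(f"bad date {value!r} (expected YYYYMMDD)")
    return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))


@dataclass(frozen=True)
class Annotation:
    gene_id: str
    gene_symbol: str
    term_id: str
    qualifier_negated: bool
    evidence_code: str
    aspect: str
    date: _dt.date

    @property
    def date_yyyymmdd(self) -> str:
        return self.date.strftime("%Y%m%d")


@dataclass
class ParseReport:
    """Per-line problems collected during non-strict GAF parsing."""

    errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.errors)


@dataclass
class AnnotationSet:
    records: list[Annotation]
    snapshot_label: str = ""
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_gene(self) -> dict[str, list[Annotation]]:
        out: dict[str, list[Annotation]] = {}
        for rec in self.records:
            out.setdefault(rec.gene_id, []).append(rec)
        return out

    def by_term(self) -> dict[str, list[Annotation]]:
        out: dict[str, list[Annotation]] = {}
        for rec in self.records:
            out.setdefault(rec.term_id, []).append(rec)
        return out

    def gene_term_pairs(self) -> set[tuple[str, str]]:
        """Distinct (gene, term) pairs; duplicates count once downstream."""
        return {(r.gene_id, r.term_id) for r in self.records}


def parse_gaf(
    stream: Iterable[str], snapshot_label: str = "", strict: bool = False
) -> AnnotationSet:
    """Parse GAF 1.0/2.x tab-delimited text.

    Columns consumed (1-based): 2 gene id, 3 symbol, 4 qualifier, 5 GO id,
    7 evidence code, 9 aspect, 14 date.  ``qualifier_negated`` is true iff
    the qualifier field contains the pipe-separated token ``NOT``.  Lines
    with fewer than 15 columns, a malformed GO id or a malformed date are
    collected into the parse report (or raised when ``strict``).
    """
    records: list[Annotation] = []
    report = ParseReport()

    def problem(lineno: int, msg: str) -> None:
        if strict:
            raise GafFormatError(f"line {lineno}: {msg}")
        report.errors.append((lineno, msg))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            problem(lineno, f"expected >= 15 columns, got {len(cols)}")
            continue
        term_id = cols[4]
        if not GO_ID_PATTERN.match(term_id):
            problem(lineno, f"malformed GO id {term_id!r}")
            continue
        try:
            date = _as_date(cols[13])
        except (GafFormatError, ValueError):
            problem(lineno, f"malformed date {cols[13]!r}")
            continue
        aspect = cols[8]
        if aspect not in ASPECTS:
            problem(lineno, f"unknown aspect {aspect!r}")
            continue
        records.append(
            Annotation(
                gene_id=cols[1],
                gene_symbol=cols[2],
                term_id=term_id,
                qualifier_negated="NOT" in cols[3].split("|"),
                evidence_code=cols[6],
                aspect=aspect,
                date=date,
            )
        )
    return AnnotationSet(records=records, snapshot_label=snapshot_label,
                         parse_report=report)


def read_gaf(path: str | Path, snapshot_label: str = "",
             strict: bool = False) -> AnnotationSet:
    """Read a GAF file; ``.gz`` paths are decompressed transparently."""
    path = Path(path)
    label = snapshot_label or path.stem
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return parse_gaf(fh, snapshot_label=label, strict=strict)
    with open(path, encoding="utf-8") as fh:
        return parse_gaf(fh, snapshot_label=label, strict=strict)


def write_gaf(annos: AnnotationSet, stream: TextIO) -> None:
    """Write records back out as 17-column GAF 2.2-style lines."""
    stream.write("!gaf-version: 2.2\n")
    for r in annos.records:
        qualifier = "NOT|involved_in" if r.qualifier_negated else "involved_in"
        cols = [
            "SYNTH", r.gene_id, r.gene_symbol, qualifier, r.term_id, "REF:0",
            r.evidence_code, "", r.aspect, "", "", "protein", "taxon:9606",
            r.date_yyyymmdd, "SYNTH", "", "",
        ]
        stream.write("\t".join(cols) + "\n")


def gaf_to_string(annos: AnnotationSet) -> str:
    buf = io.StringIO()
    write_gaf(annos, buf)
    return buf.getvalue()


def filter_annotations(
    annos: AnnotationSet,
    max_date=None,
    evidence_exclude: Iterable[str] | None = None,
    drop_negated: bool = False,
    aspect: str | None = None,
) -> AnnotationSet:
    """Conjunctive record filter; each criterion applies only when given.

    ``max_date`` keeps records dated at or before the cutoff (ties included),
    which is the cumulative-reconstruction rule.  The result's snapshot label
    records the cutoff.
    """
    cutoff = _as_date(max_date) if max_date is not None else None
    excluded = frozenset(evidence_exclude) if evidence_exclude else frozenset()
    if aspect is not None and aspect not in ASPECTS:
        raise ValueError(f"aspect must be one of {ASPECTS}, got {aspect!r}")

    kept = [
        r
        for r in annos.records
        if (cutoff is None or r.date <= cutoff)
        and r.evidence_code not in excluded
        and not (drop_negated and r.qualifier_negated)
        and (aspect is None or r.aspect == aspect)
    ]
    label = annos.snapshot_label
    if cutoff is not None:
        label = f"{label}<= {cutoff.isoformat()}" if label else f"<={cutoff.isoformat()}"
    return AnnotationSet(records=kept, snapshot_label=label)
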