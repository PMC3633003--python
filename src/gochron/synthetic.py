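"""Synthetic knowledgebase and expression generator.

Everything the evaluation pipeline consumes can be generated here without
external downloads: a rooted ontology DAG, a dated annotation corpus that
grows across snapshots (emulating cumulative curation), and a two-group
expression matrix in which the genes of one *planted* term are shifted on
the natural-log scale.  Generation is deterministic for a fixed seed, down
to byte-identical OBO/GAF serializations.

The planted term plays the role of a known-relevant biological process: a
pipeline that works should call its genes differentially expressed and rank
the term first in the enrichment results, and its p-value should fall as the
annotation corpus grows toward completeness.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .annotations import Annotation, AnnotationSet, write_gaf
from .enrichment import EnrichmentResult, enrich
from .evaluation import AnalysisConfig, Snapshot, TrajectoryTable, run_series
from .expression import (
    ExpressionMatrix,
    differential_expression,
    filter_probes,
    log_transform,
)
from .genesets import GeneSetCollection, build_gene_sets, filter_by_size
from .ontology import DEFAULT_RELATIONS, OntologyGraph, OntologyTerm

_EVIDENCE_CODES = ("IEA", "IDA", "TAS")
_EVIDENCE_PROPS = (0.5, 0.3, 0.2)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a small but realistic evaluation: a 200-term ontology,
    500 annotated genes, a planted process whose genes are over-expressed by
    δ = 2 on the ln scale against noise σ = 0.5, measured in 10 samples per
    group, with the corpus growing through five snapshots to completeness.
    """

    n_terms: int = 200
    max_depth: int = 5
    branching: float = 3.0
    n_genes: int = 500
    annotations_per_gene: float = 2.0
    planted_term: str | None = None
    effect_size: float = 2.0
    noise_sd: float = 0.5
    samples_per_group: int = 10
    growth_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        fr = self.growth_fractions
        if not fr or any(f <= 0 for f in fr) or fr[-1] > 1:
            raise ValueError("growth_fractions must lie in (0, 1]")
        if any(a > b for a, b in zip(fr, fr[1:])):
            raise ValueError("growth_fractions must be non-decreasing")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per pipeline stage, all derived from seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def simulate_ontology(config: SimulationConfig) -> OntologyGraph:
    """A rooted DAG: levels sized ~ branching**depth, each non-root term
    taking 1–2 parents from strictly shallower levels (acyclic by
    construction).  Roughly one edge in five is part_of, the rest is_a."""
    rng = config.rng(1)
    n = config.n_terms
    depth = max(1, config.max_depth)

    # allocate terms to levels: root alone at level 0, the rest by weight
    weights = np.array([config.branching**lvl for lvl in range(1, depth + 1)])
    counts = np.floor(weights / weights.sum() * (n - 1)).astype(int)
    for i in range(int(n - 1 - counts.sum())):
        counts[i % len(counts)] += 1

    levels = [0] + [lvl for lvl, c in enumerate(counts, start=1) for _ in range(c)]
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    terms: dict[str, OntologyTerm] = {}
    shallower: list[list[int]] = []
    for idx, (tid, lvl) in enumerate(zip(ids, levels)):
        if lvl == 0:
            terms[tid] = OntologyTerm(term_id=tid, name=f"synthetic process {idx:05d}")
            shallower.append(idx)
            continue
        pool = [i for i in range(idx) if levels[i] < lvl]
        n_parents = min(int(rng.integers(1, 3)), len(pool))
        parents = rng.choice(len(pool), size=n_parents, replace=False)
        isa, partof = set(), set()
        for p in parents:
            target = ids[pool[int(p)]]
            (partof if rng.random() < 0.2 else isa).add(target)
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=f"synthetic process {idx:05d}",
            isa_parents=frozenset(isa),
            partof_parents=frozenset(partof),
        )
    return OntologyGraph(terms=terms, snapshot_label=f"synthetic-seed{config.seed}")


def simulate_annotations(
    graph: OntologyGraph, config: SimulationConfig
) -> AnnotationSet:
    """Direct annotations: per gene a Poisson number of uniformly chosen
    terms (minimum 1), dated uniformly over a synthetic decade, evidence
    codes drawn IEA/IDA/TAS at fixed proportions."""
    if not graph.terms:
        raise ValueError("graph has no terms")
    rng = config.rng(2)
    term_ids = sorted(t for t, term in graph.terms.items() if not term.obsolete)
    start = _dt.date(2003, 1, 1)
    span_days = (_dt.date(2012, 12, 31) - start).days

    records: list[Annotation] = []
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:05d}"
        count = max(1, int(rng.poisson(config.annotations_per_gene)))
        count = min(count, len(term_ids))
        chosen = rng.choice(len(term_ids), size=count, replace=False)
        for c in sorted(int(i) for i in chosen):
            records.append(
                Annotation(
                    gene_id=gene,
                    gene_symbol=gene,
                    term_id=term_ids[c],
                    qualifier_negated=False,
                    evidence_code=str(
                        rng.choice(_EVIDENCE_CODES, p=_EVIDENCE_PROPS)
                    ),
                    aspect="P",
                    date=start + _dt.timedelta(days=int(rng.integers(0, span_days + 1))),
                )
            )
    return AnnotationSet(records=records, snapshot_label=f"synthetic-seed{config.seed}")


def choose_planted_term(
    collection: GeneSetCollection,
    graph: OntologyGraph,
    min_size: int = 15,
    max_size: int = 80,
) -> str:
    """Pick a term to plant a signal in: mid-sized, and strictly smaller than
    every proper ancestor so the signal is term-specific (an ancestor with an
    identical gene set would tie on p-value).  Deterministic."""
    candidates = []
    for term_id, genes in collection.sets.items():
        if not (min_size <= len(genes) <= max_size):
            continue
        proper = graph.ancestors(term_id, DEFAULT_RELATIONS) - {term_id}
        if all(len(collection.sets[a]) > len(genes) for a in proper):
            candidates.append(term_id)
    if not candidates:
        candidates = [
            t for t, g in collection.sets.items() if min_size <= len(g) <= max_size
        ]
    if not candidates:
        raise ValueError(
            f"no term has a propagated set of size {min_size}–{max_size}; "
            "increase n_genes or annotations_per_gene"
        )
    target = (min_size + max_size) / 2
    return min(candidates, key=lambda t: (abs(len(collection.sets[t]) - target), t))


def simulate_expression(
    annos: AnnotationSet,
    collection: GeneSetCollection,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """One probe per annotated gene, values on the natural intensity scale.

    Control samples: exp(baseline_g + N(0, σ)); case samples add the ln-scale
    shift δ for genes in the planted term's propagated set.  Values are
    positive by construction, so the probe-filter → ln → t-test pipeline
    applies verbatim.
    """
    planted = config.planted_term
    if planted is None or planted not in collection.sets:
        raise ValueError(f"planted term {planted!r} not present in the collection")
    planted_genes = collection.sets[planted]
    rng = config.rng(3)
    genes = sorted({r.gene_id for r in annos.records})
    n = config.samples_per_group
    case_ids = [f"case{i + 1:03d}" for i in range(n)]
    ctrl_ids = [f"ctrl{i + 1:03d}" for i in range(n)]

    baseline = rng.normal(6.0, 1.0, size=len(genes))
    shift = np.array([config.effect_size if g in planted_genes else 0.0 for g in genes])
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n))
    ln_values = baseline[:, None] + noise
    ln_values[:, :n] += shift[:, None]  # first n columns are cases

    data = pd.DataFrame(
        np.exp(ln_values),
        index=[f"PR_{g}" for g in genes],
        columns=case_ids + ctrl_ids,
    )
    labels = {s: "case" for s in case_ids} | {s: "control" for s in ctrl_ids}
    probe_map = {f"PR_{g}": g for g in genes}
    return ExpressionMatrix(data=data, group_labels=labels, probe_gene_map=probe_map)


def simulate_growth(
    full: AnnotationSet, config: SimulationConfig
) -> list[AnnotationSet]:
    """Nested annotation snapshots: for each growth fraction f, a subset of
    exactly round(f·N) records, each snapshot contained in the next, in a
    seed-fixed selection order.  Labels t1, t2, ..."""
    rng = config.rng(4)
    n = len(full.records)
    order = rng.permutation(n)
    snapshots = []
    for i, f in enumerate(config.growth_fractions, start=1):
        size = round(f * n)
        chosen = sorted(int(j) for j in order[:size])
        snapshots.append(
            AnnotationSet(
                records=[full.records[j] for j in chosen],
                snapshot_label=f"t{i}",
            )
        )
    return snapshots


@dataclass
class SyntheticStudy:
    """A complete generated study: knowledgebase, expression, planted truth."""

    config: SimulationConfig  # with planted_term filled in
    graph: OntologyGraph
    annotations: AnnotationSet
    collection: GeneSetCollection  # unfiltered, propagated, BP
    matrix: ExpressionMatrix

    @property
    def planted_term(self) -> str:
        return self.config.planted_term

    @property
    def platform_genes(self) -> frozenset[str]:
        return frozenset(self.matrix.probe_gene_map.values())


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate ontology, annotations, propagated gene sets and expression.

    When ``config.planted_term`` is unset a suitable term is chosen
    automatically (see :func:`choose_planted_term`).
    """
    graph = simulate_ontology(config)
    annos = simulate_annotations(graph, config)
    collection = build_gene_sets(graph, annos, namespace="biological_process")
    if config.planted_term is None:
        config = replace(config, planted_term=choose_planted_term(collection, graph))
    matrix = simulate_expression(annos, collection, config)
    return SyntheticStudy(
        config=config, graph=graph, annotations=annos,
        collection=collection, matrix=matrix,
    )


@dataclass
class RecoveryResult:
    """Outcome of one end-to-end planted-term recovery run."""

    study: SyntheticStudy
    de_genes: frozenset[str]
    results: list[EnrichmentResult]
    planted_rank: int | None
    planted_p_raw: float | None


def derive_study_genes(study: SyntheticStudy, alpha: float = 0.05) -> frozenset[str]:
    """Run the expression pipeline (filter → ln → t-test → Bonferroni)."""
    m = log_transform(filter_probes(study.matrix))
    return differential_expression(m, alpha=alpha).de_genes


def run_recovery_experiment(
    config: SimulationConfig, analysis: AnalysisConfig | None = None
) -> RecoveryResult:
    """Full pipeline on one synthetic study: does enrichment rank the planted
    term first?"""
    study = simulate_study(config)
    de_genes = derive_study_genes(study)
    analysis = analysis or AnalysisConfig(restrict_universe=study.platform_genes)
    filtered = filter_by_size(
        study.collection,
        min_size=analysis.min_term_size,
        max_size=analysis.max_term_size,
        restrict_to=analysis.restrict_universe,
    )
    results = enrich(de_genes, filtered)
    planted = study.planted_term
    hit = next((r for r in results if r.term_id == planted), None)
    return RecoveryResult(
        study=study,
        de_genes=de_genes,
        results=results,
        planted_rank=hit.rank if hit else None,
        planted_p_raw=hit.p_raw if hit else None,
    )


def run_growth_experiment(
    config: SimulationConfig,
) -> tuple[TrajectoryTable, SyntheticStudy]:
    """Temporal analogue: freeze the structure, grow the annotations through
    the configured fractions, and track the planted term's trajectory with a
    study list derived once from the full corpus."""
    study = simulate_study(config)
    de_genes = derive_study_genes(study)
    snapshots = [
        Snapshot(label=a.snapshot_label, graph=study.graph, annos=a)
        for a in simulate_growth(study.annotations, config)
    ]
    analysis = AnalysisConfig(restrict_universe=study.platform_genes)
    table = run_series(snapshots, de_genes, [study.planted_term], analysis)
    return table, study


def write_corpus(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete corpus to disk: ontology OBO, one GAF per growth
    snapshot, expression TSV, group labels, probe→gene map and a manifest
    consumable by the series/decouple commands.  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)

    paths: dict[str, Path] = {}
    obo = outdir / "ontology.obo"
    with open(obo, "w", encoding="utf-8") as fh:
        study.graph.to_obo(fh)
    paths["obo"] = obo

    manifest_rows = []
    for snap in simulate_growth(study.annotations, study.config):
        gaf = outdir / f"{snap.snapshot_label}.gaf"
        with open(gaf, "w", encoding="utf-8") as fh:
            write_gaf(snap, fh)
        paths[snap.snapshot_label] = gaf
        manifest_rows.append((snap.snapshot_label, obo.name, gaf.name))

    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("label\tobo_path\tgaf_path\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    paths["manifest"] = manifest

    expr = outdir / "expression.tsv"
    study.matrix.data.to_csv(expr, sep="\t", index_label="probe_id")
    paths["expression"] = expr

    groups = outdir / "groups.tsv"
    with open(groups, "w", encoding="utf-8") as fh:
        for sample in study.matrix.sample_ids:
            fh.write(f"{sample}\t{study.matrix.group_labels[sample]}\n")
    paths["groups"] = groups

    probe_map = outdir / "probe_map.tsv"
    with open(probe_map, "w", encoding="utf-8") as fh:
        for probe, gene in study.matrix.probe_gene_map.items():
            fh.write(f"{probe}\t{gene}\n")
    paths["probe_map"] = probe_map

    planted = outdir / "planted_term.txt"
    planted.write_text(study.planted_term + "\n", encoding="utf-8")
    paths["planted_term"] = planted
    return paths


def ontology_to_string(graph: OntologyGraph) -> str:
    buf = io.StringIO()
    graph.to_obo(buf)
    return buf.getvalue()
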