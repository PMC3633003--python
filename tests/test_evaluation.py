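"""Snapshot series, trajectories, decoupling, top-term tracking."""

import io

import pytest

from gochron.enrichment import enrich, term_report
from gochron.evaluation import (
    AnalysisConfig,
    Snapshot,
    TrajectoryCell,
    TrajectoryTable,
    decouple,
    run_series,
    top_terms,
    track_terms,
)
from gochron.genesets import filter_by_size
from gochron.synthetic import SimulationConfig, simulate_growth, simulate_study


@pytest.fixture(scope="module")
def small_study():
    return simulate_study(SimulationConfig(n_terms=40, n_genes=80, seed=11))


def _snapshot(study, label="t1", annos=None):
    return Snapshot(label=label, graph=study.graph,
                    annos=annos or study.annotations)


def _study_genes(study):
    # half of the planted set plus a few outsiders: a realistic study list
    planted = sorted(study.collection.sets[study.planted_term])
    others = sorted(study.collection.universe - set(planted))
    return set(planted[: max(3, len(planted) // 2)]) | set(others[:5])


class TestRunSeries:
    def test_single_snapshot_equals_standalone_enrichment_path(self, small_study):
        study = small_study
        genes = _study_genes(study)
        config = AnalysisConfig()
        terms = [study.planted_term, "GO:7777777"]

        table = run_series([_snapshot(study)], genes, terms, config)

        filtered = filter_by_size(study.collection, 3, 500)
        results = enrich(genes, filtered)
        rows = term_report(results, terms, unfiltered_terms=study.collection.sets)
        for term, row in zip(terms, rows):
            cell = table.cell(term, "t1")
            assert cell.status == row.status
            assert cell.p_raw == row.p_raw
            assert cell.p_adjusted == row.p_adjusted
            assert cell.rank == row.rank

    def test_identical_snapshots_give_identical_columns(self, small_study):
        study = small_study
        genes = _study_genes(study)
        snaps = [_snapshot(study, label) for label in ("a", "b", "c")]
        table = run_series(snaps, genes, [study.planted_term])
        cells = [table.cell(study.planted_term, s) for s in ("a", "b", "c")]
        assert cells[0] == cells[1] == cells[2]

    def test_duplicate_labels_are_rejected(self, small_study):
        snaps = [_snapshot(small_study, "x"), _snapshot(small_study, "x")]
        with pytest.raises(ValueError, match="unique"):
            run_series(snaps, set(), ["GO:0000001"])

    def test_disjoint_study_yields_all_absent_column_with_warning(self, small_study):
        study = small_study
        table = run_series(
            [_snapshot(study)], {"no_such_gene"}, [study.planted_term]
        )
        assert table.warnings
        cell = table.cell(study.planted_term, "t1")
        assert not cell.tested and cell.status == "p_equals_1"

    def test_unresolvable_term_is_absent_from_snapshot(self, small_study):
        study = small_study
        table = run_series(
            [_snapshot(study)], _study_genes(study), ["GO:9999999"]
        )
        assert table.cell("GO:9999999", "t1").status == "absent_from_snapshot"


class TestDecouple:
    def test_fixed_point_when_series_shares_components(self, small_study):
        study = small_study
        snaps = [_snapshot(study, label) for label in ("a", "b")]
        for mode in ("fix_annotations", "fix_structure"):
            out = decouple(snaps, mode, "a")
            assert [s.label for s in out] == ["a", "b"]
            assert all(s.graph is study.graph for s in out)
            assert all(s.annos is study.annotations for s in out)

    def test_single_snapshot_collapses_to_plain_enrichment(self, small_study):
        study = small_study
        genes = _study_genes(study)
        snaps = [_snapshot(study)]
        plain = run_series(snaps, genes, [study.planted_term])
        for mode in ("fix_annotations", "fix_structure"):
            out = run_series(decouple(snaps, mode, "t1"), genes, [study.planted_term])
            assert out.cells == plain.cells

    def test_modes_cross_check_against_direct_runs(self, small_study):
        """Two snapshots differing only in annotations: fixing annotations
        flattens the trajectory; fixing structure reproduces the original."""
        study = small_study
        genes = _study_genes(study)
        config = SimulationConfig(
            n_terms=40, n_genes=80, seed=11, growth_fractions=(0.5, 1.0)
        )
        grown = simulate_growth(study.annotations, config)
        snaps = [
            Snapshot("t1", study.graph, grown[0]),
            Snapshot("t2", study.graph, grown[1]),
        ]
        plain = run_series(snaps, genes, [study.planted_term])

        fixed_annos = run_series(
            decouple(snaps, "fix_annotations", "t2"), genes, [study.planted_term]
        )
        c1 = fixed_annos.cell(study.planted_term, "t1")
        c2 = fixed_annos.cell(study.planted_term, "t2")
        assert c1 == c2  # flat trajectory
        assert c2 == plain.cell(study.planted_term, "t2")

        fixed_structure = run_series(
            decouple(snaps, "fix_structure", "t2"), genes, [study.planted_term]
        )
        assert fixed_structure.cells == plain.cells

    def test_unknown_reference_label_raises(self, small_study):
        with pytest.raises(ValueError, match="reference"):
            decouple([_snapshot(small_study)], "fix_structure", "nope")

    def test_unknown_mode_raises(self, small_study):
        with pytest.raises(ValueError, match="mode"):
            decouple([_snapshot(small_study)], "fix_everything", "t1")


class TestTopTerms:
    def test_truncates_to_available(self, small_study):
        filtered = filter_by_size(small_study.collection, 3, 500)
        results = enrich(_study_genes(small_study), filtered)[:3]
        assert top_terms(results, k=10) == [r.term_id for r in results]

    def test_k_zero_is_empty(self):
        assert top_terms([], k=0) == []

    def test_tie_prefers_lexicographically_smaller_id(self, small_study):
        filtered = filter_by_size(small_study.collection, 3, 500)
        results = enrich(set(), filtered)  # all p = 1: pure tie-break
        ids = top_terms(results, k=5)
        assert ids == sorted(ids)


class TestTrackTerms:
    def _table(self, cells):
        labels = sorted({s for (_, s) in cells})
        terms = sorted({t for (t, _) in cells})
        return TrajectoryTable(snapshot_labels=labels, term_ids=terms, cells=cells)

    def test_p_equal_one_becomes_reasoned_absence(self):
        cells = {
            ("GO:0000001", "t1"): TrajectoryCell("tested", 1.0, 1.0, 9, 10),
            ("GO:0000001", "t2"): TrajectoryCell("tested", 0.5, 1.0, 1, 10),
        }
        out = track_terms(self._table(cells))
        assert out.cell("GO:0000001", "t1").status == "p_equals_1"
        assert out.cell("GO:0000001", "t2").tested

    def test_small_gene_set_becomes_reasoned_absence(self):
        cells = {
            ("GO:0000001", "t1"): TrajectoryCell("tested", 0.2, 1.0, 2, 2),
            ("GO:0000001", "t2"): TrajectoryCell("tested", 0.1, 0.9, 1, 5),
        }
        out = track_terms(self._table(cells), min_genes=3)
        assert out.cell("GO:0000001", "t1").status == "fewer_than_min_genes"

    def test_everywhere_absent_terms_are_dropped(self):
        cells = {
            ("GO:0000001", "t1"): TrajectoryCell("tested", 1.0, 1.0, 2, 10),
            ("GO:0000002", "t1"): TrajectoryCell("tested", 0.3, 1.0, 1, 10),
        }
        out = track_terms(self._table(cells))
        assert out.term_ids == ["GO:0000002"]


def test_trajectory_tsv_round_trip(small_study):
    study = small_study
    genes = _study_genes(study)
    snaps = [_snapshot(study, label) for label in ("2010", "2012")]
    table = run_series(snaps, genes, [study.planted_term, "GO:9999999"])
    buf = io.StringIO()
    table.to_tsv(buf)
    buf.seek(0)
    back = TrajectoryTable.from_tsv(buf)
    assert back.snapshot_labels == table.snapshot_labels
    assert back.term_ids == table.term_ids
    assert back.cells == table.cells
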