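"""Expression matrix parsing and the filter → ln → t-test pipeline."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from gochron.expression import (
    ExpressionFormatError,
    ExpressionMatrix,
    differential_expression,
    filter_probes,
    log_transform,
    parse_matrix,
)

# pooled two-sample t for {1,2,3} vs {4,5,6}: t = (2-5)/(s_p*sqrt(2/3)) with
# s_p = 1; two-sided p frozen from the regularized incomplete beta
# I_{df/(df+t^2)}(df/2, 1/2) at df = 4 (independent of scipy.ttest_ind).
ORACLE_T = -3.6742346141747673
ORACLE_P = 0.021311641128756723


def _matrix(values, probes=None, samples=None, labels=None, probe_map=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=probes, columns=samples),
        group_labels=labels or {},
        probe_gene_map=probe_map or {},
    )


class TestParsing:
    def test_tsv_round_trip(self):
        text = "probe\ts1\ts2\npA\t1.5\t2.5\npB\t3.0\t4.0\n"
        m = parse_matrix(io.StringIO(text))
        assert m.probe_ids == ["pA", "pB"]
        assert m.sample_ids == ["s1", "s2"]
        assert m.data.loc["pB", "s2"] == 4.0

    def test_empty_data_section_is_an_error(self):
        with pytest.raises(ExpressionFormatError, match="no data rows"):
            parse_matrix(io.StringIO("probe\ts1\ts2\n"))

    def test_duplicate_probe_ids_are_rejected_by_name(self):
        text = "probe\ts1\npA\t1\npA\t2\n"
        with pytest.raises(ExpressionFormatError, match="pA"):
            parse_matrix(io.StringIO(text))

    def test_ragged_and_non_numeric_rows_are_rejected_with_location(self):
        with pytest.raises(ExpressionFormatError, match="line 2"):
            parse_matrix(io.StringIO("probe\ts1\ts2\npA\t1.0\n"))
        with pytest.raises(ExpressionFormatError, match="line 3"):
            parse_matrix(io.StringIO("probe\ts1\npA\t1.0\npB\tx\n"))

    def test_soft_dialect_extracts_table_subsets_and_gene_map(self):
        soft = "\n".join(
            [
                "^DATASET = GDS0001",
                "^SUBSET = GDS0001_1",
                "!subset_description = tumor",
                "!subset_sample_id = GSM1,GSM2",
                "^SUBSET = GDS0001_2",
                "!subset_description = normal tissue",
                "!subset_sample_id = GSM3,GSM4",
                "!dataset_table_begin",
                "ID_REF\tIDENTIFIER\tGSM1\tGSM2\tGSM3\tGSM4",
                "pA\tVEGFA\t5.0\t6.0\t1.0\t2.0",
                "pB\tACTB\t3.0\t3.5\t3.2\t3.1",
                "!dataset_table_end",
            ]
        )
        m = parse_matrix(io.StringIO(soft), dialect="soft",
                         case_subset="tumor", control_subset="normal")
        assert m.samples_in_group("case") == ["GSM1", "GSM2"]
        assert m.samples_in_group("control") == ["GSM3", "GSM4"]
        assert m.probe_gene_map == {"pA": "VEGFA", "pB": "ACTB"}
        assert m.data.loc["pA", "GSM3"] == 1.0


class TestFilterProbes:
    def test_global_median_filter_on_two_by_two(self):
        # values [[1,2],[3,4]]: global median 2.5 (midpoint convention);
        # probe 0 (max 2) is removed, probe 1 kept
        m = filter_probes(_matrix([[1, 2], [3, 4]]))
        assert m.probe_ids == ["p1"]

    def test_constant_matrix_keeps_everything(self):
        m = filter_probes(_matrix([[7, 7], [7, 7]]))
        assert m.probe_ids == ["p0", "p1"]

    def test_single_surviving_probe_is_identity(self):
        m = filter_probes(_matrix([[10, 20]]))
        assert m.probe_ids == ["p0"]

    def test_dominating_probe_always_survives(self):
        # the row holding the grid maximum can never fall below the global
        # median, so the filter always returns at least one probe
        data = _matrix([[1, 2], [3, 4], [100, 200]])
        kept = filter_probes(data)
        assert "p2" in kept.probe_ids and "p0" not in kept.probe_ids


class TestLogTransform:
    def test_known_values(self):
        m = log_transform(_matrix([[1.0, math.e, math.e**2]]))
        assert np.allclose(m.data.to_numpy(), [[0.0, 1.0, 2.0]])

    def test_non_positive_without_floor_is_an_error(self):
        with pytest.raises(ExpressionFormatError, match="p0"):
            log_transform(_matrix([[0.0, 1.0]]))

    def test_floor_clips_before_transform(self):
        m = log_transform(_matrix([[0.0, 1.0]]), floor=1.0)
        assert np.allclose(m.data.to_numpy(), [[0.0, 0.0]])


class TestDifferentialExpression:
    def _labeled(self, values, n_case, n_control, probe_map=None):
        samples = [f"c{i}" for i in range(n_case)] + [
            f"k{i}" for i in range(n_control)
        ]
        labels = {s: ("case" if s.startswith("c") else "control") for s in samples}
        return _matrix(values, samples=samples, labels=labels,
                       probe_map=probe_map or {})

    def test_pooled_t_matches_closed_form_oracle(self):
        m = self._labeled([[1, 2, 3, 4, 5, 6]], 3, 3, {"p0": "G"})
        res = differential_expression(m)
        assert res.table.t[0] == pytest.approx(ORACLE_T, abs=1e-12)
        assert res.table.p_raw[0] == pytest.approx(ORACLE_P, abs=1e-12)

    def test_constant_identical_probe_has_p_one(self):
        m = self._labeled([[5, 5, 5, 5], [1, 2, 3, 4]], 2, 2, {"p0": "A", "p1": "B"})
        res = differential_expression(m)
        assert res.table.p_raw[0] == 1.0 and res.table.t[0] == 0.0
        assert "A" not in res.de_genes

    def test_bonferroni_is_min_one_m_times_p(self):
        rng = np.random.default_rng(0)
        m = self._labeled(rng.lognormal(0, 1, size=(10, 8)), 4, 4)
        res = differential_expression(m)
        assert res.n_tests == 10
        assert np.allclose(
            res.table.p_bonferroni, np.minimum(1.0, 10 * res.table.p_raw)
        )

    def test_raw_p_01_at_10_tests_is_not_significant(self):
        # arithmetic of the correction: p=0.01, m=10 -> 0.1 > 0.05
        assert min(1.0, 10 * 0.01) == pytest.approx(0.1)

    def test_group_swap_negates_t_and_preserves_p(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(2, 0.5, size=(20, 10))
        m = self._labeled(values, 5, 5)
        swapped_labels = {
            s: ("control" if g == "case" else "case")
            for s, g in m.group_labels.items()
        }
        m_swapped = ExpressionMatrix(m.data, swapped_labels, m.probe_gene_map)
        a = differential_expression(m)
        b = differential_expression(m_swapped)
        assert np.allclose(a.table.t, -b.table.t)
        assert np.allclose(a.table.p_raw, b.table.p_raw)

    def test_de_genes_shrink_as_alpha_decreases(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(2, 0.5, size=(30, 12))
        values[:5, :6] *= 8  # strong real signal in 5 probes
        m = self._labeled(values, 6, 6, {f"p{i}": f"G{i}" for i in range(30)})
        loose = differential_expression(m, alpha=0.05).de_genes
        tight = differential_expression(m, alpha=0.001).de_genes
        assert tight <= loose

    def test_small_group_is_rejected(self):
        m = self._labeled([[1, 2, 3]], 1, 2)
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(m)

    def test_unmapped_probes_are_tallied_not_de(self):
        m = self._labeled([[10, 11, 1, 1.2], [1, 1.1, 1, 1.05]], 2, 2,
                          {"p1": "B"})
        res = differential_expression(m)
        assert res.n_unmapped_probes == 1
        assert all(g == "B" for g in res.de_genes)

    def test_null_data_calibration(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(6, 0.5, size=(2000, 20)))
        m = self._labeled(values, 10, 10)
        res = differential_expression(m)
        frac = float((res.table.p_raw < 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se

    def test_planted_shift_raises_median_t(self):
        rng = np.random.default_rng(4)
        ln = rng.normal(6, 0.5, size=(200, 20))
        ln[:50, :10] += 1.0  # delta = 1 on ln scale, 10 per group
        m = self._labeled(np.exp(ln), 10, 10)
        res = differential_expression(log_transform(m))
        t = res.table.t.to_numpy()
        assert np.median(t[:50]) > np.median(t[50:])


def test_matrix_rejects_non_finite_values():
    with pytest.raises(ExpressionFormatError, match="non-finite"):
        _matrix([[1.0, float("nan")]])
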