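"""Microarray differential-expression pipeline.

The pipeline mirrors a classical two-group microarray workflow: remove probes
whose maximum intensity never clears the global median, take the natural log
of every value, run an independent two-sample t-test per probe, then
Bonferroni-correct over the probes actually tested and call a gene
differentially expressed when any of its probes is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("case", "control")


class ExpressionFormatError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity grid with group labels and a probe→gene map."""

    data: pd.DataFrame  # index: probe ids; columns: sample ids
    group_labels: dict[str, str] = field(default_factory=dict)
    probe_gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ExpressionFormatError(f"duplicate probe id {dup!r}")
        if self.data.columns.has_duplicates:
            raise ExpressionFormatError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionFormatError(
                f"non-finite value at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        bad = set(self.group_labels.values()) - set(GROUPS)
        if bad:
            raise ExpressionFormatError(f"group labels must be in {GROUPS}: {bad}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels.get(s) == group]


@dataclass
class DEResult:
    """Per-probe statistics and the derived differentially-expressed gene set."""

    table: pd.DataFrame  # columns: probe, gene, t, p_raw, p_bonferroni, is_de
    de_genes: frozenset[str]
    n_tests: int
    alpha: float
    n_unmapped_probes: int = 0

    def write_tsv(self, stream: TextIO) -> None:
        self.table.to_csv(stream, sep="\t", index=False)


def parse_matrix(
    stream: Iterable[str],
    dialect: str = "tsv",
    group_labels: dict[str, str] | None = None,
    probe_gene_map: dict[str, str] | None = None,
    case_subset: str | None = None,
    control_subset: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``tsv`` dialect: header row of sample ids, first column probe ids; group
    labels and the probe→gene map are supplied separately.  ``soft`` dialect:
    a GEO GDS SOFT file — the dataset table provides values and (via the
    IDENTIFIER column) the probe→gene map, and subset blocks provide group
    labels; ``case_subset``/``control_subset`` select which subset
    descriptions map to which group (substring match).
    """
    if dialect == "tsv":
        return _parse_tsv(stream, group_labels or {}, probe_gene_map or {})
    if dialect == "soft":
        return _parse_soft(stream, case_subset, control_subset)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_tsv(stream, group_labels, probe_gene_map) -> ExpressionMatrix:
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if len(lines) < 2:
        raise ExpressionFormatError("matrix has no data rows")
    header = lines[0].split("\t")
    samples = header[1:]
    n = len(samples)
    probes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != n + 1:
            raise ExpressionFormatError(
                f"line {lineno}: expected {n + 1} columns, got {len(cols)}"
            )
        try:
            rows.append([float(c) for c in cols[1:]])
        except ValueError as exc:
            raise ExpressionFormatError(f"line {lineno}: non-numeric cell ({exc})")
        probes.append(cols[0])
    data = pd.DataFrame(rows, index=probes, columns=samples, dtype=float)
    return ExpressionMatrix(data, dict(group_labels), dict(probe_gene_map))


def _parse_soft(stream, case_subset, control_subset) -> ExpressionMatrix:
    subsets: dict[str, list[str]] = {}
    desc, sample_ids = None, None
    table_lines: list[str] = []
    in_table = False
    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith("^SUBSET"):
            desc, sample_ids = None, None
        elif line.startswith("!subset_description"):
            desc = line.split("=", 1)[1].strip()
        elif line.startswith("!subset_sample_id"):
            sample_ids = [s.strip() for s in line.split("=", 1)[1].split(",")]
        elif line.startswith("!dataset_table_begin"):
            in_table = True
            continue
        elif line.startswith("!dataset_table_end"):
            in_table = False
        elif in_table and line:
            table_lines.append(line)
        if desc is not None and sample_ids is not None:
            subsets[desc] = sample_ids
            desc, sample_ids = None, None

    if not table_lines:
        raise ExpressionFormatError("SOFT stream has no dataset table")
    header = table_lines[0].split("\t")
    if header[:2] != ["ID_REF", "IDENTIFIER"]:
        raise ExpressionFormatError("dataset table must start ID_REF, IDENTIFIER")
    samples = header[2:]
    probes, genes, rows = [], [], []
    for line in table_lines[1:]:
        cols = line.split("\t")
        probes.append(cols[0])
        genes.append(cols[1])
        rows.append([float(c) if c not in ("", "null") else np.nan
                     for c in cols[2 : 2 + len(samples)]])
    labels: dict[str, str] = {}
    for description, members in subsets.items():
        group = None
        if case_subset and case_subset in description:
            group = "case"
        elif control_subset and control_subset in description:
            group = "control"
        if group:
            for s in members:
                labels[s] = group
    data = pd.DataFrame(rows, index=probes, columns=samples, dtype=float)
    # drop probes with missing values: the t-test pipeline requires finite data
    data = data.dropna(axis=0)
    probe_gene_map = {p: g for p, g in zip(probes, genes) if p in data.index}
    return ExpressionMatrix(data, labels, probe_gene_map)


def read_group_labels(stream: Iterable[str]) -> dict[str, str]:
    """Two-column TSV: sample id, group (case/control)."""
    labels: dict[str, str] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sample, group = line.split("\t")[:2]
        labels[sample] = group
    return labels


def read_probe_gene_map(stream: Iterable[str]) -> dict[str, str]:
    """Two-column TSV: probe id, gene id."""
    mapping: dict[str, str] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        probe, gene = line.split("\t")[:2]
        mapping[probe] = gene
    return mapping


def filter_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes whose row maximum is below the global median intensity.

    The median is taken over every value in the grid (probes × samples); a
    probe whose maximum equals the median survives (strict inequality).
    """
    if matrix.data.empty:
        raise ExpressionFormatError("cannot filter an empty matrix")
    global_median = float(np.median(matrix.data.to_numpy()))
    keep = matrix.data.max(axis=1) >= global_median
    if not keep.any():
        raise ExpressionFormatError("probe filter removed every probe")
    return replace(matrix, data=matrix.data.loc[keep])


def log_transform(matrix: ExpressionMatrix, floor: float | None = None) -> ExpressionMatrix:
    """Natural log of every value; non-positive values are clipped to
    ``floor`` first when one is configured, otherwise they are an error."""
    values = matrix.data.to_numpy(copy=True)
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        values = np.maximum(values, floor)
    elif (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ExpressionFormatError(
            f"non-positive value at probe {matrix.data.index[i]!r}, "
            f"sample {matrix.data.columns[j]!r}; configure a floor to clip"
        )
    logged = pd.DataFrame(np.log(values), index=matrix.data.index,
                          columns=matrix.data.columns)
    return replace(matrix, data=logged)


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = True,
    gene_rule: str = "best",
) -> DEResult:
    """Two-sided independent t-test per probe with Bonferroni correction.

    ``equal_var=True`` gives the pooled-variance Student test (default);
    False gives Welch.  ``n_tests`` is the number of probes in ``matrix``
    (i.e. the probes surviving any upstream filter).  A probe that is
    constant and identical in both groups carries no signal and is assigned
    t = 0, p = 1.  ``gene_rule`` "best" marks a gene DE when *any* of its
    probes is significant; "all" requires every probe.
    """
    case = matrix.samples_in_group("case")
    control = matrix.samples_in_group("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError(
            f"need >= 2 samples per group (case={len(case)}, control={len(control)})"
        )
    unlabeled = [s for s in matrix.sample_ids if s not in matrix.group_labels]
    if unlabeled:
        raise ValueError(f"samples without group label: {unlabeled[:5]}")
    if gene_rule not in ("best", "all"):
        raise ValueError("gene_rule must be 'best' or 'all'")

    a = matrix.data[case].to_numpy()
    b = matrix.data[control].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    # degenerate probes: zero variance in both groups
    no_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t[no_var & same_mean] = 0.0
    p[no_var & same_mean] = 1.0
    sep = no_var & ~same_mean  # perfectly separated: infinitely strong signal
    t[sep] = np.sign(a.mean(axis=1) - b.mean(axis=1))[sep] * np.inf
    p[sep] = 0.0

    n_tests = len(matrix.data)
    p_bonf = np.minimum(1.0, n_tests * p)
    genes = [matrix.probe_gene_map.get(pr) for pr in matrix.probe_ids]
    is_de = p_bonf < alpha
    table = pd.DataFrame(
        {
            "probe": matrix.probe_ids,
            "gene": genes,
            "t": t,
            "p_raw": p,
            "p_bonferroni": p_bonf,
            "is_de": is_de,
        }
    )
    mapped = table[table["gene"].notna()]
    if gene_rule == "best":
        de_flags = mapped.groupby("gene")["is_de"].any()
    else:
        de_flags = mapped.groupby("gene")["is_de"].all()
    de_genes = frozenset(de_flags[de_flags].index)
    return DEResult(
        table=table,
        de_genes=de_genes,
        n_tests=n_tests,
        alpha=alpha,
        n_unmapped_probes=int(table["gene"].isna().sum()),
    )
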