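# Methods

## Model and procedure

`gochron` treats a knowledgebase snapshot as a pair *(ontology structure,
annotation set)* and scores it by a task: given a study gene list known to
represent some biology, how significantly does the corresponding term enrich?

**Propagation (true-path rule).** A direct annotation (gene g, term t)
implies g belongs to every ancestor of t. Ancestor closure is reflexive and
taken over `is_a` + `part_of` by default; `regulates` (which entered GO in
2008) is parsed but excluded from propagation unless requested, since
is_a + part_of is the classical true-path relation set and including
`regulates` changes gene-set semantics from composition to influence.
Cross-namespace parent edges are rejected outright — GO does not use them in
the era this framework models, and silently mixing namespaces would corrupt
per-branch universes. Duplicate (gene, term) assertions from multiple
evidence lines count once; a pair whose every assertion is NOT-qualified is
treated as evidence *against* membership and dropped (configurable).

**Enrichment.** One-sided over-representation via the hypergeometric upper
tail, computed through scipy's log-space survival function (stable to
universe sizes ~1e5). Bonferroni m = number of terms actually tested after
the 3–500 size filter: terms the filter removed yield no p-value, so
counting them would be incoherent. Ranks break p ties lexicographically by
term id, making every ordering deterministic. The size filter's bounds are
inclusive, and it is applied after intersecting sets with the measured-gene
universe (when one is supplied), keeping the 2×2 table margins
self-consistent: every count in the table is drawn from the same population.

**Expression pipeline.** Probe filter (row max < global grid median, strict
inequality, midpoint convention for even counts) → natural log → two-sided
pooled-variance t-test (Welch behind a flag) → Bonferroni over the surviving
probes. Filtering precedes the log transform. A gene is differentially
expressed when any of its probes is significant ("best-probe"; an
"all-probes" rule is available). Probes constant and identical across both
groups get t = 0, p = 1 (no signal); constant but separated probes get
p = 0. Values must be positive before the log; an optional floor clips
non-positive values for data that contain background-subtracted negatives.

**Series and decoupling.** The study list is derived once and reused across
snapshots: the object under evaluation is the knowledgebase, not the DE
call. Term identity across snapshots is keyed by the requested id with
per-snapshot alt-id resolution, so a term keeps one trajectory row as its id
drifts; a term unresolvable in a snapshot is an `absent_from_snapshot` cell.
Every (term, snapshot) cell is either a full record (p, Bonferroni p, rank,
set size) or a reasoned absence — `filtered_by_size`, `absent_from_snapshot`,
and after the omission rule (`track_terms`) also `p_equals_1` and
`fewer_than_min_genes`. Bonferroni m is per-snapshot, since each snapshot
tests its own term count. A snapshot sharing no genes with the study list
becomes an all-absent column plus a warning rather than an error.
`decouple` replaces either every graph or every annotation set with a
reference snapshot's; the result feeds `run_series` unchanged.

## Synthetic data: what it emulates, and what it does not

The generator stands in for an archived knowledgebase series plus a
two-group microarray study:

- **Ontology**: a rooted DAG built by levels (root alone; deeper levels
  sized ∝ branching^depth; each term takes 1–2 parents from strictly
  shallower levels, ~20% of edges `part_of`). Acyclicity holds by
  construction, so generation never needs cycle repair.
- **Annotations**: per gene a Poisson(2) number (min 1) of uniformly chosen
  direct terms, dates uniform over 2003–2012, evidence IEA/IDA/TAS at
  50/30/20%.
- **Growth**: nested record subsets of exactly round(f·N) records per
  fraction f — subsetting rather than date filtering, for exact sizes;
  date-based reconstruction is exercised separately in the annotation
  filters.
- **Expression**: one probe per gene; control intensities
  exp(baseline_g + N(0, σ)) with baseline_g ~ N(6, 1); case samples add δ on
  the ln scale for genes in the planted term's propagated set. Simulating on
  the natural scale and exponentiating means the pipeline's positivity
  precondition and log transform are exercised verbatim.

Default study conditions: 200 terms, depth 5, 500 genes, δ = 2, σ = 0.5,
10 samples per group, growth fractions 0.2–1.0 in steps of 0.2. δ = 2 at
σ = 0.5 gives per-probe t ≈ 8.9 — a strong but not degenerate signal, the
regime where a planted process should be recoverable if and only if the
machinery is correct.

The planted term is chosen mid-sized (15–80 propagated genes) and strictly
smaller than each of its proper ancestors. Without that constraint an
ancestor with an identical gene set ties the planted term's p exactly and
can win rank 1 on the lexicographic tie-break — a property of set identity,
not of the method.

What the generator does **not** emulate: real GO topology statistics
(term-size power laws, depth distribution), annotation bias toward
well-studied genes, probe-level artifacts (multiple probes per gene,
cross-hybridization), or correlated expression between genes. Passing tests
therefore demonstrate the machinery's correctness and calibration under
idealized conditions, not performance claims about any real knowledgebase.

## Numerical choices and degenerate inputs

- Hypergeometric tails via `hypergeom.sf(k-1, N, K, n)`; exhaustive
  integer enumeration agrees to < 1e-12 on every valid table with N ≤ 12.
- Even-count medians are the midpoint of the two central order statistics.
- Date cutoffs are inclusive (`date ≤ cutoff`), so a snapshot reconstructed
  at its own date retains that day's records.
- The probe filter cannot empty a finite matrix (the row holding the grid
  maximum always survives); the error path exists for defensive symmetry.
- Empty study ∩ universe is legal (all k = 0, p = 1); an empty collection or
  universe is a hard error.
- Trajectory TSVs serialize floats with `repr`, so table → TSV → table
  round-trips bit-exactly.

## Design decisions made where the design was open

- Whether the size filter counts all annotated genes or only measured genes:
  both supported; default counts within the supplied analysis universe.
- Probe→gene aggregation for DE calls: best-probe by default (the common
  convention); all-probes available.
- t-test variant: pooled two-sided by default, Welch optional.
- IEA annotations are kept by default — their exclusion is a hypothesis to
  test with the framework (via the evidence filter), not a baked-in prior.
- The decade-spanning archive retrieval that a real historical analysis
  needs is operational, not computational: snapshot files arrive via a
  user-supplied manifest (label, OBO path, GAF path), never the network.

## Known limitations

- No moderated statistics (limma-style), FDR control, or normalization; the
  evaluated pipeline is deliberately the plain classical one.
- No OWL parsing and no relationship types beyond is_a/part_of/regulates.
- The SOFT reader covers the GDS dialect's dataset table and subset blocks
  only.
- Exact reproduction of published historical analyses additionally depends
  on choices their authors did not document (probe→gene mapping version,
  background universe, exact snapshot dates); the framework exposes each as
  a parameter rather than fixing one silently.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
conditions above: 100 replicates for planted-term recovery, 50 replicated
five-snapshot growth series for trajectory monotonicity, and exhaustive
enumeration for the exact test. One replicate is ~0.1 s; the whole
acceptance run completes in well under a minute.
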