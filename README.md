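# gochron

**Task-based, temporal evaluation of Gene Ontology knowledgebases.**

The Gene Ontology (GO) and its annotation corpus (GOA) change continuously:
terms are added, moved and obsoleted, annotations accumulate. `gochron`
measures how well a given *(ontology structure, annotation set)* pair
recovers known biology through the field's most common application —
gene-set over-representation analysis — and tracks that performance across
time-stamped knowledgebase snapshots, separating the effect of structural
change from annotation change.

It is aimed at curators and computational biologists who want to ask: *for
my biological domain, is the knowledgebase getting better — and is that
driven by the ontology's structure or by its annotations?*

## The method

1. **Pick a term of interest** *T* and a dataset known to express the
   corresponding biology (e.g. a two-group expression experiment).
2. **Derive a study gene list** with a standard pipeline: drop probes whose
   maximum intensity is below the global median of the matrix, take the
   natural log, run an independent two-sample (pooled-variance) t-test per
   probe, keep genes with Bonferroni-corrected p < 0.05.
3. **Build term gene sets** from one snapshot: propagate every direct
   annotation (g, t) to all ancestors of t over `is_a`/`part_of` (the
   true-path rule), then keep terms annotated to between 3 and 500 genes.
4. **Enrich**: for each term with K of the N universe genes, overlapping the
   n-gene study list in k genes, the one-sided Fisher / hypergeometric tail

   p = P(X ≥ k), X ~ Hypergeom(N, K, n),

   Bonferroni-corrected over the m terms tested, ranked ascending by p.
5. **Evaluate**: the rank and p-value of *T* quantify how well this snapshot
   captures the expected biology. Repeat over a series of snapshots to get a
   trajectory; freeze one component (`decouple`) to attribute change to
   structure or annotations.

Everything is also exercisable without downloads through a synthetic
generator: a random rooted DAG ontology, a dated annotation corpus growing
across snapshots, and an expression matrix with a *planted* over-expressed
term whose recovery the pipeline should — and measurably does — achieve.

## Worked example

```python
from gochron.evaluation import track_terms
from gochron.synthetic import SimulationConfig, run_growth_experiment

table, study = run_growth_experiment(SimulationConfig(seed=1))
table = track_terms(table)
for label in table.snapshot_labels:
    c = table.cell(study.planted_term, label)
    print(label, c.set_size, f"{c.p_raw:.3e}", c.rank)
```

prints

```
t1 11 2.299e-09 1
t2 20 1.418e-20 1
t3 27 2.462e-29 1
t4 38 5.762e-45 1
t5 48 1.629e-65 1
```

Each row is one knowledgebase snapshot (annotation corpus grown to 20%,
40%, …, 100% of its final size under a frozen structure): the planted term's
propagated gene-set size, its raw enrichment p-value against the fixed study
list, and its rank among all tested terms. The monotone fall of p — some 56
orders of magnitude — is the signature of an annotation corpus converging on
the planted biology; the rank staying at 1 means the term of interest is
always the most significant hit. `examples/` contains this and three more
narrative scripts (single-snapshot enrichment, the expression pipeline, and
the structure-vs-annotation decoupling contrast).

A thin CLI mirrors the library: `gochron simulate` writes a complete corpus
(OBO, per-snapshot GAFs, expression TSV, manifest), and `gochron de`,
`enrich`, `series` and `decouple` run the pipeline from files.

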