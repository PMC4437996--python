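# rqlnet

Query-driven rule discovery and regulatory-network inference from
heterogeneous omics tables.

Regulatory networks link transcription factors, genes, metabolites and
experimental conditions.  Correlation-based inference treats all of these
the same way; rqlnet instead mines *multipredicate rules* X→Y, where each
side carries its own predicate, so one run can state things like
"whenever this deletion flag is 1, that transcript is strongly down" or
"whenever G3 is high, the A1 flag is clear" — mixing quantitative, binary
and categorical attributes in a single inference.  Rule semantics are
declared in a SQL-like query language, which makes the method
*query-driven*: the biologist states which kind of relationship to look
for instead of receiving one global network.

It is aimed at computational biologists who want programmable, inspectable
network inference: a Python API, plain-TSV inputs and outputs, Cytoscape
export, and a small command-line front end.

## The measures at the core

Rules are counted on evaluation units (samples, or sample pairs under a
WHERE condition) and scored with the four standard association measures:

    support(X→Y)    = count(X∪Y) / N
    confidence(X→Y) = count(X∪Y) / count(X)
    lift(X→Y)       = count(X∪Y)·N / (count(X)·count(Y))
    leverage(X→Y)   = count(X∪Y)/N − count(X)/N · count(Y)/N

A rule with confidence 1 is *exact*.  For multi-attribute antecedents only
two covers are reported: the exact rules with inclusion-minimal left-hand
sides (via minimal hypergraph transversals of the complemented violator
sets) and the approximate rules with inclusion-maximal left-hand sides.
Networks assembled from rules come with a topology panel (density,
clustering, centralization, heterogeneity, characteristic path length,
scale-free fit P(k) ~ k^−γ) and ranked interactions can be scored against
a gold standard with AUPR/AUROC.

## Worked example

`examples/01_toy_rules.py` mines a six-sample database of three tables —
gene expression (`gen`), metabolites (`met`) and sample annotation
(`ann`) — with one query mixing three predicates:

    FINDRULES
      SCOPE t1 IN (ann)
      HAVING one: t1.$a = 1 OVER A1
      AND zero: t1.$a = 0 OVER A1
      AND high: t1.$a > 0.5 OVER met.M2, gen.G3;

Running it prints:

    6 evaluation units × 4 labeled attributes: ['A1_one', 'A1_zero', 'M2_high', 'G3_high']
    2 rules at support ≥ 0.10, confidence ≥ 0.90:
      G3_high→A1_zero  [exact]  support=0.333 confidence=1.000 lift=2.000 leverage=0.167
      A1_one→M2_high  [exact]  support=0.500 confidence=1.000 lift=1.500 leverage=0.167

Both rules are exact: in every sample where the binary flag A1 is 1 the
metabolite M2 exceeds 0.5 (A1=1 is a sufficient condition), and in every
sample where gene G3 is high A1 is 0 (A1=0 is a necessary condition).
Support is the fraction of samples where both sides hold; lift > 1 and
leverage > 0 say the co-occurrence exceeds what independence would give.

The other examples cover the quadratic growth of rule counts with
attribute count (`02_scaling_study.py`), benchmarking ranked interactions
from co-expression and knockout queries against a gold standard with
best-rank combination (`03_knockout_benchmark.py`), and the topology
panel vs a Pearson-correlation baseline (`04_topology_panel.py`).

## Command line

    rqlnet fixtures out/fixtures --seed 0     # materialise synthetic inputs
    rqlnet infer config.yaml                  # tables + queries -> rules, edges, topology
    rqlnet eval config.yaml                   # ranked lists + AUPR/AUROC scores
    rqlnet topology out/edges.tsv             # panel for an exported edge table

`config.yaml` is flat: `tables` (list of paths, or name→path mapping),
`queries`, `output_dir`, optional `discovery` thresholds
(`min_support`, `min_confidence`, `max_lhs`, `mode`), `scale_center`,
`central`, `gold`.

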