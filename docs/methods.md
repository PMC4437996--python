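# Methods

## The model: multipredicate rules

rqlnet infers regulatory networks from tabular omics data by mining
*multipredicate rules* (MP-rules).  A rule X→Y states that whenever a
chosen predicate holds for every attribute in X on an evaluation unit, a
(possibly different) predicate holds for Y on the same unit.  Because each
side carries its own predicate, one inference run can mix quantitative
attributes (expression, metabolite levels), binary flags (a treatment or
deletion indicator) and categorical labels (a time point or developmental
phase) — e.g. "whenever the A1 flag is set, metabolite M2 exceeds 0.5".

Rule semantics are declared in a SQL-like statement:

    FINDRULES
      SCOPE t1 IN (table1), t2 IN (table2), ...
      WHERE condition(t1, t2, ...)
      HAVING label1: predicate1 OVER attributes1
      AND    label2: predicate2 OVER attributes2 ... ;

SCOPE binds tuple variables to tables; the optional WHERE restricts which
sample assignments count; each HAVING clause instantiates its predicate
once per OVER attribute, with the placeholder `tvar.$a` bound to that
attribute.  The concrete grammar is a reconstruction from the published
statement template and examples (the original dialect's full BNF is not
public); it adds an `abs()` function, which the similar-profile template
requires.

## Evaluation units and counting

All counting happens on the *satisfaction matrix*: evaluation units ×
labeled attributes, each cell true/false/missing.

* Arity 1: one unit per sample row (filtered by WHERE).
* Arity 2: combinations of one row per variable.  Two variables over the
  same table never share a row.  When there is no WHERE and every
  predicate is symmetric under exchanging the variables (checked
  syntactically after normalising commutative operators and
  abs-of-difference), unordered pairs are enumerated once; otherwise
  ordered pairs.  Symmetric semantics would double-count under ordering.
* Cross-table references (an annotation-table scope reading an expression
  value, or vice versa) are joined row-wise by sample identifier;
  mismatched identifiers are a binding error.

Missing values: input files mark them as empty cells, and any predicate
evaluated on a missing value yields a missing cell.  A unit contributes to
a rule's counts only when every cell of the rule's LHS∪RHS is non-missing
(pairwise-complete counting), which keeps all four measures well defined;
a unit whose WHERE value is missing is excluded.  This treatment is this
package's choice — the original platform does not document one.

## Interest measures

With counts taken over the units complete on X∪{Y}:

* support(X→Y) = count(X∪Y)/N — the rule's importance;
* confidence(X→Y) = count(X∪Y)/count(X) — its strength, directed;
* lift(X→Y) = count(X∪Y)·N/(count(X)·count(Y)) — 1 under independence;
* leverage(X→Y) = count(X∪Y)/N − count(X)/N·count(Y)/N — 0 under
  independence.

A rule is *exact* when confidence = 1 (to 1e−12).  Working defaults are
support ≥ 0.10 and confidence ≥ 0.90; discovery never prunes on lift or
leverage (they are ranking criteria only).

## Rule discovery

**1–1 rules** are found by scoring every ordered pair of non-sibling
columns (vectorised as boolean matrix products).  Two labels of the same
underlying attribute (`G1_high`, `G1_low`) are siblings and never pair —
such rules are tautological or contradictory, never informative.

**n–1 rules** would explode combinatorially, so only two covers are
reported, per consequent y.  The *violator set* S(u) of a unit u where y
is present-but-false collects the satisfied columns at u (missing cells
never count as satisfied, which is exactly consistent with
pairwise-complete confidence).  Then:

* exact rules (canonical cover, smallest LHSs): X→y is exact iff X is a
  hitting set of the complemented violator sets {U_y − S(u)}; the
  inclusion-minimal exact LHSs are the minimal hypergraph transversals of
  that family.  Transversals are enumerated by a depth-first minimal
  hitting-set search with uncovered-edge branching and criticality
  pruning (MMCS-style), capped at |LHS| ≤ max_lhs.  An antecedent that is
  never satisfied (vacuously exact) is dropped.  If y is never violated
  the degenerate rule ∅→y is reported; it carries no network edge.
* approximate rules (Gottlob–Libkin cover, largest LHSs): the
  inclusion-maximal members of {X : |X| ≤ max_lhs, X ⊆ some S(u)} whose
  confidence clears the threshold.  A violator set larger than max_lhs
  contributes its size-max_lhs subsets before maximality is applied.

Both discovery modes are validated against brute-force subset enumeration
on small random matrices (including matrices with missing cells), and the
transversal enumerator against the full subset lattice.

*Central attributes* restrict discovery to rules touching at least one of
a user-chosen set — turning inference into biology-driven clustering
around chosen anchors.  Output order is deterministic: (rhs, |lhs|,
lexicographic lhs).

## Networks and topology

Each 1–1 rule is one edge; an n–1 rule contributes one edge per LHS member
(star expansion, matching flat Cytoscape edge lists; the shared rule id
preserves the hyperedge).  Label collapsing (`A_high`/`A_low` → `A`) and
undirected merging keep the best-confidence rule's metrics on the
surviving edge.

The topology panel is computed on the undirected simple-graph view:
density 2E/(n(n−1)); average neighbours 2E/n; heterogeneity = coefficient
of variation of the degree sequence; centralization = n/(n−2) ·
(max_degree/(n−1) − density); average clustering over all nodes with 0
assigned below degree 2 (one of two common conventions; stated because
published tools differ); characteristic path length over connected pairs;
connected-component count.  The scale-free criterion fits log P(k) against
log k by unbinned least squares over observed degrees k ≥ 1 and reports
the squared correlation r² and |slope| = γ; at least three distinct
positive degrees are required.  Metrics are cross-checked in the test
suite against python-igraph, an independent graph library.

A Pearson baseline network (undirected edge where |r| ≥ cutoff, default
0.8) is provided as the standard correlation comparator; constant
attributes are excluded with a warning.

## Benchmark evaluation

Rules map to regulator→target interactions through their underlying
attributes and are ranked by descending leverage, then descending
confidence, then lexicographically (fully deterministic); duplicate
interactions keep their best rank, and lists truncate at 100 000 entries.
Rankings from several queries merge by *best rank* (absent = worse than
anything present; ties break on the secondary rank, then
lexicographically) — the QD1+2-style combination.

Scoring drops interactions absent from the gold standard, sweeps the
remainder, and integrates precision–recall and ROC curves trapezoidally.
Positives never retrieved count as misses: the recall denominator is the
full positive set, AUPR is integrated over the achieved recall range, and
the ROC curve is completed from the last swept point to (1, 1),
equivalent to a random ordering of everything not retrieved.  Overall
scores are geometric means of per-network AUPR and AUROC, and the overall
score is the arithmetic mean of the two — the plain-composition variant,
not the p-value-transformed challenge score.  A zero metric zeroes its
geometric mean.

The QD1/QD2 query semantics shipped here are reconstructions (the
originals are not public): QD1 mines high/low co-expression rules on
scaled data at ±1 sd; QD2 mines cross-table rules from binary deletion
flags to strong raw-scale expression responses at ±2 baseline sd.  Both
are plain text templates under `examples/queries/` and builder functions
in `rqlnet.evaluation`.

## Synthetic data

The generators are seed-deterministic (identical spec → bit-identical
output) and emit datasets that round-trip through the TSV dialect.

* `random_dataset`: iid uniform(0,1) matrices (distribution switchable to
  normal), the input of the rule-count scaling study.
* `toy_database`: six samples × three tables with two planted exact rules
  (A1=1 ⇒ M2>0.5; G3>0.5 ⇒ A1=0), non-vacuous antecedents, one
  deliberately violated candidate (M2>0.5 does not force A1=1), and a
  categorical time column of consecutive integers for WHERE clauses.  The
  planted implications are fixed; only rule-irrelevant cells get seeded
  jitter, so the constraints hold for every seed.
* `planted_rules`: binary matrices with implanted implications; each
  holds on a (1−noise) fraction of antecedent-true units.  Consequents
  may not feed other rules' antecedents (forced values would conflict).
* `knockout_compendium`: a steady-state deletion compendium.  Each TF
  activates a random subset of targets; expression baselines are N(0,1);
  in a TF's deletion samples its own expression and its targets drop by
  the effect size; one binary deletion flag per TF sits in a separate
  annotation table; the gold standard is the generating edge set plus an
  equal-size random negative sample.  There is no dynamical simulation —
  steady-state shifts are all the knockout semantics needs.

What passing tests on these generators show — and what they do not: the
generators produce clean, low-dimensional signals with known ground
truth, so tests demonstrate correctness of the machinery (counting,
covers, ranking, scoring), not performance on real compendia with
correlated noise, batch effects and indirect regulation.

## Scales, defaults and design choices

* z-scoring uses sd with one delta degree of freedom (the convention of
  R's `scale()`); constant attributes are a hard error.
* Type inference: all values in {0,1} → binary; any non-numeric value →
  categorical; else quantitative.  Explicit hints win.  Categorical
  values that happen to be numeric (e.g. the time column) are coerced in
  predicate arithmetic; truly non-numeric operands raise an evaluation
  error naming the unit and column.
* Q1's discretisation threshold defaults to δ = 0 (above/below the mean
  after scaling) — the parameter-free choice; Q2's agreement tolerance
  defaults to ε = 0.25 sd so exact ties always agree.  Both are exposed
  as knobs.
* The scaling study runs at desk scale: 20 samples, 50–800 attributes,
  five replicate matrices per size with counts averaged before the
  log-log fit (rule counts on random data vary dataset to dataset).  The
  per-pair pass probability is independent of the attribute count, so the
  expected slope is exactly 2.
* The knockout perfect-recovery check uses effect size 8 with noise sd 1:
  at that separation a single replicate crossing the ±2 response
  threshold has probability ≈ 1e−9, so full recovery (AUROC = 1) holds at
  any seed.  At the generator default of 5 the per-edge miss probability
  is ≈ 0.4%, which occasionally costs one edge.
* Thresholds are compared with a 1e−12 tolerance so borderline floating
  sums never flip a rule.

## Known limitations

* The satisfaction matrix is materialised in memory; there is no
  streaming or DBMS-backed evaluation.
* Predicate evaluation is interpreted per unit × column; very large
  arity-2 scopes (tens of thousands of pairs × thousands of columns) are
  slow.
* Approximate n–1 discovery enumerates size-max_lhs subsets of oversized
  violator sets; with max_lhs > 3 and wide matrices this can blow up.
* The grammar is a reconstruction; statements valid in the original
  dialect may not parse here and vice versa.
* Label collapsing and interaction mapping strip the final
  `_label` suffix; attribute names whose own final underscore group
  collides with a predicate label should be avoided.
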