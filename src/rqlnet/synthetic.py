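"""Seed-deterministic synthetic inputs for every pipeline stage.

Four generators cover the study conditions the package is exercised under:

* :func:`random_dataset` — iid uniform(0,1) numeric matrices, the input of
  the rule-count scaling study;
* :func:`toy_database` — a three-table, six-sample heterogeneous database
  (gene expression / metabolites / sample annotation) with two planted
  exact rules and one deliberately violated candidate rule;
* :func:`planted_rules` — binary matrices with implanted implications at a
  controlled noise level, for rule-recovery scoring;
* :func:`knockout_compendium` — a steady-state expression compendium with
  transcription-factor deletion conditions and the generating
  regulator→target gold standard.

Identical ``GeneratorSpec`` (in particular the seed) → bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .evaluation import GoldStandard
from .tables import Dataset


@dataclass(frozen=True)
class GeneratorSpec:
    """Shared knobs for the generators."""
    seed: int = 0
    n_samples: int = 100
    n_attrs: int = 100
    noise: float = 0.0
    extras: tuple = ()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def random_dataset(spec: GeneratorSpec, name: str = "rand",
                   distribution: str = "uniform") -> Dataset:
    """iid quantitative matrix; attributes G0001, G0002, ...

    ``distribution`` is 'uniform' (on (0,1), the default) or 'normal'
    (standard normal).
    """
    if spec.n_samples < 1 or spec.n_attrs < 1:
        raise GenerationError("need at least one sample and one attribute")
    rng = spec.rng()
    if distribution == "uniform":
        values = rng.random((spec.n_samples, spec.n_attrs))
    elif distribution == "normal":
        values = rng.standard_normal((spec.n_samples, spec.n_attrs))
    else:
        raise GenerationError(f"unknown distribution {distribution!r}")
    attrs = [f"G{j + 1:04d}" for j in range(spec.n_attrs)]
    frame = pd.DataFrame(values, index=_sample_ids(spec.n_samples),
                         columns=attrs)
    return Dataset(name, frame, {a: "quantitative" for a in attrs})


# ---------------------------------------------------------------------------
# Toy heterogeneous database
# ---------------------------------------------------------------------------

def toy_database(seed: int = 0) -> dict[str, Dataset]:
    """Three tables (gen, met, ann) over six shared samples.

    Constructed so that, on every seed:

    1. whenever ``A1 = 1``, ``M2 > 0.5`` (exact rule A1_1 → M2_high);
    2. whenever ``G3 > 0.5``, ``A1 = 0`` (exact rule G3_high → A1_0);
    3. both antecedents hold at least twice (the rules are non-vacuous);
    4. ``M2_high → A1_1`` is violated, so approximate ≠ exact.

    ``gen`` holds quantitative G1–G4, ``met`` quantitative M1–M3, ``ann``
    binary A1, A2, quantitative A3 and a categorical ``time`` column of
    consecutive integers (supporting consecutive-sample WHERE clauses).
    Only attributes irrelevant to the planted rules are jittered by the
    seed.
    """
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(1, 7)]

    a1 = np.array([1, 1, 0, 0, 0, 1])
    a2 = np.array([0, 1, 0, 1, 1, 0])
    # M2 > 0.5 wherever A1 = 1, and also at s4 (A1 = 0) → rule 4's violation
    m2 = np.array([0.80, 0.90, 0.30, 0.70, 0.20, 0.60])
    # G3 > 0.5 only where A1 = 0 (s3, s4)
    g3 = np.array([0.20, 0.40, 0.90, 0.70, 0.30, 0.10])

    def jitter(base):
        return np.round(base + rng.uniform(-0.04, 0.04, size=6), 3)

    gen = pd.DataFrame({
        "G1": jitter([0.55, 0.62, 0.31, 0.44, 0.71, 0.52]),
        "G2": jitter([0.25, 0.37, 0.66, 0.58, 0.12, 0.47]),
        "G3": g3,
        "G4": jitter([0.91, 0.15, 0.48, 0.33, 0.62, 0.27]),
    }, index=ids)
    met = pd.DataFrame({
        "M1": jitter([0.42, 0.51, 0.23, 0.67, 0.35, 0.58]),
        "M2": m2,
        "M3": jitter([0.12, 0.83, 0.45, 0.29, 0.74, 0.38]),
    }, index=ids)
    ann = pd.DataFrame({
        "A1": a1, "A2": a2,
        "A3": jitter([0.31, 0.46, 0.59, 0.22, 0.68, 0.41]),
        "time": np.arange(1, 7),
    }, index=ids)

    return {
        "gen": Dataset("gen", gen, {c: "quantitative" for c in gen.columns}),
        "met": Dataset("met", met, {c: "quantitative" for c in met.columns}),
        "ann": Dataset("ann", ann, {"A1": "binary", "A2": "binary",
                                    "A3": "quantitative",
                                    "time": "categorical"}),
    }


TOY_QUERY = """\
# the worked predicates on the toy database: binary flags of ann,
# high metabolite / expression levels of met and gen (joined by sample id)
FINDRULES
  SCOPE t1 IN (ann)
  HAVING one: t1.$a = 1 OVER A1
  AND zero: t1.$a = 0 OVER A1
  AND high: t1.$a > 0.5 OVER met.M2, gen.G3;
"""


# ---------------------------------------------------------------------------
# Planted implications
# ---------------------------------------------------------------------------

def planted_rules(spec: GeneratorSpec,
                  rules: Sequence[tuple[Sequence[str], str]],
                  p_true: float = 0.6,
                  ) -> tuple[Dataset, list[tuple[frozenset[str], str]]]:
    """Binary matrix with implanted implications.

    Attributes are B01, B02, ... (``spec.n_attrs`` of them).  Background
    cells are iid Bernoulli(``p_true``); then, in generation order, each
    planted rule (lhs, rhs) forces rhs = 1 on a (1 − ``spec.noise``)
    fraction of the units where all lhs attributes are 1, and rhs = 0 on
    the remainder.  An rhs that also feeds a later rule's lhs (a chain or
    cycle) is rejected, as is a repeated rhs — both would let one rule
    silently overwrite another's forced values.

    Returns the dataset and the planted truth as (frozenset lhs, rhs).
    """
    names = [f"B{j + 1:02d}" for j in range(spec.n_attrs)]
    known = set(names)
    for lhs, rhs in rules:
        for a in list(lhs) + [rhs]:
            if a not in known:
                raise GenerationError(f"planted rule references unknown "
                                      f"attribute {a!r}")
    rhss = [rhs for _, rhs in rules]
    if len(set(rhss)) != len(rhss):
        raise GenerationError("two planted rules share a consequent")
    lhs_attrs = {a for lhs, _ in rules for a in lhs}
    clash = sorted(set(rhss) & lhs_attrs)
    if clash:
        raise GenerationError(
            f"attributes {clash} are both consequent and antecedent; "
            f"the forced values would conflict")
    rng = spec.rng()
    data = (rng.random((spec.n_samples, spec.n_attrs)) < p_true
            ).astype(float)
    col = {a: j for j, a in enumerate(names)}
    for lhs, rhs in rules:
        mask = np.all(data[:, [col[a] for a in lhs]] == 1, axis=1)
        hold = rng.random(spec.n_samples) >= spec.noise
        data[mask & hold, col[rhs]] = 1.0
        data[mask & ~hold, col[rhs]] = 0.0
    frame = pd.DataFrame(data, index=_sample_ids(spec.n_samples),
                         columns=names)
    ds = Dataset("planted", frame, {a: "binary" for a in names})
    truth = [(frozenset(lhs), rhs) for lhs, rhs in rules]
    return ds, truth


# ---------------------------------------------------------------------------
# Knockout compendium
# ---------------------------------------------------------------------------

def knockout_compendium(spec: GeneratorSpec, n_tfs: int = 5,
                        n_targets: int = 20, effect_size: float = 5.0,
                        n_replicates: int = 3, n_controls: int = 6,
                        edge_density: float = 0.3,
                        ) -> tuple[Dataset, Dataset, GoldStandard]:
    """Steady-state expression data with TF-deletion conditions.

    Each of ``n_tfs`` transcription factors (TF01, ...) activates a random
    ~``edge_density`` subset of ``n_targets`` target genes (G01, ...; every
    TF gets at least one target).  Expression baselines are N(0, 1); in the
    ``n_replicates`` samples where a TF is deleted, the TF's own expression
    and each of its targets are shifted by −``effect_size``.  The
    annotation table carries one binary deletion flag per TF, aligned by
    sample id.  The gold standard holds the generating regulator→target
    pairs and an equal-size random negative set.
    """
    if n_tfs < 1 or n_targets < 1:
        raise GenerationError("need at least one TF and one target")
    rng = spec.rng()
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    targets = [f"G{j + 1:02d}" for j in range(n_targets)]

    edges = set()
    for i, tf in enumerate(tfs):
        picks = rng.random(n_targets) < edge_density
        if not picks.any():
            picks[rng.integers(n_targets)] = True
        for j in np.nonzero(picks)[0]:
            edges.add((tf, targets[j]))

    n_samples = n_tfs * n_replicates + n_controls
    ids = _sample_ids(n_samples)
    deleted = np.zeros((n_samples, n_tfs))
    for i in range(n_tfs):
        deleted[i * n_replicates:(i + 1) * n_replicates, i] = 1

    genes = tfs + targets
    expr = rng.standard_normal((n_samples, len(genes)))
    for i, tf in enumerate(tfs):
        rows = deleted[:, i] == 1
        expr[rows, i] -= effect_size  # the deleted TF itself reads low
        for j, tgt in enumerate(targets):
            if (tf, tgt) in edges:
                expr[rows, n_tfs + j] -= effect_size

    expression = Dataset(
        "expr", pd.DataFrame(expr, index=ids, columns=genes),
        {g: "quantitative" for g in genes})
    annotation = Dataset(
        "ann", pd.DataFrame(deleted, index=ids, columns=tfs),
        {t: "binary" for t in tfs})

    non_edges = [(tf, tgt) for tf in tfs for tgt in targets
                 if (tf, tgt) not in edges]
    k = min(len(edges), len(non_edges))
    pick = rng.choice(len(non_edges), size=k, replace=False)
    negatives = frozenset(non_edges[i] for i in sorted(pick))
    gold = GoldStandard(frozenset(edges), negatives)
    return expression, annotation, gold
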