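"""Rule discovery from a satisfaction matrix, with interest measures.

A rule X→Y states that whenever every labeled attribute in X is satisfied
on an evaluation unit, Y is satisfied too.  Rules are scored with the four
standard association-rule measures, computed over the units that are
*complete* (no missing cell) on X∪{Y}:

    support(X→Y)    = count(X∪Y) / N
    confidence(X→Y) = count(X∪Y) / count(X)
    lift(X→Y)       = count(X∪Y)·N / (count(X)·count(Y))
    leverage(X→Y)   = count(X∪Y)/N − count(X)/N · count(Y)/N

A rule is *exact* when its confidence is 1.  Discovery modes:

``one_to_one``
    every ordered pair of non-sibling columns passing the support and
    confidence thresholds;
``n_to_one``
    for each consequent, the exact rules with inclusion-minimal left-hand
    sides (the canonical cover, via minimal hypergraph transversals of the
    complemented violator sets) and the approximate rules with
    inclusion-maximal left-hand sides (the Gottlob–Libkin cover).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .engine import MISSING, SatisfactionMatrix
from .errors import BindingError, UndefinedMeasureError

_EPS = 1e-12


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds and mode for rule discovery.

    min_support / min_confidence are the working defaults used for network
    inference (0.10 / 0.90); max_lhs is the n of n–1 rules.
    """
    min_support: float = 0.10
    min_confidence: float = 0.90
    max_lhs: int = 1
    mode: str = "one_to_one"

    def __post_init__(self):
        if not (0 <= self.min_support <= 1 and 0 <= self.min_confidence <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.max_lhs < 1:
            raise ValueError("max_lhs must be ≥ 1")
        if self.mode not in ("one_to_one", "n_to_one"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Rule:
    lhs: frozenset[str]
    rhs: str
    support: float
    confidence: float
    lift: float
    leverage: float
    exact: bool

    def __str__(self):
        left = ",".join(sorted(self.lhs)) if self.lhs else "∅"
        return f"{left}→{self.rhs}"

    @property
    def sort_key(self):
        return (self.rhs, len(self.lhs), tuple(sorted(self.lhs)))


@dataclass
class RuleSet:
    rules: list[Rule]
    config: DiscoveryConfig
    query_id: str = ""
    N: int = 0

    def __post_init__(self):
        keys = [(r.lhs, r.rhs) for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (lhs, rhs) pairs in rule set")

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"lhs": ",".join(sorted(r.lhs)), "rhs": r.rhs,
              "support": r.support, "confidence": r.confidence,
              "lift": r.lift, "leverage": r.leverage,
              "exact": int(r.exact), "query_id": self.query_id}
             for r in self.rules],
            columns=["lhs", "rhs", "support", "confidence", "lift",
                     "leverage", "exact", "query_id"])

    def to_tsv(self, path) -> None:
        """Tab-delimited rule table (the Cytoscape-compliant edge dialect)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interest measures (single-rule API)
# ---------------------------------------------------------------------------

def _counts(m: SatisfactionMatrix, X: Iterable[str], Y: str):
    """(count X, count Y, count X∪Y, N) over units complete on X∪{Y}."""
    cols = [m.column_index(c) for c in set(X) | {Y}]
    xcols = [m.column_index(c) for c in set(X)]
    ycol = m.column_index(Y)
    sub = m.data[:, cols]
    complete = (sub != MISSING).all(axis=1)
    true = m.data == 1
    n = int(complete.sum())
    n_x = int((complete & true[:, xcols].all(axis=1)).sum()) if xcols else n
    n_y = int((complete & true[:, ycol]).sum())
    n_xy = int((complete & true[:, xcols].all(axis=1)
                & true[:, ycol]).sum()) if xcols else n_y
    return n_x, n_y, n_xy, n


def support(m: SatisfactionMatrix, X: Iterable[str], Y: str) -> float:
    """Fraction of complete units where every member of X∪{Y} is true."""
    _, _, n_xy, n = _counts(m, X, Y)
    return n_xy / n if n else 0.0


def confidence(m: SatisfactionMatrix, X: Iterable[str], Y: str) -> float:
    """Conditional frequency of Y among units where X holds (directed)."""
    n_x, _, n_xy, _ = _counts(m, X, Y)
    if n_x == 0:
        raise UndefinedMeasureError(
            f"confidence undefined: antecedent {sorted(set(X))} never holds")
    return n_xy / n_x


def lift(m: SatisfactionMatrix, X: Iterable[str], Y: str) -> float:
    """Observed-to-expected co-occurrence ratio; 1 under independence."""
    n_x, n_y, n_xy, n = _counts(m, X, Y)
    if n_x == 0 or n_y == 0:
        raise UndefinedMeasureError("lift undefined: zero marginal count")
    return (n_xy * n) / (n_x * n_y)


def leverage(m: SatisfactionMatrix, X: Iterable[str], Y: str) -> float:
    """Difference between observed and independence-expected support."""
    n_x, n_y, n_xy, n = _counts(m, X, Y)
    if n == 0:
        return 0.0
    return n_xy / n - (n_x / n) * (n_y / n)


def measure_rule(m: SatisfactionMatrix, X: frozenset[str], Y: str) -> Rule:
    """Score one rule with all four measures."""
    n_x, n_y, n_xy, n = _counts(m, X, Y)
    if n_x == 0:
        raise UndefinedMeasureError(
            f"rule {sorted(X)}→{Y}: antecedent never holds")
    conf = n_xy / n_x
    lft = (n_xy * n) / (n_x * n_y) if n_y else float("nan")
    return Rule(frozenset(X), Y,
                support=n_xy / n if n else 0.0,
                confidence=conf,
                lift=lft,
                leverage=(n_xy / n - (n_x / n) * (n_y / n)) if n else 0.0,
                exact=abs(conf - 1.0) <= _EPS)


# ---------------------------------------------------------------------------
# 1–1 discovery (vectorised over all column pairs)
# ---------------------------------------------------------------------------

def discover_11(m: SatisfactionMatrix, cfg: DiscoveryConfig | None = None,
                central: Optional[frozenset[str]] = None,
                query_id: str = "") -> RuleSet:
    """All ordered non-sibling column pairs x→y passing the thresholds."""
    cfg = cfg or DiscoveryConfig()
    names = m.column_names
    C = len(names)
    true = (m.data == 1).astype(np.float64)
    present = (m.data != MISSING).astype(np.float64)
    n_pair = present.T @ present          # units complete on {x, y}
    n_xy = true.T @ true
    n_x = true.T @ present                # x true among pair-complete units
    n_y = n_x.T

    with np.errstate(divide="ignore", invalid="ignore"):
        sup = np.where(n_pair > 0, n_xy / n_pair, 0.0)
        conf = np.where(n_x > 0, n_xy / np.where(n_x > 0, n_x, 1), 0.0)

    ok = (n_x > 0) & (sup >= cfg.min_support - _EPS) \
        & (conf >= cfg.min_confidence - _EPS)
    np.fill_diagonal(ok, False)
    # sibling exclusion: never pair two labels of one underlying attribute
    underlying = {(c.dataset, c.attribute) for c in m.columns}
    uid = {u: k for k, u in enumerate(sorted(underlying))}
    ids = np.array([uid[(c.dataset, c.attribute)] for c in m.columns])
    ok &= ids[:, None] != ids[None, :]
    if central is not None:
        _check_central(m, central)
        cmask = np.array([n in central for n in names])
        ok &= cmask[:, None] | cmask[None, :]

    rules = []
    for i, j in zip(*np.nonzero(ok)):
        nx, ny, nxy, n = n_x[i, j], n_y[i, j], n_xy[i, j], n_pair[i, j]
        lft = (nxy * n) / (nx * ny) if ny else float("nan")
        cf = nxy / nx
        rules.append(Rule(frozenset([names[i]]), names[j],
                          support=nxy / n, confidence=cf, lift=lft,
                          leverage=nxy / n - (nx / n) * (ny / n),
                          exact=abs(cf - 1.0) <= _EPS))
    rules.sort(key=lambda r: r.sort_key)
    return RuleSet(rules, cfg, query_id, m.N)


# ---------------------------------------------------------------------------
# Violator families and hypergraph transversals (n–1 discovery)
# ---------------------------------------------------------------------------

def violator_families(m: SatisfactionMatrix, y: str) -> set[frozenset[str]]:
    """The family {S(u)} of satisfied-column sets at units violating y.

    For every unit where y is present but false, S(u) collects the columns
    (excluding y and its siblings) satisfied at that unit; a missing cell is
    never counted as satisfied.  Duplicates collapse (the family is a set).
    """
    ycol = m.column_index(y)
    sibs = m.siblings(y)
    keep = [j for j, c in enumerate(m.columns) if c.name not in sibs]
    names = [m.columns[j].name for j in keep]
    fam = set()
    for i in range(m.N):
        if m.data[i, ycol] == 0:
            fam.add(frozenset(names[k] for k, j in enumerate(keep)
                              if m.data[i, j] == 1))
    return fam


def minimal_transversals(family: Iterable[Iterable],
                         max_size: int | None = None) -> list[frozenset]:
    """All inclusion-minimal hitting sets of a set family.

    Depth-first enumeration with uncovered-edge branching and criticality
    pruning (MMCS-style): a branch dies as soon as a chosen vertex stops
    being the unique cover of some edge, so only minimal transversals are
    emitted.  The empty family has the single transversal ∅; a family
    containing ∅ has none.  Output is canonical: sorted by size, then
    lexicographically.
    """
    edges = {frozenset(e) for e in family}
    if not edges:
        return [frozenset()]
    if frozenset() in edges:
        return []
    # only inclusion-minimal edges constrain the transversals
    edge_list = [e for e in edges if not any(o < e for o in edges)]
    universe = sorted(set().union(*edge_list))
    edges_with = {v: frozenset(i for i, e in enumerate(edge_list) if v in e)
                  for v in universe}
    results: list[frozenset] = []

    def walk(partial: list, cand: set, uncov: list, crit: dict):
        if not uncov:
            results.append(frozenset(partial))
            return
        if max_size is not None and len(partial) >= max_size:
            return
        pivot = min(uncov, key=lambda i: len(edge_list[i] & cand))
        branch = sorted(edge_list[pivot] & cand)
        if not branch:
            return
        cand = cand - set(branch)
        for v in branch:
            new_crit, alive = {}, True
            for u in partial:
                cu = crit[u] - edges_with[v]
                if not cu:
                    alive = False
                    break
                new_crit[u] = cu
            if alive:
                new_crit[v] = frozenset(i for i in uncov
                                        if v in edge_list[i])
                walk(partial + [v], cand,
                     [i for i in uncov if v not in edge_list[i]], new_crit)
            cand = cand | {v}

    walk([], set(universe), list(range(len(edge_list))), {})
    return sorted(set(results), key=lambda s: (len(s), tuple(sorted(s))))


def discover_n1(m: SatisfactionMatrix, cfg: DiscoveryConfig | None = None,
                central: Optional[frozenset[str]] = None,
                query_id: str = "") -> RuleSet:
    """Canonical (minimal exact) + Gottlob–Libkin (maximal approximate)
    covers for every consequent, capped at |lhs| ≤ max_lhs."""
    cfg = cfg or DiscoveryConfig(mode="n_to_one")
    if central is not None:
        _check_central(m, central)
    rules: list[Rule] = []
    for col in m.columns:
        y = col.name
        ycol = m.column_index(y)
        if not (m.data[:, ycol] != MISSING).any():
            continue  # consequent entirely missing
        sibs = m.siblings(y)
        universe = frozenset(n for n in m.column_names if n not in sibs)
        fam = violator_families(m, y)

        # exact rules: minimal transversals of the complemented violators
        complements = [universe - s for s in fam]
        for T in minimal_transversals(complements, max_size=cfg.max_lhs):
            if not T and fam:
                continue
            try:
                r = measure_rule(m, frozenset(T), y)
            except UndefinedMeasureError:
                continue  # vacuous antecedent: no unit ever satisfies it
            if r.support >= cfg.min_support - _EPS:
                rules.append(r)

        # approximate rules: maximal violator sets, capped at max_lhs
        candidates: set[frozenset[str]] = set()
        maximal_fam = [s for s in fam
                       if not any(s < o for o in fam)]
        for s in maximal_fam:
            if not s:
                continue
            if len(s) <= cfg.max_lhs:
                candidates.add(s)
            else:
                candidates.update(frozenset(c) for c in
                                  itertools.combinations(sorted(s),
                                                         cfg.max_lhs))
        candidates = {c for c in candidates
                      if not any(c < o for o in candidates)}
        for X in candidates:
            r = measure_rule(m, X, y)
            if (r.support >= cfg.min_support - _EPS
                    and r.confidence >= cfg.min_confidence - _EPS
                    and not r.exact):
                rules.append(r)

    if central is not None:
        rules = [r for r in rules if (r.lhs | {r.rhs}) & central]
    rules.sort(key=lambda r: r.sort_key)
    return RuleSet(rules, cfg, query_id, m.N)


def discover(m: SatisfactionMatrix, cfg: DiscoveryConfig | None = None,
             central: Optional[frozenset[str]] = None,
             query_id: str = "") -> RuleSet:
    """Dispatch on ``cfg.mode``."""
    cfg = cfg or DiscoveryConfig()
    if cfg.mode == "n_to_one":
        return discover_n1(m, cfg, central, query_id)
    return discover_11(m, cfg, central, query_id)


def filter_central(rs: RuleSet, central: frozenset[str]) -> RuleSet:
    """Keep only rules touching at least one central attribute."""
    if not central:
        raise ValueError("central attribute set must be non-empty")
    kept = [r for r in rs.rules if (r.lhs | {r.rhs}) & central]
    return RuleSet(kept, rs.config, rs.query_id, rs.N)


def _check_central(m: SatisfactionMatrix, central: frozenset[str]) -> None:
    missing = sorted(c for c in central if c not in m.column_names)
    if missing:
        raise BindingError(
            f"central attributes not in satisfaction matrix: {missing}")
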