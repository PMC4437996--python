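"""Benchmark-style scoring of inferred interactions.

The protocol mirrors community network-inference challenges: each method
submits a ranked list of regulator→target interactions; the list is scored
against a gold standard of experimentally supported positives (and known
negatives) with the areas under the precision-recall (AUPR) and receiver
operating characteristic (AUROC) curves, computed only over interactions
present in the gold standard.  Scores from several networks are summarised
by geometric means, and the overall score is the arithmetic mean of the
overall AUPR and AUROC.

Rules map to interactions through their underlying attributes: the rule
``TF1_ko → G7_low`` predicts the interaction (TF1, G7).  Interactions are
ranked by descending leverage, then descending confidence.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import UndefinedMeasureError
from .rules import RuleSet

DEFAULT_MAX_LEN = 100_000


@dataclass
class RankedList:
    """Ordered regulator→target predictions (best first)."""
    interactions: list[tuple[str, str]]
    scores: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)  # (leverage, confidence) keys used for ranking
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self):
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError("duplicate interactions in ranked list")
        if len(self.interactions) > self.max_len:
            self.interactions = self.interactions[: self.max_len]

    def rank_of(self) -> dict[tuple[str, str], int]:
        """1-based rank per interaction."""
        return {pair: i + 1 for i, pair in enumerate(self.interactions)}

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["regulator", "target", "rank"])
            for i, (reg, tgt) in enumerate(self.interactions, start=1):
                w.writerow([reg, tgt, i])


@dataclass
class GoldStandard:
    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"gold standard labels overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_tsv(cls, path) -> "GoldStandard":
        """TSV with columns regulator, target, label (1 positive / 0 negative)."""
        pos, neg = set(), set()
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            for reg, tgt, label in reader:
                (pos if label.strip() == "1" else neg).add((reg, tgt))
        return cls(frozenset(pos), frozenset(neg))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["regulator", "target", "label"])
            for reg, tgt in sorted(self.positives):
                w.writerow([reg, tgt, 1])
            for reg, tgt in sorted(self.negatives):
                w.writerow([reg, tgt, 0])


@dataclass(frozen=True)
class EvalScores:
    aupr: float
    auroc: float


def _underlying(name: str) -> str:
    return name.rsplit("_", 1)[0] if "_" in name else name


def rank_interactions(rs: RuleSet, max_len: int = DEFAULT_MAX_LEN,
                      strip_labels: bool = True) -> RankedList:
    """Rank a rule set's interactions by (leverage ↓, confidence ↓).

    n–1 rules are star-expanded (one interaction per LHS member).  When the
    same interaction arises from several rules (e.g. the high and low
    labels of one attribute pair) the best-ranked occurrence wins.  Fully
    tied rules fall back to lexicographic (regulator, target) order, so the
    ranking is deterministic.
    """
    entries = []
    for rule in rs.rules:
        for src in rule.lhs:
            reg = _underlying(src) if strip_labels else src
            tgt = _underlying(rule.rhs) if strip_labels else rule.rhs
            if reg == tgt:
                continue
            entries.append((-rule.leverage, -rule.confidence, reg, tgt))
    entries.sort()
    seen, ordered, scores = set(), [], {}
    for neglev, negconf, reg, tgt in entries:
        if (reg, tgt) in seen:
            continue
        seen.add((reg, tgt))
        ordered.append((reg, tgt))
        scores[(reg, tgt)] = (-neglev, -negconf)
    return RankedList(ordered[:max_len], scores, max_len)


def combine_best_rank(lists: Sequence[RankedList],
                      max_len: int = DEFAULT_MAX_LEN) -> RankedList:
    """Merge ranked lists by keeping each interaction's best rank.

    An interaction absent from a list counts as ranked worse than anything
    present in it.  Re-sorted by best rank; ties break on the better
    secondary rank, then lexicographically.
    """
    if len(lists) < 1:
        raise ValueError("need at least one ranked list")
    inf = math.inf
    pairs: set[tuple[str, str]] = set()
    rank_maps = []
    for lst in lists:
        rm = lst.rank_of()
        rank_maps.append(rm)
        pairs.update(rm)
    keyed = []
    for pair in pairs:
        ranks = sorted(rm.get(pair, inf) for rm in rank_maps)
        best = ranks[0]
        second = ranks[1] if len(ranks) > 1 else inf
        keyed.append((best, second, pair[0], pair[1]))
    keyed.sort()
    ordered = [(reg, tgt) for _, _, reg, tgt in keyed]
    return RankedList(ordered[:max_len], {}, max_len)


def pr_roc(ranked: RankedList, gold: GoldStandard) -> EvalScores:
    """AUPR and AUROC of a ranked list against a gold standard.

    Interactions absent from the gold standard are dropped before the
    sweep.  Positives never retrieved count as misses: the recall
    denominator is the full positive set, so AUPR is integrated over the
    achieved recall range only, and the ROC curve is completed from the
    last swept point to (1, 1) — equivalent to a random ordering of
    everything not retrieved.
    """
    n_pos, n_neg = len(gold.positives), len(gold.negatives)
    if n_pos == 0:
        raise UndefinedMeasureError("gold standard has no positives")
    if n_neg == 0:
        raise UndefinedMeasureError("gold standard has no negatives")
    labels = [pair in gold.positives for pair in ranked.interactions
              if pair in gold.positives or pair in gold.negatives]

    tp = fp = 0
    roc_pts = [(0.0, 0.0)]
    pr_pts = []
    for is_pos in labels:
        tp += is_pos
        fp += not is_pos
        roc_pts.append((fp / n_neg, tp / n_pos))
        pr_pts.append((tp / n_pos, tp / (tp + fp)))
    roc_pts.append((1.0, 1.0))  # random tail over unretrieved items

    auroc = _trapezoid(roc_pts)
    if pr_pts:
        first_prec = pr_pts[0][1]
        aupr = _trapezoid([(0.0, first_prec)] + pr_pts)
    else:
        aupr = 0.0
    return EvalScores(aupr=aupr, auroc=auroc)


def _trapezoid(points: list[tuple[float, float]]) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def overall_scores(per_network: Sequence[EvalScores]
                   ) -> tuple[float, float, float]:
    """Geometric means of AUPR and AUROC across networks; overall score =
    arithmetic mean of the two.  Any zero metric zeroes its geometric mean."""
    if not per_network:
        raise ValueError("need at least one network's scores")
    k = len(per_network)
    g_aupr = math.prod(s.aupr for s in per_network) ** (1.0 / k)
    g_auroc = math.prod(s.auroc for s in per_network) ** (1.0 / k)
    return g_aupr, g_auroc, (g_aupr + g_auroc) / 2.0


# ---------------------------------------------------------------------------
# Benchmark query templates (reconstructions; editable copies live in
# examples/queries/)
# ---------------------------------------------------------------------------

def qd1_text(expression_ds: str, threshold: float = 1.0) -> str:
    """High/low co-expression semantics over a scaled expression table:
    rules between strongly over- and under-expressed genes."""
    t = repr(float(threshold))
    return (f"FINDRULES SCOPE t1 IN ({expression_ds}) "
            f"HAVING high: t1.$a >= {t} OVER * "
            f"AND low: t1.$a <= -{t} OVER *;")


def qd2_text(expression_ds: str, ko_attrs: Sequence[str],
             target_attrs: Sequence[str], threshold: float = 2.0,
             annotation_ds: str = "ann") -> str:
    """Knockout semantics: rules from a binary "this TF is deleted here"
    annotation to strong target-expression responses (cross-table,
    sample-id aligned).  Attribute lists are dataset-qualified because TF
    names may appear in both tables (deletion flag vs own expression)."""
    t = repr(float(threshold))
    ko = ", ".join(f"{annotation_ds}.{a}" for a in ko_attrs)
    tg = ", ".join(f"{expression_ds}.{a}" for a in target_attrs)
    return (f"FINDRULES SCOPE t1 IN ({expression_ds}) "
            f"HAVING ko: t1.$a = 1 OVER {ko} "
            f"AND down: t1.$a <= -{t} OVER {tg} "
            f"AND up: t1.$a >= {t} OVER {tg};")
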