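import numpy as np
import pytest

from rqlnet import evaluation as E
from rqlnet.errors import UndefinedMeasureError
from rqlnet.rules import DiscoveryConfig, Rule, RuleSet


def rule(lhs, rhs, lev, conf):
    return Rule(frozenset(lhs), rhs, support=0.2, confidence=conf,
                lift=1.5, leverage=lev, exact=conf == 1.0)


def rl(pairs):
    return E.RankedList(list(pairs))


def gold(pos, neg):
    return E.GoldStandard(frozenset(pos), frozenset(neg))


class TestRankInteractions:
    def test_leverage_is_primary_key(self):
        rs = RuleSet([rule(["A_h"], "B_h", 0.1, 1.0),
                      rule(["C_h"], "D_h", 0.2, 0.9)],
                     DiscoveryConfig(), "q", 10)
        ranked = E.rank_interactions(rs)
        assert ranked.interactions == [("C", "D"), ("A", "B")]

    def test_confidence_breaks_leverage_ties(self):
        rs = RuleSet([rule(["A_h"], "B_h", 0.2, 0.95),
                      rule(["C_h"], "D_h", 0.2, 1.0)],
                     DiscoveryConfig(), "q", 10)
        assert E.rank_interactions(rs).interactions == \
            [("C", "D"), ("A", "B")]

    def test_full_ties_fall_back_to_lexicographic(self):
        rs = RuleSet([rule(["Z_h"], "Y_h", 0.2, 1.0),
                      rule(["A_h"], "B_h", 0.2, 1.0)],
                     DiscoveryConfig(), "q", 10)
        assert E.rank_interactions(rs).interactions == \
            [("A", "B"), ("Z", "Y")]

    def test_duplicate_interactions_keep_best_rank(self):
        rs = RuleSet([rule(["A_high"], "B_high", 0.3, 1.0),
                      rule(["A_low"], "B_low", 0.1, 0.9)],
                     DiscoveryConfig(), "q", 10)
        ranked = E.rank_interactions(rs)
        assert ranked.interactions == [("A", "B")]
        assert ranked.scores[("A", "B")] == (0.3, 1.0)

    def test_star_expansion_and_truncation(self):
        rs = RuleSet([rule(["A_h", "B_h"], "C_h", 0.2, 1.0)],
                     DiscoveryConfig(max_lhs=2, mode="n_to_one"), "q", 10)
        assert len(E.rank_interactions(rs).interactions) == 2
        assert len(E.rank_interactions(rs, max_len=1).interactions) == 1


class TestCombineBestRank:
    def test_minimum_rank_wins(self):
        combined = E.combine_best_rank([
            rl([("x", "a"), ("x", "b"), ("x", "c"), ("x", "d"), ("r", "t")]),
            rl([("q", "z"), ("r", "t")]),
        ])
        # (r,t): best rank 2; (x,a) and (q,z): best rank 1
        ranks = {p: i + 1 for i, p in enumerate(combined.interactions)}
        assert ranks[("r", "t")] == 3

    def test_single_source_interaction_keeps_rank(self):
        combined = E.combine_best_rank([rl([("a", "b")]), rl([])])
        assert combined.interactions == [("a", "b")]

    def test_secondary_rank_breaks_ties(self):
        l1 = rl([("a", "a"), ("b", "b"), ("z", "z")])
        l2 = rl([("p", "p"), ("q", "q"), ("b", "b")])
        combined = E.combine_best_rank([l1, l2])
        pos = {p: i for i, p in enumerate(combined.interactions)}
        # (a,a) and (p,p) both best-rank 1 with secondary ∞ → lexicographic;
        # (b,b) best 2, secondary 3 beats (q,q) best 2, secondary ∞
        assert pos[("a", "a")] < pos[("p", "p")]
        assert pos[("b", "b")] < pos[("q", "q")]

    def test_idempotent_on_duplicates(self):
        lst = rl([("a", "b"), ("c", "d"), ("e", "f")])
        assert E.combine_best_rank([lst, lst]).interactions == \
            lst.interactions


class TestPrRoc:
    def test_perfect_ranking(self):
        g = gold({("a", "b"), ("c", "d")}, {("e", "f"), ("g", "h")})
        s = E.pr_roc(rl([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]), g)
        assert s.auroc == 1.0
        assert s.aupr == 1.0

    def test_inverted_ranking(self):
        g = gold({("a", "b")}, {("e", "f")})
        s = E.pr_roc(rl([("e", "f"), ("a", "b")]), g)
        assert s.auroc == 0.0

    def test_two_item_enumeration(self):
        g = gold({("a", "b")}, {("e", "f")})
        s = E.pr_roc(rl([("a", "b"), ("e", "f")]), g)
        assert s.aupr == 1.0 and s.auroc == 1.0

    def test_invariant_to_unscored_interactions(self):
        g = gold({("a", "b")}, {("e", "f")})
        with_extra = rl([("zz", "zz"), ("a", "b"), ("yy", "yy"), ("e", "f")])
        plain = rl([("a", "b"), ("e", "f")])
        assert E.pr_roc(with_extra, g) == E.pr_roc(plain, g)

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(0)
        pos = {(f"p{i}", "t") for i in range(50)}
        neg = {(f"n{i}", "t") for i in range(50)}
        g = gold(pos, neg)
        aurocs = []
        for _ in range(30):
            order = list(pos | neg)
            rng.shuffle(order)
            aurocs.append(E.pr_roc(rl(order), g).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_matches_sklearn_on_scored_lists(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        for _ in range(10):
            pairs = [(f"r{i}", "t") for i in range(40)]
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            order = list(rng.permutation(40))
            ranked = rl([pairs[i] for i in order])
            g = gold({p for p, l in zip(pairs, labels) if l},
                     {p for p, l in zip(pairs, labels) if not l})
            # score = −rank reproduces the ranked sweep exactly
            scores = {pairs[i]: -r for r, i in enumerate(order)}
            skl = roc_auc_score([p in g.positives for p in pairs],
                                [scores[p] for p in pairs])
            assert E.pr_roc(ranked, g).auroc == pytest.approx(skl, abs=1e-12)

    def test_missing_positives_lower_both_areas(self):
        g = gold({("a", "b"), ("c", "d")}, {("e", "f")})
        s = E.pr_roc(rl([("a", "b"), ("e", "f")]), g)  # (c,d) never retrieved
        assert s.auroc < 1.0
        assert s.aupr < 1.0

    def test_empty_gold_classes_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            E.pr_roc(rl([("a", "b")]), gold(set(), {("e", "f")}))
        with pytest.raises(UndefinedMeasureError):
            E.pr_roc(rl([("a", "b")]), gold({("a", "b")}, set()))


class TestOverallScores:
    def test_constant_inputs(self):
        s = [E.EvalScores(0.5, 0.5)] * 3
        assert E.overall_scores(s) == (0.5, 0.5, 0.5)

    def test_geometric_mean(self):
        s = [E.EvalScores(0.25, 1.0), E.EvalScores(1.0, 1.0)]
        g_aupr, g_auroc, overall = E.overall_scores(s)
        assert g_aupr == pytest.approx(0.5)
        assert overall == pytest.approx(0.75)

    def test_single_network_degenerates_to_mean(self):
        g_aupr, g_auroc, overall = E.overall_scores([E.EvalScores(0.3, 0.7)])
        assert overall == pytest.approx(0.5)

    def test_zero_metric_zeroes_geometric_mean(self):
        s = [E.EvalScores(0.0, 0.5), E.EvalScores(0.8, 0.5)]
        assert E.overall_scores(s)[0] == 0.0


class TestGoldStandardIO:
    def test_tsv_roundtrip(self, tmp_path):
        g = gold({("a", "b")}, {("c", "d"), ("e", "f")})
        p = tmp_path / "gold.tsv"
        g.to_tsv(p)
        back = E.GoldStandard.from_tsv(p)
        assert back == g

    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError):
            gold({("a", "b")}, {("a", "b")})
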