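import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rqlnet import rules as R
from rqlnet.engine import SatisfactionMatrix
from rqlnet.errors import BindingError, UndefinedMeasureError

from oracles import brute_rules_11, brute_transversals
from conftest import random_bool_matrix


class TestMeasures:
    def test_hand_counted_fractions(self, ac_matrix):
        m = ac_matrix
        assert R.support(m, {"A"}, "C") == pytest.approx(2 / 6, abs=0)
        assert R.support(m, set(), "C") == pytest.approx(2 / 6, abs=0)
        assert R.confidence(m, {"A"}, "C") == pytest.approx(2 / 3, abs=0)
        assert R.lift(m, {"A"}, "C") == pytest.approx(2.0, abs=0)
        assert R.leverage(m, {"A"}, "C") == pytest.approx(1 / 6, abs=1e-15)

    def test_independent_pair(self, indep_matrix):
        assert R.lift(indep_matrix, {"X"}, "Y") == 1.0
        assert R.leverage(indep_matrix, {"X"}, "Y") == 0.0

    def test_degenerate_cases(self):
        m = SatisfactionMatrix.from_columns(
            {"A": [1, 1, 0], "Z": [0, 0, 0], "N": [0, 0, 0]})
        assert R.support(m, {"A"}, "Z") == 0.0
        assert R.confidence(m, {"A"}, "A") == 1.0
        with pytest.raises(UndefinedMeasureError):
            R.confidence(m, {"Z"}, "A")
        with pytest.raises(KeyError):
            R.support(m, {"A"}, "nope")

    def test_self_dependence_lift(self):
        m = SatisfactionMatrix.from_columns({"A": [1, 1, 0, 0, 0],
                                             "B": [1, 1, 0, 0, 0]})
        assert R.lift(m, {"A"}, "B") == pytest.approx(5 / 2, abs=0)
        assert R.leverage(m, {"A"}, "B") == \
            pytest.approx(2 / 5 - (2 / 5) ** 2, abs=1e-15)


class TestDiscover11:
    def test_identical_columns_give_reciprocal_exact_rules(self):
        m = SatisfactionMatrix.from_columns({"A": [1, 0, 1, 0],
                                             "B": [1, 0, 1, 0]})
        rs = R.discover_11(m, R.DiscoveryConfig(min_support=0.1,
                                                min_confidence=0.9))
        got = {(tuple(sorted(r.lhs)), r.rhs, r.exact) for r in rs}
        assert got == {(("A",), "B", True), (("B",), "A", True)}

    def test_independent_columns_below_confidence(self, indep_matrix):
        rs = R.discover_11(indep_matrix,
                           R.DiscoveryConfig(min_confidence=0.9))
        assert len(rs) == 0

    def test_sibling_labels_never_pair(self):
        m = SatisfactionMatrix.from_columns({"G1_high": [1, 0, 1],
                                             "G1_low": [0, 1, 0]})
        rs = R.discover_11(m, R.DiscoveryConfig(min_support=0.0,
                                                min_confidence=0.0))
        assert len(rs) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        m = random_bool_matrix(rng)
        keys = {}
        for conf in (0.0, 0.5, 0.9, 1.0):
            rs = R.discover_11(m, R.DiscoveryConfig(min_support=0.1,
                                                    min_confidence=conf))
            keys[conf] = {(r.lhs, r.rhs) for r in rs}
        assert keys[1.0] <= keys[0.9] <= keys[0.5] <= keys[0.0]

    def test_measure_identities_on_emitted_rules(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m = random_bool_matrix(rng, p_missing=0.1)
            rs = R.discover_11(m, R.DiscoveryConfig(min_support=0.0,
                                                    min_confidence=0.0))
            for r in rs:
                assert 0 <= r.support <= r.confidence <= 1
                denom = _pairwise_support(m, r.lhs, r.rhs)
                assert r.confidence == pytest.approx(
                    R.support(m, r.lhs, r.rhs) / denom, abs=1e-12)
                assert r.exact == (abs(r.confidence - 1) <= 1e-12)

    def test_matches_brute_force_with_missing_cells(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = random_bool_matrix(rng, max_cols=6, max_units=10,
                                   p_missing=0.15)
            rs = R.discover_11(m, R.DiscoveryConfig(min_support=0.1,
                                                    min_confidence=0.7))
            got = {(r.lhs, r.rhs): (r.support, r.confidence) for r in rs}
            want = brute_rules_11(m, 0.1, 0.7)
            assert got.keys() == want.keys()
            for k in got:
                assert got[k] == pytest.approx(want[k], abs=1e-12)


def _pairwise_support(m, X, y):
    """support of X over units complete on X∪{y} (the rule's denominator)."""
    import numpy as np
    from rqlnet.engine import MISSING
    cols = [m.column_index(c) for c in set(X) | {y}]
    xcols = [m.column_index(c) for c in X]
    complete = (m.data[:, cols] != MISSING).all(axis=1)
    return ((m.data[:, xcols] == 1).all(axis=1) & complete).sum() \
        / complete.sum()


class TestViolatorFamilies:
    def test_read_off_true_sets(self):
        m = SatisfactionMatrix.from_columns({
            "A": [1, 0, 1], "B": [1, 1, 1], "C": [0, 1, 1],
            "Y": [0, 0, 1]})
        fam = R.violator_families(m, "Y")
        assert fam == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_no_violators_when_always_true(self):
        m = SatisfactionMatrix.from_columns({"A": [1, 0], "Y": [1, 1]})
        assert R.violator_families(m, "Y") == set()

    def test_duplicate_units_collapse(self):
        m = SatisfactionMatrix.from_columns({
            "A": [1, 1, 0], "Y": [0, 0, 1]})
        assert R.violator_families(m, "Y") == {frozenset({"A"})}

    def test_siblings_excluded_from_sets(self):
        m = SatisfactionMatrix.from_columns({
            "Y_high": [0, 1], "Y_low": [1, 0], "A": [1, 0]})
        assert R.violator_families(m, "Y_high") == {frozenset({"A"})}


class TestMinimalTransversals:
    @pytest.mark.parametrize("family,expected", [
        ([{"C"}, {"A"}], [{"A", "C"}]),
        ([{"a", "b"}, {"b", "c"}], [{"b"}, {"a", "c"}]),
        ([], [set()]),
        ([set()], []),
        ([{"a"}, set(), {"b"}], []),
    ])
    def test_known_families(self, family, expected):
        got = R.minimal_transversals(family)
        assert got == sorted((frozenset(e) for e in expected),
                             key=lambda s: (len(s), tuple(sorted(s))))

    @given(st.lists(st.sets(st.sampled_from("abcdef"), max_size=6),
                    max_size=6),
           st.integers(min_value=1, max_value=6))
    @settings(max_examples=150, deadline=None)
    def test_equals_brute_force_and_respects_cap(self, family, cap):
        full = R.minimal_transversals(family)
        assert full == brute_transversals(family)
        capped = R.minimal_transversals(family, max_size=cap)
        assert capped == [t for t in full if len(t) <= cap]

    def test_outputs_are_minimal_hitting_sets(self):
        fam = [{"a", "b"}, {"c", "d"}, {"a", "d"}, {"b", "c", "e"}]
        for t in R.minimal_transversals(fam):
            assert all(t & e for e in fam)
            for v in t:
                assert not all((t - {v}) & e for e in fam)


class TestDiscoverN1:
    CFG = R.DiscoveryConfig(min_support=0.0, min_confidence=0.5,
                            max_lhs=3, mode="n_to_one")

    @pytest.fixture
    def abcd(self):
        return SatisfactionMatrix.from_columns({
            "A": [1, 0, 1, 1], "B": [1, 1, 1, 0],
            "C": [0, 1, 1, 1], "D": [0, 0, 1, 1]})

    def test_smallest_exact_lhs_for_d(self, abcd):
        rs = R.discover_n1(abcd, self.CFG)
        exact_d = {r.lhs for r in rs if r.rhs == "D" and r.exact}
        assert exact_d == {frozenset({"A", "C"})}

    def test_maximal_approximate_lhs_for_d(self, abcd):
        rs = R.discover_n1(abcd, self.CFG)
        approx_d = {r.lhs for r in rs if r.rhs == "D" and not r.exact}
        assert approx_d == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_tautological_consequent_gives_empty_lhs(self):
        m = SatisfactionMatrix.from_columns({"A": [1, 0], "Y": [1, 1]})
        rs = R.discover_n1(m, self.CFG)
        empty = [r for r in rs if r.rhs == "Y" and not r.lhs]
        assert len(empty) == 1
        assert empty[0].exact
        assert empty[0].support == 1.0

    def test_cover_properties_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            m = random_bool_matrix(rng, max_cols=7, max_units=10)
            rs = R.discover_n1(m, R.DiscoveryConfig(
                min_support=0.0, min_confidence=0.6, max_lhs=3,
                mode="n_to_one"))
            by_rhs = {}
            for r in rs:
                by_rhs.setdefault(r.rhs, []).append(r)
            for y, lst in by_rhs.items():
                exact = {r.lhs for r in lst if r.exact}
                for r in lst:
                    if r.exact:
                        assert r.confidence == 1.0
                        # no proper exact subset was also emitted
                        assert not any(o < r.lhs for o in exact)
                    else:
                        assert r.confidence < 1


class TestFilterCentral:
    def make_ruleset(self):
        m = SatisfactionMatrix.from_columns({
            "A": [1, 1, 0], "B": [1, 1, 0], "N_def": [1, 1, 0],
            "C": [1, 1, 1]})
        return m, R.discover_11(m, R.DiscoveryConfig(min_support=0.0,
                                                     min_confidence=1.0))

    def test_keeps_rules_touching_central(self):
        _, rs = self.make_ruleset()
        kept = R.filter_central(rs, frozenset({"N_def"}))
        assert all("N_def" in (r.lhs | {r.rhs}) for r in kept)
        assert len(kept) > 0

    def test_all_central_is_identity(self):
        m, rs = self.make_ruleset()
        kept = R.filter_central(rs, frozenset(m.column_names))
        assert [(r.lhs, r.rhs) for r in kept] == \
            [(r.lhs, r.rhs) for r in rs]

    def test_pushed_down_matches_post_filter(self):
        m, rs = self.make_ruleset()
        cfg = R.DiscoveryConfig(min_support=0.0, min_confidence=1.0)
        pushed = R.discover_11(m, cfg, central=frozenset({"N_def"}))
        post = R.filter_central(rs, frozenset({"N_def"}))
        assert {(r.lhs, r.rhs) for r in pushed} == \
            {(r.lhs, r.rhs) for r in post}

    def test_unknown_central_attribute(self):
        m, _ = self.make_ruleset()
        with pytest.raises(BindingError):
            R.discover_11(m, central=frozenset({"missing"}))
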