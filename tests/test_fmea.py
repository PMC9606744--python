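"""FMEA scoring: fuzzy factor means, FRPN, traditional RPN, ranking, votes."""

import itertools

import pytest

from fmea_triz.fmea import (
    Factor,
    RatingPanel,
    RatingRecord,
    RiskScore,
    VoteTally,
    compare_rankings,
    compute_frpn,
    compute_fuzzy_factor_means,
    compute_traditional_rpn,
    expert_vote_summary,
    rank_failures,
)
from fmea_triz.fuzzy import DefuzzMethod, defuzzify, fuzzify, round_half_up


def make_panel(cells):
    """cells: {(fid, factor): [scores]} -> RatingPanel."""
    records = []
    for (fid, fac), scores in cells.items():
        for t, s in enumerate(scores, 1):
            records.append(RatingRecord(f"r{t}", fid, fac, s))
    return RatingPanel(records)


class TestFactorMeans:
    def test_constant_panel(self, scale):
        panel = make_panel({("F1", Factor.S): [5] * 35})
        means = compute_fuzzy_factor_means(panel, scale)
        assert means[("F1", Factor.S)].as_tuple() == (0.75, 1, 1)

    def test_fitted_count_vector_reproduces_printed_means(self, scale):
        scores = [s for s, k in zip(range(1, 6), (0, 3, 8, 20, 4)) for _ in range(k)]
        panel = make_panel({("F1", Factor.S): scores})
        got = compute_fuzzy_factor_means(panel, scale)[("F1", Factor.S)]
        assert round_half_up(got.q) == 0.429
        assert round_half_up(got.o) == 0.679
        assert round_half_up(got.p) == 0.900

    def test_missing_cell_for_registered_failure(self, scale, register):
        panel = make_panel({("F1", Factor.S): [3]})
        with pytest.raises(ValueError, match=r"\(F1, O\)"):
            compute_fuzzy_factor_means(panel, scale, failures=register[:1])

    def test_duplicate_rating_rejected(self):
        with pytest.raises(ValueError, match="duplicate rating record"):
            RatingPanel([RatingRecord("r1", "F1", Factor.S, 3),
                         RatingRecord("r1", "F1", Factor.S, 4)])


class TestFRPN:
    @pytest.mark.parametrize("sod,expected", [
        ((0.669, 0.657, 0.667), 0.293),
        ((0.610, 0.607, 0.633), 0.234),
        ((1, 1, 1), 1.0),
    ])
    def test_triple_product(self, sod, expected):
        assert round_half_up(compute_frpn(*sod)) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            compute_frpn(1.2, 0.5, 0.5)

    def test_strictly_increasing_in_each_factor(self):
        base = compute_frpn(0.5, 0.6, 0.7)
        assert compute_frpn(0.6, 0.6, 0.7) > base
        assert compute_frpn(0.5, 0.7, 0.7) > base
        assert compute_frpn(0.5, 0.6, 0.8) > base


class TestTraditionalRPN:
    def test_unanimous_extremes(self):
        all5 = make_panel({("F1", f): [5, 5] for f in Factor})
        all1 = make_panel({("F1", f): [1, 1] for f in Factor})
        assert compute_traditional_rpn(all5)["F1"] == 125
        assert compute_traditional_rpn(all1)["F1"] == 1

    def test_two_rater_hand_computation(self):
        # (S,O,D) = (3,4,5) and (5,4,3): factor means all 4 -> 64
        panel = make_panel({
            ("F1", Factor.S): [3, 5],
            ("F1", Factor.O): [4, 4],
            ("F1", Factor.D): [5, 3],
        })
        assert compute_traditional_rpn(panel)["F1"] == pytest.approx(64)


class TestRanking:
    def test_printed_frpn_values_rank_as_printed(self):
        frpns = {"F1": 0.293, "F2": 0.228, "F3": 0.188,
                 "F4": 0.207, "F5": 0.173, "F6": 0.234}
        scores = [RiskScore(fid, 0.5, 0.5, 0.5, v) for fid, v in frpns.items()]
        ranked = {s.failure_id: s.rank for s in rank_failures(scores)}
        assert ranked == {"F1": 1, "F6": 2, "F2": 3, "F4": 4, "F3": 5, "F5": 6}

    def test_single_failure(self):
        [s] = rank_failures([RiskScore("F1", 0.5, 0.5, 0.5, 0.125)])
        assert s.rank == 1

    def test_tie_breaks_by_ascending_id(self):
        scores = [RiskScore("F2", 0.5, 0.5, 0.5, 0.2),
                  RiskScore("F1", 0.5, 0.5, 0.5, 0.2)]
        ranked = {s.failure_id: s.rank for s in rank_failures(scores)}
        assert ranked == {"F1": 1, "F2": 2}

    def test_duplicate_ids_rejected(self):
        scores = [RiskScore("F1", 0.5, 0.5, 0.5, 0.2)] * 2
        with pytest.raises(ValueError, match="duplicate failure ids"):
            rank_failures(scores)

    def test_ranks_are_permutation(self):
        import random

        rnd = random.Random(7)
        scores = [RiskScore(f"F{i}", 0.5, 0.5, 0.5, rnd.random()) for i in range(12)]
        ranked = rank_failures(scores)
        assert sorted(s.rank for s in ranked) == list(range(1, 13))


class TestCompareRankings:
    def test_case_fuzzy_vs_traditional_printed_ranks(self):
        fuzzy = {"F1": 1, "F2": 3, "F3": 5, "F4": 4, "F5": 6, "F6": 2}
        trad = {"F1": 1, "F2": 3, "F3": 6, "F4": 4, "F5": 5, "F6": 2}
        cmp = compare_rankings(fuzzy, trad)
        assert cmp.disagreements == ("F3", "F5")
        assert cmp.kendall_tau == pytest.approx(13 / 15)

    def test_identical_rankings(self):
        r = {"A": 1, "B": 2, "C": 3}
        cmp = compare_rankings(r, dict(r))
        assert cmp.kendall_tau == 1 and cmp.spearman_rho == 1
        assert cmp.disagreements == ()

    def test_reversed_three_item_ranking(self):
        cmp = compare_rankings({"A": 1, "B": 2, "C": 3}, {"A": 3, "B": 2, "C": 1})
        assert cmp.kendall_tau == pytest.approx(-1)

    def test_mismatched_id_sets_rejected(self):
        with pytest.raises(ValueError, match="different failure sets"):
            compare_rankings({"A": 1}, {"B": 1})


class TestExpertVotes:
    def test_ten_of_thirteen(self):
        pct = expert_vote_summary(VoteTally({"traditional": 3, "fuzzy": 10}))
        assert pct == {"traditional": 23.07, "fuzzy": 76.93}
        assert sum(pct.values()) == pytest.approx(100)

    def test_zero_votes_for_an_option(self):
        pct = expert_vote_summary(VoteTally({"a": 0, "b": 7}))
        assert pct == {"a": 0.0, "b": 100.0}

    def test_zero_experts_rejected(self):
        with pytest.raises(ValueError, match="zero experts"):
            expert_vote_summary(VoteTally({"a": 0}))


class TestFuzzyVsTraditionalOrder:
    """How the two risk keys relate on per-cell-unanimous panels.

    On componentwise-dominated score triples the two keys always agree
    (both are products of increasing per-factor maps).  Across arbitrary
    triples they can legitimately disagree -- the fuzzy scale compresses
    the top scores -- e.g. (5,4,1) vs (3,3,2).
    """

    @staticmethod
    def keys(triple, scale):
        trad = triple[0] * triple[1] * triple[2]
        fuzzy = 1.0
        for s in triple:
            fuzzy *= defuzzify(fuzzify(s, scale), DefuzzMethod.CENTROID)
        return trad, fuzzy

    def test_dominated_pairs_always_agree(self, scale):
        # brute-force oracle over every componentwise-ordered pair of the
        # 125 unanimous triples
        triples = list(itertools.product(range(1, 6), repeat=3))
        checked = 0
        for a, b in itertools.combinations(triples, 2):
            if not (all(x >= y for x, y in zip(a, b))
                    or all(x <= y for x, y in zip(a, b))):
                continue
            ta, fa = self.keys(a, scale)
            tb, fb = self.keys(b, scale)
            assert (ta - tb) * (fa - fb) >= 0, (a, b)
            checked += 1
        assert checked > 1000

    def test_non_dominated_counterexample(self, scale):
        # traditional prefers (5,4,1); fuzzy prefers (3,3,2)
        t_a, f_a = self.keys((5, 4, 1), scale)
        t_b, f_b = self.keys((3, 3, 2), scale)
        assert t_a > t_b and f_a < f_b
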