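"""Fine-grained classifier-engine operations: matching, covering, prediction,
action choice, reinforcement updates, generality and the rule file format."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rbnxcs as rx
from rbnxcs import xcs as X
from rbnxcs import _kernels as K


def ternary(n):
    return st.text(alphabet="01#", min_size=n, max_size=n)


def bitstring(n):
    return st.text(alphabet="01", min_size=n, max_size=n)


class TestMatching:
    @pytest.mark.parametrize(
        "cond,state,expected",
        [
            ("0101110101", "0101110101", True),  # direct match
            ("1111##0001", "1111000001", True),  # indirect match through #
            ("1###", "0111", False),
            ("####", "1010", True),
        ],
    )
    def test_examples(self, cond, state, expected):
        assert rx.matches(cond, state) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rx.matches("01#", "0101")

    @given(ternary(6), bitstring(6))
    def test_agrees_with_mask_encoding(self, cond, state):
        mask, val = X.condition_to_masks(cond)
        assert rx.matches(cond, state) == (
            (rx.state_to_int(state) & mask) == val
        )

    @given(ternary(7))
    def test_condition_mask_round_trip(self, cond):
        mask, val = X.condition_to_masks(cond)
        assert X.masks_to_condition(mask, val, 7) == cond


class TestCovering:
    def test_zero_hash_probability_copies_state(self, default_params):
        cl = rx.cover("01011", set(), default_params.replace(p_hash=0.0), rx.Rng(1))
        assert cl.condition == "01011"

    def test_certain_hash_probability_all_wildcards(self, default_params):
        cl = rx.cover("01011", set(), default_params.replace(p_hash=1.0), rx.Rng(1))
        assert cl.condition == "#####"

    def test_initial_statistics_are_the_configured_defaults(self, default_params):
        cl = rx.cover("01011", set(), default_params, rx.Rng(5))
        assert (cl.prediction, cl.error, cl.fitness) == (7.4, 1.0, 0.03)
        assert (cl.numerosity, cl.experience) == (1, 0)

    def test_action_drawn_from_absent_actions(self, default_params):
        for seed in range(20):
            cl = rx.cover("01011", {0, 2, 3, 5}, default_params, rx.Rng(seed))
            assert cl.action in {1, 4}

    def test_exhausted_actions_rejected(self, default_params):
        with pytest.raises(ValueError):
            rx.cover("01", {0, 1, 2}, default_params, rx.Rng(0))

    def test_covering_fills_distinct_actions(self, default_params):
        pop = rx.Population.for_params(default_params, 5)
        mset = rx.build_match_set(pop, "10101", default_params, rx.Rng(3))
        actions = {c.action for c in mset.classifiers(pop)}
        assert len(actions) >= default_params.theta_mna
        assert all(rx.matches(c.condition, "10101") for c in mset.classifiers(pop))

    def test_no_covering_when_all_actions_present(self, default_params):
        pop = rx.Population(5, 100)
        for a in range(6):
            pop.add(rx.Classifier("#####", a))
        before = len(pop)
        mset = rx.build_match_set(pop, "00000", default_params, rx.Rng(0))
        assert len(pop) == before and len(mset) == 6

    def test_theta_mna_above_action_count_rejected(self, default_params):
        pop = rx.Population(2, 50)
        with pytest.raises(ValueError):
            rx.build_match_set(pop, "01", default_params, rx.Rng(0))

    @pytest.mark.parametrize("seed", range(5))
    def test_match_set_equals_brute_force_filter(self, seed, small_params):
        pop = rx.Population.for_params(small_params, 5)
        rng = rx.Rng(seed)
        for state in ("00000", "11111", "01010"):
            rx.build_match_set(pop, state, small_params, rng)
        state = "01100"
        mset = rx.build_match_set(pop, state, small_params, rng)
        got = {(c.condition, c.action) for c in mset.classifiers(pop)}
        oracle = {
            (c.condition, c.action)
            for c in pop.classifiers()
            if rx.matches(c.condition, state)
        }
        assert got == oracle


class TestPredictionArray:
    def _pa(self, rules, state="0000"):
        pop = rx.Population(4, 50)
        for cl in rules:
            pop.add(cl)
        mset = rx.build_match_set(pop, state, rx.XcsParams(), covering=False)
        return rx.build_prediction_array(pop, mset)

    def test_singleton(self):
        pa = self._pa([rx.Classifier("####", 2, prediction=100, fitness=0.7)])
        assert pa == {2: pytest.approx(100.0)}

    def test_equal_weights_average(self):
        pa = self._pa(
            [
                rx.Classifier("####", 3, prediction=100, fitness=0.5),
                rx.Classifier("00##", 3, prediction=200, fitness=0.5),
            ]
        )
        assert pa[3] == pytest.approx(150.0)

    def test_weighted_mean(self):
        pa = self._pa(
            [
                rx.Classifier("####", 1, prediction=0, fitness=1),
                rx.Classifier("0###", 1, prediction=1000, fitness=3),
            ]
        )
        assert pa[1] == pytest.approx(750.0)

    def test_zero_fitness_falls_back_to_unweighted_mean(self):
        pa = self._pa(
            [
                rx.Classifier("####", 1, prediction=100, fitness=0.0),
                rx.Classifier("0###", 1, prediction=300, fitness=0.0),
            ]
        )
        assert pa[1] == pytest.approx(200.0)

    def test_absent_actions_missing(self):
        pa = self._pa([rx.Classifier("####", 0, prediction=5, fitness=0.1)])
        assert set(pa) == {0}


class TestSelectAction:
    def test_exploit_above_threshold(self):
        assert rx.select_action({4: 600.0, 1: 599.0}, rx.Rng(0)) == 4

    def test_explore_below_threshold_uniform(self):
        rng = rx.Rng(3)
        seen = {rx.select_action({1: 400.0, 3: 100.0}, rng) for _ in range(100)}
        assert seen == {1, 3}

    def test_exactly_500_explores(self):
        # with a single present action exploring still returns it, but a
        # random draw is consumed — the boundary payoff goes down the
        # explore branch, not the exploit branch
        rng = rx.Rng(1)
        s0 = int(rng.state[0])
        assert rx.select_action({2: 500.0}, rng) == 2
        assert int(rng.state[0]) != s0

    def test_greedy_tie_breaks_to_lowest_action(self):
        assert rx.select_action({2: 700.0, 1: 700.0}, greedy=True) == 1

    def test_empty_array_rejected(self):
        with pytest.raises(ValueError):
            rx.select_action({}, rx.Rng(0))


class TestTargetPayoff:
    def test_discounted_backup(self):
        assert rx.compute_target_P(0.0, {1: 1000.0}, 0.76) == pytest.approx(760.0)

    def test_empty_prediction_array(self):
        assert rx.compute_target_P(500.0, {}, 0.76) == pytest.approx(500.0)


class TestAccuracy:
    def test_below_threshold_is_one(self, default_params):
        assert rx.classifier_accuracy(10.0, default_params) == 1.0

    def test_at_threshold_equals_alpha(self, default_params):
        assert rx.classifier_accuracy(18.5, default_params) == pytest.approx(0.087)

    def test_powerlaw_tail(self, default_params):
        assert rx.classifier_accuracy(37.0, default_params) == pytest.approx(
            0.087 * 2 ** (-0.01)
        )

    @given(st.floats(0.0, 5000.0), st.floats(0.0, 5000.0))
    def test_non_increasing(self, e1, e2):
        params = rx.XcsParams()
        lo, hi = sorted((e1, e2))
        assert rx.classifier_accuracy(lo, params) >= rx.classifier_accuracy(
            hi, params
        )


class TestUpdateActionSet:
    def _single(self, params):
        pop = rx.Population(5, 50)
        pop.add(
            rx.Classifier(
                "#####", 2, prediction=params.p_init, error=params.eps_init,
                fitness=params.f_init,
            )
        )
        mset = rx.build_match_set(pop, "00000", params, covering=False)
        return pop, mset

    def test_first_update_replaces_prediction(self, default_params):
        pop, mset = self._single(default_params)
        rx.update_action_set(pop, mset, 1000.0, default_params)
        cl = pop.classifiers()[0]
        assert cl.prediction == pytest.approx(1000.0)
        assert cl.experience == 1
        # error moved toward |P - p_old| using the pre-update prediction
        assert cl.error == pytest.approx(1000.0 - 7.4)

    def test_second_update_averages(self, default_params):
        pop, mset = self._single(default_params)
        rx.update_action_set(pop, mset, 1000.0, default_params)
        rx.update_action_set(pop, mset, 500.0, default_params)
        assert pop.classifiers()[0].prediction == pytest.approx(750.0)

    def test_experienced_zero_error_step_leaves_prediction(self, default_params):
        pop = rx.Population(5, 50)
        pop.add(
            rx.Classifier(
                "#####", 1, prediction=1000.0, error=0.0, fitness=0.5, experience=500
            )
        )
        mset = rx.build_match_set(pop, "00000", default_params, covering=False)
        rx.update_action_set(pop, mset, 1000.0, default_params)
        assert pop.classifiers()[0].prediction == pytest.approx(1000.0)

    def test_accurate_classifier_fitness_rises(self, default_params):
        pop = rx.Population(5, 50)
        pop.add(rx.Classifier("#####", 1, prediction=1000, error=0.0, fitness=0.1))
        mset = rx.build_match_set(pop, "00000", default_params, covering=False)
        rx.update_action_set(pop, mset, 1000.0, default_params)
        cl = pop.classifiers()[0]
        assert cl.fitness > 0.1  # relative accuracy 1 pulls fitness upward


class TestGenerality:
    def test_wildcards_are_more_general(self):
        assert rx.is_more_general(rx.Classifier("##", 1), rx.Classifier("01", 1))

    def test_asymmetry(self):
        assert not rx.is_more_general(rx.Classifier("01", 1), rx.Classifier("##", 1))

    def test_strictness_on_identical_conditions(self):
        assert not rx.is_more_general(rx.Classifier("0#", 1), rx.Classifier("0#", 1))

    def test_actions_must_match(self):
        assert not rx.is_more_general(rx.Classifier("##", 2), rx.Classifier("01", 1))

    def test_literals_must_agree(self):
        assert not rx.is_more_general(rx.Classifier("1#", 1), rx.Classifier("01", 1))


class TestCrossoverAndMutation:
    def test_segment_swap_hand_trace(self):
        m1, v1 = X.condition_to_masks("00000")
        m2, v2 = X.condition_to_masks("11111")
        out = K._crossover_segment(
            np.int64(m1), np.int64(v1), np.int64(m2), np.int64(v2),
            np.int64(5), np.int64(1), np.int64(3),
        )
        assert X.masks_to_condition(int(out[0]), int(out[1]), 5) == "01100"
        assert X.masks_to_condition(int(out[2]), int(out[3]), 5) == "10011"

    def test_full_exchange_and_empty_segment(self):
        m1, v1 = X.condition_to_masks("0#1")
        m2, v2 = X.condition_to_masks("1#0")
        full = K._crossover_segment(
            np.int64(m1), np.int64(v1), np.int64(m2), np.int64(v2),
            np.int64(3), np.int64(0), np.int64(3),
        )
        assert X.masks_to_condition(int(full[0]), int(full[1]), 3) == "1#0"
        none = K._crossover_segment(
            np.int64(m1), np.int64(v1), np.int64(m2), np.int64(v2),
            np.int64(3), np.int64(2), np.int64(2),
        )
        assert X.masks_to_condition(int(none[0]), int(none[1]), 3) == "0#1"

    @given(ternary(6), ternary(6), st.integers(0, 2**31 - 1))
    def test_crossover_preserves_multiset_of_columns(self, c1, c2, seed):
        o1, o2 = rx.crossover_two_point(c1, c2, rx.Rng(seed))
        for i in range(6):
            assert {o1[i], o2[i]} == {c1[i], c2[i]}

    def test_zero_mutation_is_identity(self, default_params):
        cl = rx.Classifier("1#0#1", 3)
        out = rx.mutate_classifier(
            cl, "10011", default_params.replace(mu=0.0), rx.Rng(0)
        )
        assert (out.condition, out.action) == ("1#0#1", 3)

    def test_certain_mutation_toggles_every_position(self, default_params):
        out = rx.mutate_classifier(
            rx.Classifier("1#110", 2), "10110", default_params.replace(mu=1.0),
            rx.Rng(0),
        )
        # every literal becomes '#', every '#' becomes the situation's bit
        assert out.condition == "#0###"
        assert out.action != 2  # the action is re-drawn as well

    @given(st.integers(0, 2**31 - 1), bitstring(5))
    def test_mutant_still_matches_situation(self, seed, situation):
        params = rx.XcsParams()
        base = rx.cover(situation, set(), params, rx.Rng(seed))
        out = rx.mutate_classifier(base, situation, params, rx.Rng(seed + 1))
        assert rx.matches(out.condition, situation)


class TestRuleFormat:
    def test_round_trip_at_printed_precision(self, tmp_path):
        rules = [
            rx.Classifier("####1", 2, prediction=174.82, fitness=0.9105),
            rx.Classifier("#####", 0, prediction=135.11, fitness=0.0642),
        ]
        path = tmp_path / "rules.txt"
        rx.write_ruleset(rules, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "####1 : 2 [174.82/0.9105]"
        back = rx.read_ruleset(path)
        assert [rx.format_rule(c) for c in back] == lines

    def test_malformed_line_rejected(self):
        with pytest.raises(ValueError):
            rx.parse_rule("012#1 : x [1/2]")


class TestParamsIO:
    def test_yaml_round_trip(self, tmp_path):
        p = rx.XcsParams(R=500, chi=0.5)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert rx.XcsParams.from_yaml(path) == p

    def test_aliases_accepted(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("eps0: 10.0\nthetaGa: 50\n")
        p = rx.XcsParams.from_yaml(path)
        assert p.eps_0 == 10.0 and p.theta_ga == 50

    def test_defaults_reject_probabilistic_chooser(self):
        with pytest.raises(ValueError):
            rx.XcsParams(use_new_action_chooser=False)
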