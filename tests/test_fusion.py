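"""Fusion rules vs brute-force oracles; PSO behavior."""

import numpy as np
import pytest

from ecgfusion import fusion


ROWS = np.array([[0.6, 0.4, 0.0],
                 [0.2, 0.5, 0.3],
                 [0.1, 0.6, 0.3]])


def random_profiles(n, L=3, C=3, seed=0):
    return np.random.default_rng(seed).random((n, L, C))


class TestAlgebraicRules:
    def test_mean_rule_hand_arithmetic(self):
        s, d = fusion.combine_mean(ROWS)
        np.testing.assert_allclose(s, [0.3, 0.5, 0.2])
        assert d == 1

    def test_unanimous_profile(self):
        s, d = fusion.combine_mean(np.tile([1.0, 0.0, 0.0], (3, 1)))
        np.testing.assert_allclose(s, [1, 0, 0])
        assert d == 0

    def test_min_rule_hand_arithmetic(self):
        s, d = fusion.combine_min(ROWS)
        np.testing.assert_allclose(s, [0.1, 0.4, 0.0])
        assert d == 1

    def test_product_rule_hand_arithmetic(self):
        s, d = fusion.combine_product(ROWS)
        np.testing.assert_allclose(s, [0.6 * 0.2 * 0.1, 0.4 * 0.5 * 0.6, 0.0])
        assert d == 1

    def test_product_veto_property(self):
        dp = np.array([[0.9, 0.0], [0.8, 1.0]])
        s, d = fusion.combine_product(dp)
        assert s[1] == 0.0 and d == 0

    def test_all_ones_profile_ties_to_class_zero(self):
        s, d = fusion.combine_product(np.ones((3, 3)))
        np.testing.assert_allclose(s, 1.0)
        assert d == 0

    def test_single_classifier_rules_return_the_row(self):
        row = np.array([[0.2, 0.7, 0.1]])
        for fn in (fusion.combine_min, fusion.combine_max,
                   fusion.combine_median):
            s, d = fn(row)
            np.testing.assert_allclose(s, row[0])
            assert d == 1

    def test_order_statistics_ordering(self):
        for dp in random_profiles(200, seed=5):
            lo = fusion.combine_min(dp)[0]
            mid = fusion.combine_median(dp)[0]
            hi = fusion.combine_max(dp)[0]
            assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)

    def test_mean_decision_equals_sum_rule_decision(self):
        for dp in random_profiles(1000, seed=1):
            assert fusion.combine_mean(dp)[1] == int(np.argmax(dp.sum(axis=0)))

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="L x C"):
            fusion.combine_mean(np.empty((0, 3)))


class TestVoting:
    def test_majority_two_against_one(self):
        dp = np.array([[0.9, 0.1, 0.0], [0.8, 0.2, 0.0], [0.1, 0.2, 0.7]])
        assert fusion.majority_vote(dp) == 0

    def test_three_way_tie_goes_to_lowest_class(self):
        dp = np.array([[0.9, 0.1, 0.0], [0.1, 0.9, 0.0], [0.1, 0.2, 0.7]])
        assert fusion.majority_vote(dp) == 0

    def test_agreement_with_brute_force_counting(self):
        for dp in random_profiles(1000, seed=2):
            counts = [0] * 3
            for row in dp:
                counts[int(np.argmax(row))] += 1
            best = counts.index(max(counts))
            assert fusion.majority_vote(dp) == best


class TestBorda:
    def test_hand_ranked_example(self):
        dp = np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3], [0.4, 0.5, 0.1]])
        votes, d = fusion.borda_count(dp)
        np.testing.assert_allclose(votes, [3, 5, 1])
        assert d == 1

    def test_single_classifier_borda_equals_argmax(self):
        for dp in random_profiles(50, L=1, seed=3):
            assert fusion.borda_count(dp)[1] == int(np.argmax(dp[0]))

    def test_total_votes_conserved(self):
        for dp in random_profiles(300, L=4, C=5, seed=4):
            votes, _ = fusion.borda_count(dp)
            assert votes.sum() == pytest.approx(4 * 5 * 4 / 2)

    def test_within_row_ties_share_average_points(self):
        votes, _ = fusion.borda_count(np.array([[0.5, 0.5, 0.1]]))
        np.testing.assert_allclose(votes, [1.5, 1.5, 0.0])

    def test_agreement_with_brute_force_ranking(self):
        for dp in random_profiles(500, seed=6):
            # oracle: points by sorting each row (no ties expected in
            # continuous random draws)
            pts = np.zeros(3)
            for row in dp:
                order = np.argsort(row)
                for points, cls in enumerate(order):
                    pts[cls] += points
            votes, d = fusion.borda_count(dp)
            np.testing.assert_allclose(votes, pts)
            assert d == int(np.argmax(pts))


class TestDecisionTemplates:
    def test_one_instance_per_class_templates_equal_profiles(self):
        profs = random_profiles(3, seed=7)
        dts = fusion.fit_decision_templates(profs, [0, 1, 2], 3)
        np.testing.assert_allclose(dts.templates, profs)

    def test_duplicate_instances_average_to_themselves(self):
        p = random_profiles(1, seed=8)[0]
        dts = fusion.fit_decision_templates([p, p, p, p], [0, 0, 1, 2], 3)
        np.testing.assert_allclose(dts.templates[0], p)

    def test_mean_matches_accumulation_oracle(self):
        profs = random_profiles(10, seed=9)
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 0, 1, 2])
        dts = fusion.fit_decision_templates(profs, labels, 3)
        for c in range(3):
            acc = np.zeros((3, 3))
            n = 0
            for p, l in zip(profs, labels):
                if l == c:
                    acc += p
                    n += 1
            np.testing.assert_allclose(dts.templates[c], acc / n)

    def test_missing_class_rejected_by_name(self):
        with pytest.raises(ValueError, match="class 2"):
            fusion.fit_decision_templates(random_profiles(4, seed=1),
                                          [0, 1, 0, 1], 3)

    def test_exact_template_match_gives_similarity_one(self):
        profs = random_profiles(3, seed=10)
        dts = fusion.fit_decision_templates(profs, [0, 1, 2], 3)
        sims, d = fusion.apply_decision_templates(dts, profs[1])
        assert sims[1] == pytest.approx(1.0)
        assert d == 1

    def test_maximal_distance_gives_similarity_zero(self):
        dts = fusion.DecisionTemplateSet(
            templates=np.stack([np.ones((2, 2)), np.zeros((2, 2))]),
            class_counts=np.array([1, 1]))
        sims, _ = fusion.apply_decision_templates(dts, np.zeros((2, 2)))
        assert sims[0] == pytest.approx(0.0)
        assert sims[1] == pytest.approx(1.0)

    def test_similarity_matches_double_loop_oracle(self):
        profs = random_profiles(6, seed=11)
        dts = fusion.fit_decision_templates(profs, [0, 1, 2, 0, 1, 2], 3)
        dp = random_profiles(1, seed=12)[0]
        sims, _ = fusion.apply_decision_templates(dts, dp)
        for c in range(3):
            acc = 0.0
            for i in range(3):
                for j in range(3):
                    acc += (dts.templates[c][i, j] - dp[i, j]) ** 2
            assert sims[c] == pytest.approx(1 - acc / 9)

    def test_shape_mismatch_rejected(self):
        dts = fusion.fit_decision_templates(random_profiles(3, seed=1),
                                            [0, 1, 2], 3)
        with pytest.raises(ValueError, match="shape"):
            fusion.apply_decision_templates(dts, np.zeros((2, 3)))


class TestPSO:
    def test_sphere_function_reaches_near_zero(self):
        cfg = fusion.PSOConfig(swarm_size=30, iterations=200, seed=0)
        _, val, _ = fusion.pso_minimize(lambda x: float(np.sum(x ** 2)), 2, cfg)
        assert val < 1e-3

    def test_shifted_quadratic_recovers_optimum(self):
        a = np.array([0.4, -0.7])
        cfg = fusion.PSOConfig(swarm_size=30, iterations=200, seed=1)
        best, _, _ = fusion.pso_minimize(
            lambda x: float(np.sum((x - a) ** 2)), 2, cfg)
        assert np.linalg.norm(best - a) < 0.05

    def test_best_value_trace_never_increases(self):
        cfg = fusion.PSOConfig(swarm_size=10, iterations=50, seed=2)
        _, _, trace = fusion.pso_minimize(
            lambda x: float(np.sum(np.abs(x))), 3, cfg)
        assert np.all(np.diff(trace) <= 0)

    def test_non_finite_objective_triggers_reset_with_warning(self):
        calls = {"n": 0}

        def objective(x):
            calls["n"] += 1
            return np.nan if calls["n"] % 7 == 3 else float(np.sum(x ** 2))

        cfg = fusion.PSOConfig(swarm_size=5, iterations=10, seed=3)
        with pytest.warns(UserWarning, match="non-finite"):
            _, val, _ = fusion.pso_minimize(objective, 2, cfg)
        assert np.isfinite(val)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fusion.PSOConfig(swarm_size=0)
        with pytest.raises(ValueError):
            fusion.PSOConfig(c1=0.0)


class TestWeightedAveraging:
    def _profiles_with_one_expert(self, n=60, seed=4):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, n)
        profs = rng.random((n, 3, 3))
        profs[np.arange(n), 0, :] = 0.05
        profs[np.arange(n), 0, y] = 0.95  # classifier 0 is always right
        return profs, y

    def test_weight_mass_concentrates_on_perfect_expert(self):
        profs, y = self._profiles_with_one_expert()
        w = fusion.fit_pso_weights(profs, y, fusion.PSOConfig(seed=5))
        assert w.weights[0] >= 0.6

    def test_identical_classifiers_still_give_simplex_weights(self):
        rng = np.random.default_rng(6)
        row = rng.random((40, 1, 3))
        profs = np.repeat(row, 3, axis=1)
        y = np.argmax(row[:, 0, :], axis=1)
        w = fusion.fit_pso_weights(profs, y, fusion.PSOConfig(seed=7))
        assert w.weights.sum() == pytest.approx(1.0)
        assert np.all(w.weights >= 0)

    def test_degenerate_weight_vector_selects_single_classifier(self):
        dp = random_profiles(1, seed=8)[0]
        s, d = fusion.combine_weighted(dp, fusion.WeightVector(
            np.array([1.0, 0.0, 0.0])))
        np.testing.assert_allclose(s, dp[0])
        assert d == int(np.argmax(dp[0]))

    def test_uniform_weights_reduce_to_mean_rule(self):
        for dp in random_profiles(100, seed=9):
            w = fusion.WeightVector(np.full(3, 1 / 3))
            np.testing.assert_allclose(fusion.combine_weighted(dp, w)[0],
                                       fusion.combine_mean(dp)[0])

    def test_weighted_support_matches_dot_product_oracle(self):
        dp = random_profiles(1, L=4, seed=10)[0]
        w = np.array([0.1, 0.2, 0.3, 0.4])
        s, _ = fusion.combine_weighted(dp, fusion.WeightVector(w))
        for j in range(3):
            assert s[j] == pytest.approx(sum(w[i] * dp[i, j] for i in range(4)))

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fusion.combine_weighted(np.ones((3, 3)),
                                    fusion.WeightVector(np.array([0.5, 0.5])))

    def test_invalid_weight_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fusion.WeightVector(np.array([0.5, 0.2]))


class TestSharedContracts:
    def test_permutation_equivariance_in_classifier_axis(self):
        rng = np.random.default_rng(13)
        for dp in random_profiles(100, L=4, seed=13):
            perm = rng.permutation(4)
            for name, fn in fusion.SIMPLE_METHODS.items():
                assert fn(dp) == fn(dp[perm]), name

    def test_unanimity_preserved_by_every_stateless_method(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            c = rng.integers(0, 3)
            dp = rng.random((3, 3)) * 0.4
            dp[:, c] = 0.6 + 0.4 * rng.random(3)
            for name, fn in fusion.SIMPLE_METHODS.items():
                assert fn(dp) == c, name

    def test_dispatch_errors(self):
        with pytest.raises(ValueError, match="unknown combination"):
            fusion.combine("nope", np.ones((2, 2)))
        with pytest.raises(ValueError, match="needs a fitted"):
            fusion.combine("dt", np.ones((2, 2)))
        with pytest.raises(ValueError, match="needs a fitted"):
            fusion.combine("pso", np.ones((2, 2)))
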