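"""Tests of the mitigation operators against hand values and enumeration."""

import numpy as np
import pytest

from fairdx.fairness import LabeledPredictions, group_confusion
from fairdx.mitigation import (
    CounterfactualQuery,
    MitigationParams,
    bpa_adjust,
    composite_fairness_loss,
    counterfactual_search,
    eq_odds_scale,
    find_k,
    reweight,
    threshold_predict,
)


class TestReweight:
    @pytest.mark.parametrize("p,w", [(1.0, 1.0), (0.5, 2.0), (0.25, 4.0)])
    def test_reciprocal(self, p, w):
        assert reweight(np.array([p]))[0] == pytest.approx(w)

    def test_zero_probability_clipped(self):
        assert reweight(np.array([0.0]), eps=1e-3)[0] == pytest.approx(1000.0)

    def test_zero_probability_without_clip_raises(self):
        with pytest.raises(ValueError):
            reweight(np.array([0.0]), clip=False)

    def test_monotone_decreasing_in_p(self):
        p = np.linspace(0.01, 1.0, 50)
        w = reweight(p)
        assert np.all(np.diff(w) < 0)


class TestThresholdPredict:
    def test_strict_inequality_at_boundary(self):
        assert threshold_predict(np.array([0.5]), 0.5)[0] == 0
        assert threshold_predict(np.array([0.51]), 0.5)[0] == 1

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=200)
        counts = [threshold_predict(s, th).sum() for th in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            threshold_predict(np.array([0.5]), 1.0)


def _rates_fixture():
    """Group rates with dTPR=0.2 (group 'u' lower) and dFPR=0.1 ('p' higher)."""
    y_true = np.array([1] * 10 + [0] * 10 + [1] * 10 + [0] * 10)
    y_pred = np.concatenate([
        np.array([1] * 6 + [0] * 4),      # u positives: TPR 0.6
        np.array([1] * 2 + [0] * 8),      # u negatives: FPR 0.2
        np.array([1] * 8 + [0] * 2),      # p positives: TPR 0.8
        np.array([1] * 3 + [0] * 7),      # p negatives: FPR 0.3
    ])
    group = np.array(["u"] * 20 + ["p"] * 20)
    lp = LabeledPredictions(y_true, np.where(y_pred == 1, 0.9, 0.1), y_pred, group)
    return lp, group_confusion(lp, privileged="p", unprivileged="u")


class TestBpaAdjust:
    def test_no_disparity_is_identity_both_modes(self):
        lp = LabeledPredictions([1, 0, 1, 0], [0.9, 0.2, 0.8, 0.1],
                                [1, 0, 1, 0], [0, 0, 1, 1])
        gr = group_confusion(lp, 0, 1)
        for mode in ("literal", "directed"):
            adj = bpa_adjust(lp.y_score, lp.group, gr, MitigationParams(), mode)
            np.testing.assert_allclose(adj.adjusted, lp.y_score)

    def test_literal_hand_value(self):
        _, gr = _rates_fixture()
        params = MitigationParams(alpha_bpa=1.0, beta_bpa=0.0)
        adj = bpa_adjust(np.array([0.5, 0.5]), np.array(["u", "p"]), gr,
                         params, mode="literal")
        # multiplier 1 + 1*0.2 = 1.2 for every subject
        np.testing.assert_allclose(adj.adjusted, [0.6, 0.6])

    def test_literal_clips_at_one(self):
        _, gr = _rates_fixture()
        params = MitigationParams(alpha_bpa=1.0, beta_bpa=0.0)
        adj = bpa_adjust(np.array([0.9]), np.array(["u"]), gr, params, "literal")
        assert adj.adjusted[0] == pytest.approx(1.0)

    def test_directed_signs(self):
        _, gr = _rates_fixture()
        params = MitigationParams(alpha_bpa=1.0, beta_bpa=1.0)
        adj = bpa_adjust(np.array([0.5, 0.5]), np.array(["u", "p"]), gr,
                         params, mode="directed")
        # u has the lower TPR: x(1 + 0.2); p has the higher FPR: x(1 - 0.1)
        np.testing.assert_allclose(adj.adjusted, [0.5 * 1.2, 0.5 * 0.9])

    def test_order_preserved_within_group(self):
        lp, gr = _rates_fixture()
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=len(lp))
        adj = bpa_adjust(scores, lp.group, gr, MitigationParams(), "directed")
        for g in ("u", "p"):
            m = lp.group == g
            order = np.argsort(scores[m])
            assert np.all(np.diff(adj.adjusted[m][order]) >= 0)

    def test_adjusted_scores_in_unit_interval(self):
        lp, gr = _rates_fixture()
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=len(lp))
        for mode in ("literal", "directed"):
            adj = bpa_adjust(scores, lp.group, gr,
                             MitigationParams(alpha_bpa=5, beta_bpa=5), mode)
            assert adj.adjusted.min() >= 0 and adj.adjusted.max() <= 1


class TestEqOddsScale:
    def test_k_one_is_identity(self):
        s = np.array([0.1, 0.5, 0.9])
        adj = eq_odds_scale(s, np.array(["a", "b", "a"]), "a", 1.0)
        np.testing.assert_allclose(adj.adjusted, s)

    def test_hand_value_and_clip(self):
        s = np.array([0.4, 0.8])
        g = np.array(["other", "other"])
        adj = eq_odds_scale(np.append(s, 0.3), np.append(g, "t"), "t", 1.5)
        assert adj.adjusted[0] == pytest.approx(0.6)
        adj2 = eq_odds_scale(np.append(s, 0.3), np.append(g, "t"), "t", 2.0)
        assert adj2.adjusted[1] == pytest.approx(1.0)  # clipped from 1.6
        assert adj2.adjusted[2] == pytest.approx(0.3)  # target untouched

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            eq_odds_scale(np.array([0.5]), np.array(["a"]), "zzz", 1.2)


class TestFindK:
    def test_already_fair_chooses_k_one(self):
        y_true = np.array([1, 0, 1, 0] * 5)
        y_score = np.tile([0.9, 0.1, 0.9, 0.1], 5)
        y_pred = threshold_predict(y_score, 0.5)
        group = np.array([0, 0, 1, 1] * 5)
        lp = LabeledPredictions(y_true, y_score, y_pred, group)
        k, gr, obj = find_k(lp, target_group=0, k_grid=np.arange(0.5, 2.01, 0.1))
        assert k == pytest.approx(1.0)
        assert obj == pytest.approx(0.0)

    def test_single_element_grid_forced(self):
        lp, _ = _rates_fixture()
        k, _, _ = find_k(lp, "p", [1.3], privileged="p", unprivileged="u")
        assert k == 1.3

    def test_objective_no_worse_than_identity(self):
        rng = np.random.default_rng(8)
        n = 2000
        group = rng.integers(0, 2, size=n)
        y_true = rng.integers(0, 2, size=n)
        shift = np.where(group == 0, -0.15, 0.0)
        y_score = np.clip(rng.uniform(size=n) * 0.5 + y_true * 0.4 + shift, 0, 1)
        y_pred = threshold_predict(y_score, 0.5)
        lp = LabeledPredictions(y_true, y_score, y_pred, group)
        grid = np.round(np.arange(0.5, 2.01, 0.1), 10)
        k, gr, obj = find_k(lp, target_group=1, k_grid=grid,
                            privileged=1, unprivileged=0)
        base = group_confusion(lp, 1, 0)
        assert obj <= base.delta_tpr + base.delta_fpr + 1e-12

    def test_matches_independent_grid_reevaluation(self):
        """The returned objective equals the brute-force minimum over the grid."""
        lp, _ = _rates_fixture()
        grid = np.round(np.arange(0.5, 2.01, 0.1), 10)
        k, gr, obj = find_k(lp, "p", grid, privileged="p", unprivileged="u")
        objectives = []
        for kk in grid:
            adj = np.where(lp.group == "p", lp.y_score,
                           np.clip(lp.y_score * kk, 0, 1))
            pred = (adj > 0.5).astype(int)
            g = group_confusion(lp.replace(y_pred=pred), "p", "u")
            objectives.append(g.delta_tpr + g.delta_fpr)
        assert obj == pytest.approx(min(objectives))

    def test_empty_grid_rejected(self):
        lp, _ = _rates_fixture()
        with pytest.raises(ValueError):
            find_k(lp, "p", [], privileged="p", unprivileged="u")


class TestCounterfactualSearch:
    def test_feasible_at_origin(self):
        q = CounterfactualQuery(
            x=[1.0], predictor=lambda X: (X[:, 0] > 0.5).astype(int),
            desired_label=1, lower=[0.0], upper=[4.0], steps=[0.25],
        )
        res = counterfactual_search(q)
        assert res.found and res.distance == pytest.approx(0.0)
        assert res.x_cf[0] == pytest.approx(1.0)

    def test_1d_threshold_hand_value(self):
        # f(x)=1 iff x>2; from x=1 with step 0.25 the nearest hit is 2.25
        q = CounterfactualQuery(
            x=[1.0], predictor=lambda X: (X[:, 0] > 2.0).astype(int),
            desired_label=1, lower=[0.0], upper=[4.0], steps=[0.25],
        )
        res = counterfactual_search(q)
        assert res.x_cf[0] == pytest.approx(2.25)
        assert res.distance == pytest.approx(1.25)

    def test_infeasible_box_not_found(self):
        q = CounterfactualQuery(
            x=[1.0], predictor=lambda X: np.zeros(len(X), dtype=int),
            desired_label=1, lower=[0.0], upper=[4.0], steps=[0.5],
        )
        res = counterfactual_search(q)
        assert not res.found and res.x_cf is None

    def test_matches_exhaustive_enumeration_2d(self):
        """Agreement with an independent nested-loop enumeration oracle."""
        def predictor(X):
            return ((X[:, 0] + 2 * X[:, 1]) > 3.0).astype(int)

        q = CounterfactualQuery(
            x=[0.5, 0.5], predictor=predictor, desired_label=1,
            lower=[0.0, 0.0], upper=[3.0, 3.0], steps=[0.1, 0.1],
        )
        res = counterfactual_search(q)

        best_d, best_x = np.inf, None
        xs = np.arange(0.0, 3.05, 0.1)
        for a in xs:
            for b in xs:
                if (a + 2 * b) > 3.0:
                    d = np.hypot(a - 0.5, b - 0.5)
                    if d < best_d:
                        best_d, best_x = d, (a, b)
        assert res.distance == pytest.approx(best_d)
        np.testing.assert_allclose(res.x_cf, best_x, atol=1e-9)

    def test_grid_size_guard(self):
        q = CounterfactualQuery(
            x=[0.0, 0.0, 0.0], predictor=lambda X: np.ones(len(X), dtype=int),
            desired_label=1, lower=[0] * 3, upper=[100] * 3, steps=[0.1] * 3,
        )
        with pytest.raises(ValueError):
            counterfactual_search(q, max_grid_points=10_000)


class TestCompositeLoss:
    @pytest.mark.parametrize(
        "task,fair,lam,expected",
        [(0.7, 0.2, 1.5, 1.0), (0.7, 0.2, 0.0, 0.7), (0.0, 0.0, 2.0, 0.0)],
    )
    def test_hand_values(self, task, fair, lam, expected):
        assert composite_fairness_loss(task, fair, lam) == pytest.approx(expected)

    def test_monotone_in_each_argument(self):
        base = composite_fairness_loss(0.5, 0.5, 0.5)
        assert composite_fairness_loss(0.6, 0.5, 0.5) >= base
        assert composite_fairness_loss(0.5, 0.6, 0.5) >= base
        assert composite_fairness_loss(0.5, 0.5, 0.6) >= base

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            composite_fairness_loss(float("nan"), 0.0, 1.0)
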