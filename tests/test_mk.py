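import numpy as np
import pytest

import morphosig as ms
from morphosig.mk import OptimConfig


class TestBuildQ:
    def test_binary_er(self):
        rm = ms.build_q(2, 0.5, "ER")
        assert np.allclose(rm.Q, [[-0.5, 0.5], [0.5, -0.5]])

    def test_three_state_er(self):
        rm = ms.build_q(3, 1.0, "ER")
        assert np.allclose(np.diag(rm.Q), -2.0)
        assert np.allclose(rm.Q[~np.eye(3, dtype=bool)], 1.0)

    def test_binary_ard(self):
        rm = ms.build_q(2, [0.1, 0.4], "ARD")
        assert np.allclose(rm.Q, [[-0.1, 0.1], [0.4, -0.4]])

    def test_rows_sum_to_zero_and_off_diagonal_order(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        rm = ms.build_q(3, rates, "ARD")
        assert np.allclose(rm.Q.sum(axis=1), 0.0)
        assert np.allclose(rm.off_diagonal, rates)

    @pytest.mark.parametrize("bad", [
        dict(k=2, rates=[-0.1], structure="ER"),
        dict(k=2, rates=[0.1, 0.2], structure="ER"),
        dict(k=3, rates=[0.1, 0.2], structure="ARD"),
        dict(k=1, rates=[0.1], structure="ER"),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            ms.build_q(**bad)


class TestTransitionProbs:
    def test_identity_at_zero_time(self):
        rm = ms.build_q(3, 0.7, "ER")
        assert np.allclose(ms.transition_probs(rm, 0.0), np.eye(3))

    def test_binary_er_closed_form(self):
        rm = ms.build_q(2, 0.5, "ER")
        P = ms.transition_probs(rm, 1.0)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-2 * 0.5 * 1.0), abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_stationary_limit(self):
        rm = ms.build_q(2, 1.0, "ER")
        assert np.allclose(ms.transition_probs(rm, 1e6), 0.5)

    def test_matches_expm_for_ard(self):
        from scipy.linalg import expm
        rm = ms.build_q(3, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], "ARD")
        assert np.allclose(ms.transition_probs(rm, 2.5), expm(rm.Q * 2.5),
                           atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ms.transition_probs(ms.build_q(2, 1.0, "ER"), -1.0)


class TestPruneLoglik:
    def test_all_missing_gives_likelihood_one(self, two_tip_tree):
        rm = ms.build_q(2, 1.0, "ER")
        assert ms.prune_loglik(two_tip_tree, [-1, -1], rm) == pytest.approx(0.0)

    def test_two_tip_closed_form(self, two_tip_tree):
        rm = ms.build_q(2, 1.0, "ER")
        p00 = 0.5 + 0.5 * np.exp(-2.0)
        p10 = 0.5 - 0.5 * np.exp(-2.0)
        expected = np.log(0.5 * (p00**2 + p10**2))
        got = ms.prune_loglik(two_tip_tree, [0, 0], rm)
        assert got == pytest.approx(expected, abs=1e-9)
        assert 0.5 * (p00**2 + p10**2) == pytest.approx(0.25458, abs=5e-6)

    def test_matches_enumeration_on_random_trees(self, enumeration_oracle):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            tree = ms.simulate_tree(n, rng).scale(0.03)
            k = int(rng.integers(2, 4))
            rm = ms.build_q(k, rng.uniform(0.05, 2.0, size=k * (k - 1)), "ARD")
            states = rng.integers(-1, k, size=n)
            got = ms.prune_loglik(tree, states, rm)
            want = enumeration_oracle(tree, states, rm.Q)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-10)

    def test_invariant_to_child_order(self, yule64):
        rng = np.random.default_rng(5)
        states = rng.integers(0, 2, size=64)
        rm = ms.build_q(2, 0.01, "ER")
        base = ms.prune_loglik(yule64, states, rm)
        # reverse every child list (a relabeling-free reordering)
        import copy
        t2 = copy.deepcopy(yule64)
        for v in range(t2.n_nodes):
            t2.children[v] = t2.children[v][::-1]
        order = []
        stack = [t2.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(t2.children[v])
        t2.postorder = np.array(order[::-1])
        assert ms.prune_loglik(t2, states, rm) == pytest.approx(base, rel=1e-12)

    def test_state_out_of_range_rejected(self, two_tip_tree):
        rm = ms.build_q(2, 1.0, "ER")
        with pytest.raises(ValueError):
            ms.prune_loglik(two_tip_tree, [0, 2], rm)

    def test_deep_tree_does_not_underflow(self):
        tree = ms.simulate_tree(128, 9)
        rng = np.random.default_rng(1)
        states = rng.integers(0, 2, size=128)
        lnL = ms.prune_loglik(tree, states, ms.build_q(2, 1e-4, "ER"))
        assert np.isfinite(lnL)


class TestFitMk:
    def test_identical_states_drive_rate_to_lower_bound(self):
        tree = ms.TimeTree.from_newick("((A:1,B:1):1,C:2);")
        fit = ms.fit_mk(tree, [0, 0, 0], "ER", OptimConfig(n_restarts=1),
                        k=2)
        assert fit.params["rates"] == pytest.approx(ms.mk.RATE_LO, rel=10)

    def test_nested_models_lnl_ordering(self, yule64):
        rng = np.random.default_rng(11)
        cfg = OptimConfig(n_restarts=2, seed=3)
        for i in range(5):
            states = ms.simulate_character(
                yule64, ms.build_q(2, 0.01, "ER"), 1.0, 100 + i)
            if np.unique(states).size < 2:
                continue
            er = ms.fit_mk(yule64, states, "ER", cfg)
            ard = ms.fit_mk(yule64, states, "ARD", cfg)
            assert ard.lnL >= er.lnL - 1e-6

    def test_er_rate_recovery_median(self):
        tree = ms.simulate_tree(128, 21)
        cfg = OptimConfig(n_restarts=1, seed=0)
        qs = []
        for i in range(60):
            states = ms.simulate_character(
                tree, ms.build_q(2, 0.005, "ER"), 1.0, 3000 + i)
            if np.unique(states).size < 2:
                continue
            qs.append(ms.fit_mk(tree, states, "ER", cfg).params["rates"])
        assert np.median(qs) == pytest.approx(0.005, rel=0.25)

    def test_aic_identity(self, yule64):
        states = ms.simulate_character(yule64, ms.build_q(2, 0.01, "ER"),
                                       1.0, 77)
        fit = ms.fit_mk(yule64, states, "ER", OptimConfig(n_restarts=1))
        assert fit.aic == pytest.approx(2 * fit.n_free - 2 * fit.lnL)
        assert fit.n_free == 1


class TestFitLambda:
    def test_synapomorphy_gives_high_lambda(self):
        tree = ms.simulate_tree(16, 3)
        # mark all descendants of one mid-sized clade
        for v in range(tree.n_tips, tree.n_nodes):
            desc, stack = [], [v]
            while stack:
                u = stack.pop()
                if tree.is_tip(u):
                    desc.append(u)
                else:
                    stack.extend(tree.children[u])
            if 3 <= len(desc) <= 8:
                break
        states = np.zeros(16, dtype=int)
        states[desc] = 1
        fit = ms.fit_lambda(tree, states)
        assert fit.params["lambda"] >= 0.95

    def test_signal_free_characters_give_low_lambda(self, yule64):
        """Characters evolved on the star (lambda=0) tree carry no
        phylogenetic structure; the estimator should say so."""
        lams = []
        for i in range(15):
            states = ms.simulate_character(
                yule64, ms.build_q(2, 0.005, "ER"), 0.0, 4000 + i)
            if np.unique(states).size < 2:
                continue
            lams.append(ms.fit_lambda(yule64, states).params["lambda"])
        assert np.median(lams) <= 0.2

    def test_invariant_to_binary_relabeling(self, yule64):
        states = ms.simulate_character(yule64, ms.build_q(2, 0.008, "ER"),
                                       0.6, 55)
        f0 = ms.fit_lambda(yule64, states)
        f1 = ms.fit_lambda(yule64, 1 - states)
        assert f0.params["lambda"] == pytest.approx(f1.params["lambda"], abs=1e-3)
        assert f0.n_free == 2


class TestInformationCriteria:
    def test_aic_from_printed_loglik(self):
        # GLS null model of the lambda comparison: lnL -103.02, 2 params
        assert ms.aic(-103.02, 2) == pytest.approx(210.04)
        assert round(ms.aic(-103.02, 2), 1) == 210.0
        # independence-weight comparison: lnL 1043.0, 2 params
        assert ms.aic(1043.0, 2) == pytest.approx(-2082.0)
        assert ms.aic(0.0, 1) == 2.0

    def test_weights_match_printed_tables(self):
        # ER-weight GLS comparison, teeth row
        w = ms.akaike_weights([-49.55, -43.50])
        assert np.round(w, 2) == pytest.approx([0.95, 0.05])
        # lambda GLS comparison, teeth row
        w = ms.akaike_weights([210.0, 211.1])
        assert np.round(w, 2) == pytest.approx([0.63, 0.37])

    def test_weight_properties(self):
        w = ms.akaike_weights([100.0, 100.0])
        assert w == pytest.approx([0.5, 0.5])
        aics = [3.0, 1.0, 7.5]
        w = ms.akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w > 0)
        assert np.argmax(w) == np.argmin(aics)
        with pytest.raises(ValueError):
            ms.akaike_weights([1.0, np.inf])

    def test_model_comparison_tie_prefers_first_listed(self):
        a = ms.MkFit("ER", -10.0, {"rates": 0.1}, 1, True, 1, 2)
        b = ms.MkFit("ARD", -9.0, {"rates": [0.1, 0.1]}, 2, True, 1, 2)
        cmp_ = ms.ModelComparison([a, b])  # identical AICs: 22 and 22
        assert cmp_.best.model == "ER"
        assert cmp_.weights == pytest.approx([0.5, 0.5])
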