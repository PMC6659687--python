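import math

import numpy as np
import pytest
from scipy import stats

from matrophylo import mk
from matrophylo.pagel import PagelDependentModel, _indep_to_dep
from matrophylo.scoring import fit_stage_mass_regression
from matrophylo.simulate import (decode_joint_states, simulate_bd_tree,
                                 simulate_bisse_tree, simulate_brood_data,
                                 simulate_dependent_traits, simulate_mk_trait)
from matrophylo.sse import SSEParams
from matrophylo.trees import check_ultrametric


class TestBirthDeathTree:
    def test_exact_tip_count(self):
        tree, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 50), seed=1)
        assert tree.n_tips == 50

    def test_deterministic_given_seed(self):
        t1, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 30), seed=7)
        t2, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 30), seed=7)
        t3, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 30), seed=8)
        assert t1.to_newick() == t2.to_newick()
        assert t1.to_newick() != t3.to_newick()

    def test_ultrametric_output(self):
        tree, _ = simulate_bd_tree(0.4, 0.15, ("age", 8.0), seed=3)
        assert check_ultrametric(tree, 1e-6)[0]

    def test_yule_expected_tip_count(self):
        lam, t, n_rep = 0.8, 1.5, 2000
        counts = np.array([simulate_bd_tree(lam, 0.0, ("age", t),
                                            seed=s)[0].n_tips
                           for s in range(n_rep)])
        expected = 2 * math.exp(lam * t)
        se = counts.std(ddof=1) / math.sqrt(n_rep)
        assert abs(counts.mean() - expected) <= 3 * se

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_bd_tree(0.1, 0.2, ("n_tips", 10))


class TestBisseTree:
    def test_zero_transition_keeps_root_state(self):
        params = SSEParams([0.3, 0.3], [0.0, 0.0], np.zeros((2, 2)))
        _, states, _ = simulate_bisse_tree(params, ("n_tips", 40), 0, seed=2)
        assert set(states.values()) == {0}

    def test_symmetric_params_balanced_states(self):
        params = SSEParams([0.4, 0.4], [0.05, 0.05], [[0, 0.3], [0.3, 0]])
        frac = []
        for s in range(150):
            _, states, _ = simulate_bisse_tree(params, ("n_tips", 30),
                                               root_state=s % 2, seed=s)
            frac.append(np.mean(list(states.values())))
        assert abs(np.mean(frac) - 0.5) <= 3 * np.std(frac) / math.sqrt(len(frac))

    def test_higher_lambda_state_overrepresented(self):
        fast = SSEParams([0.15, 0.45], [0.02, 0.02], [[0, 0.1], [0.1, 0]])
        neutral = SSEParams([0.15, 0.15], [0.02, 0.02], [[0, 0.1], [0.1, 0]])
        frac_fast, frac_neutral = [], []
        for s in range(120):
            _, st1, _ = simulate_bisse_tree(fast, ("age", 6.0), 0,
                                            seed=1000 + s)
            frac_fast.append(np.mean(list(st1.values())))
            _, st2, _ = simulate_bisse_tree(neutral, ("age", 6.0), 0,
                                            seed=5000 + s)
            frac_neutral.append(np.mean(list(st2.values())))
        se = math.hypot(np.std(frac_fast, ddof=1) / math.sqrt(120),
                        np.std(frac_neutral, ddof=1) / math.sqrt(120))
        assert np.mean(frac_fast) - np.mean(frac_neutral) > 2 * se

    def test_symmetric_bisse_indistinguishable_from_bd_plus_mk(self):
        """State-symmetric SSE simulation must match birth-death trees with
        an independently overlaid Mk character (KS tests on crown age and
        state counts)."""
        lam, mu, q, T = 0.5, 0.1, 0.15, 5.0
        params = SSEParams([lam, lam], [mu, mu], [[0, q], [q, 0]])
        n_rep = 250
        ages1, ages2, ones1, ones2 = [], [], [], []
        for s in range(n_rep):
            tree1, st1, _ = simulate_bisse_tree(params, ("age", T), 0, seed=s)
            ages1.append(tree1.n_tips)
            ones1.append(np.mean(list(st1.values())))
            tree2, _ = simulate_bd_tree(lam, mu, ("age", T), seed=10_000 + s)
            st2, _ = simulate_mk_trait(tree2, mk.MkModel.er(q).Q, 0,
                                       seed=20_000 + s)
            ages2.append(tree2.n_tips)
            ones2.append(np.mean(list(st2.values())))
        assert stats.ks_2samp(ages1, ages2).pvalue > 0.01
        assert stats.ks_2samp(ones1, ones2).pvalue > 0.01


class TestMkTrait:
    def test_zero_rate_inherits_root(self, bd_tree_50):
        tips, rec = simulate_mk_trait(bd_tree_50, np.zeros((2, 2)), 1, seed=0)
        assert set(tips.values()) == {1}
        assert rec.history["n_changes"] == 0

    def test_expected_change_count(self, bd_tree_50):
        rate = 0.04
        Q = mk.MkModel.er(rate).Q
        counts = [simulate_mk_trait(bd_tree_50, Q, s % 2, seed=s)[1]
                  .history["n_changes"] for s in range(400)]
        expected = rate * bd_tree_50.total_length()
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_tip_marginals_match_transition_probabilities(self, bd_tree_100):
        from scipy.linalg import expm
        rate = 0.06
        Q = mk.MkModel.er(rate).Q
        depth = bd_tree_100.tip_depths().mean()
        p1 = expm(Q * depth)[0, 1]
        fracs = [np.mean(list(simulate_mk_trait(bd_tree_100, Q, 0,
                                                seed=s)[0].values()))
                 for s in range(400)]
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - p1) <= 3 * se


class TestDependentTraits:
    def test_blocked_path_never_gains_trait1(self, bd_tree_50):
        # q12 = q13 = 0 and root (0,0): states 2-4 unreachable
        rates = np.array([0.0, 0.0, 0.3, 0.5, 0.3, 0.5, 0.3, 0.3])
        data, _ = simulate_dependent_traits(bd_tree_50,
                                            PagelDependentModel(rates), 1,
                                            seed=4)
        t1, t2 = decode_joint_states(data)
        assert set(t1.values()) == {0}
        assert set(t2.values()) == {0}

    def test_contingent_gains_concentrate_on_enabling_background(self,
                                                                 bd_tree_50):
        # trait1 gains: q13 from (0,0), q24 from (0,1); make q24 >> q13
        rates = np.array([0.4, 0.01, 0.2, 2.0, 0.1, 0.4, 0.1, 0.1])
        from_state2 = from_state1 = 0
        for s in range(150):
            _, rec = simulate_dependent_traits(bd_tree_50,
                                               PagelDependentModel(rates), 1,
                                               seed=s)
            node_states = rec.history["node_states"]
            for edge, changes in rec.history["edge_changes"].items():
                prev = node_states[bd_tree_50.parent[edge]]
                for _, new in changes:
                    if (prev, new) == (1, 3):
                        from_state2 += 1
                    elif (prev, new) == (0, 2):
                        from_state1 += 1
                    prev = new
        assert from_state2 > 3 * from_state1

    def test_independent_embedding_gives_independent_counts(self, bd_tree_50):
        rates = _indep_to_dep([0.25, 0.2, 0.3, 0.25])
        model = PagelDependentModel(rates)
        table = np.zeros((2, 2))
        for s in range(250):
            data, _ = simulate_dependent_traits(bd_tree_50, model, 1, seed=s)
            t1, t2 = decode_joint_states(data)
            a = int(np.mean(list(t1.values())) > np.median([0.49]))
            b = int(np.mean(list(t2.values())) > 0.49)
            table[a, b] += 1
        res = stats.chi2_contingency(table + 0.5)
        assert res.pvalue > 0.01


class TestBroodData:
    def test_noiseless_recovers_slope_exactly(self):
        for mi in (0.7, 1.0, 3.0):
            obs = simulate_brood_data(mi, n_broods=10, stage_span=40,
                                      noise_sd=0.0, seed=0)
            reg = fit_stage_mass_regression(obs)
            assert reg.slope == pytest.approx(math.log(mi) / 50, abs=1e-12)

    def test_mi_07_generating_slope(self):
        obs = simulate_brood_data(0.7, n_broods=10, stage_span=40,
                                  noise_sd=0.0, seed=0)
        reg = fit_stage_mass_regression(obs)
        assert round(reg.slope, 4) == -0.0071

    def test_deterministic(self):
        a = simulate_brood_data(2.0, seed=5)
        b = simulate_brood_data(2.0, seed=5)
        assert a.equals(b)
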