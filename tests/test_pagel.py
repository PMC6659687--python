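import math

import numpy as np
import pytest
from scipy.integrate import quad

from matrophylo import mk, pagel
from matrophylo._mcmc import mc_se
from matrophylo.pagel import (PagelDependentModel, PagelIndependentModel,
                              RJConfig, bayes_factor, dependent_loglik,
                              encode_joint_states, independent_loglik,
                              rjmcmc_sample, stepping_stone_ml, z_scores,
                              _indep_to_dep)
from matrophylo.simulate import (decode_joint_states, simulate_bd_tree,
                                 simulate_dependent_traits)
from matrophylo.trees import TimeTree

from _oracles import enum_loglik
from conftest import random_topology


@pytest.fixture
def small_data(three_tip):
    return encode_joint_states({"A": 0, "B": 1, "C": 1},
                               {"A": 0, "B": 0, "C": 1})


class TestEncoding:
    def test_state_enumeration(self):
        data = encode_joint_states({"w": 0, "x": 0, "y": 1, "z": 1},
                                   {"w": 0, "x": 1, "y": 0, "z": 1})
        assert data == {"w": 1, "x": 2, "y": 3, "z": 4}

    def test_missing_species_excluded(self):
        data = encode_joint_states({"a": 1, "b": 1}, {"a": math.nan, "b": 0})
        assert data == {"b": 3}

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            encode_joint_states({"a": 2}, {"a": 0})


class TestLikelihoods:
    def test_zero_rates_uniform_root(self, three_tip):
        data = {"A": 1, "B": 1, "C": 1}
        model = PagelDependentModel(np.zeros(8))
        assert dependent_loglik(three_tip, data, model) == \
            pytest.approx(np.log(0.25))

    def test_independent_embedding_nests_in_dependent(self, three_tip,
                                                      small_data):
        ind = PagelIndependentModel([0.5, 0.3, 0.8, 0.2])
        dep = PagelDependentModel(_indep_to_dep(ind.rates))
        assert independent_loglik(three_tip, small_data, ind) == \
            pytest.approx(dependent_loglik(three_tip, small_data, dep),
                          abs=1e-12)

    def test_independent_factorizes_into_two_prunings(self):
        rng = np.random.default_rng(3)
        tree = random_topology(rng, 6)
        t1 = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        t2 = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        data = encode_joint_states(t1, t2)
        a1, b1, a2, b2 = 0.4, 0.6, 0.9, 0.3
        lli = independent_loglik(tree, data, PagelIndependentModel([a1, b1, a2, b2]))
        prod = (mk.mk_loglik(tree, t1, mk.MkModel.ard([a1, b1]))
                + mk.mk_loglik(tree, t2, mk.MkModel.ard([a2, b2])))
        assert lli == pytest.approx(prod, abs=1e-10)

    def test_constant_second_trait_decomposes(self, three_tip):
        t1 = {"A": 0, "B": 1, "C": 1}
        t2 = {"A": 0, "B": 0, "C": 0}
        data = encode_joint_states(t1, t2)
        model = PagelIndependentModel([0.5, 0.3, 0.2, 0.7])
        lli = independent_loglik(three_tip, data, model)
        expected = (mk.mk_loglik(three_tip, t1, mk.MkModel.ard([0.5, 0.3]))
                    + mk.mk_loglik(three_tip, t2, mk.MkModel.ard([0.2, 0.7])))
        assert lli == pytest.approx(expected, abs=1e-10)

    def test_dependent_matches_enumeration(self, three_tip, small_data):
        rng = np.random.default_rng(9)
        for _ in range(5):
            rates = rng.uniform(0.05, 1.5, size=8)
            model = PagelDependentModel(rates)
            ll = dependent_loglik(three_tip, small_data, model)
            zero_based = {sp: s - 1 for sp, s in small_data.items()}
            oracle = enum_loglik(three_tip, zero_based, model.Q,
                                 np.full(4, 0.25))
            assert ll == pytest.approx(oracle, abs=1e-10)


class TestRJMCMC:
    def test_prior_recovery_without_likelihood(self):
        """With the likelihood off the sampler must reproduce the marginal
        prior: rates ~ Exp(mean m), m ~ U(0, 20), so E[rate] = 10."""
        cfg = RJConfig(n_iter=80_000, burnin=4_000, thin=20, n_chains=2,
                       rj=False)
        post = rjmcmc_sample(None, None, "independent", cfg, seed=42)
        for j in range(4):
            x = post.rates[:, j]
            assert abs(x.mean() - 10.0) <= 3 * mc_se(x)
        assert abs(post.hyper_mean.mean() - 10.0) <= 3 * mc_se(post.hyper_mean)

    def test_posterior_mean_matches_quadrature(self, three_tip, small_data):
        m0 = 1.0
        cfg = RJConfig(n_iter=40_000, burnin=2_000, thin=10, n_chains=2,
                       rj=False, tie_all_rates=True, fixed_prior_mean=m0)
        post = rjmcmc_sample(three_tip, small_data, "dependent", cfg, seed=7)
        base = pagel._make_loglik(three_tip, small_data, "dependent", "uniform")

        def integrand(q, weight):
            return weight(q) * np.exp(base(np.repeat(q, 8)) - q / m0)

        z = quad(lambda q: integrand(q, lambda _: 1.0), 0, 50, limit=200)[0]
        mean = quad(lambda q: integrand(q, lambda v: v), 0, 50, limit=200)[0] / z
        x = post.rates[:, 0]
        assert abs(x.mean() - mean) <= 3 * mc_se(x)

    def test_triplicate_chains_agree(self):
        tree, _ = simulate_bd_tree(0.3, 0.0, ("n_tips", 30), seed=2)
        model = PagelDependentModel(_indep_to_dep([0.15, 0.1, 0.2, 0.1]))
        data, _ = simulate_dependent_traits(tree, model, 1, seed=3)
        cfg = RJConfig(n_iter=20_000, burnin=2_000, thin=20, n_chains=3,
                       rj=False)
        post = rjmcmc_sample(tree, data, "independent", cfg, seed=5)
        for j in range(4):
            means, ses = [], []
            for c in range(3):
                x = post.rates[post.chain_id == c, j]
                means.append(x.mean())
                ses.append(mc_se(x))
            for a in range(3):
                for b in range(a + 1, 3):
                    joint_se = math.hypot(ses[a], ses[b])
                    assert abs(means[a] - means[b]) <= 4 * joint_se

    def test_zero_bin_samples_are_exact_zeros(self, three_tip, small_data):
        cfg = RJConfig(n_iter=20_000, burnin=1_000, thin=10, n_chains=1)
        post = rjmcmc_sample(three_tip, small_data, "dependent", cfg, seed=1)
        assert post.in_zero_bin.any()
        assert np.all(post.rates[post.in_zero_bin] == 0.0)


class TestSteppingStone:
    def test_constant_likelihood_exact(self):
        est = stepping_stone_ml(None, None, "independent", n_stones=10,
                                iters_per_stone=50, seed=0)
        assert est.log_ml == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_one_rate(self, three_tip, small_data):
        base = pagel._make_loglik(three_tip, small_data, "independent",
                                  "uniform")
        truth = np.log(quad(lambda q: np.exp(base(np.repeat(q, 4)) - q), 0,
                            60, limit=200)[0])
        est = stepping_stone_ml(three_tip, small_data, "independent",
                                n_stones=30, iters_per_stone=500, seed=3,
                                fixed_prior_mean=1.0, tie_all_rates=True)
        assert abs(est.log_ml - truth) < 0.1

    def test_repeat_runs_within_error(self, three_tip, small_data):
        kw = dict(n_stones=20, iters_per_stone=300, fixed_prior_mean=1.0,
                  tie_all_rates=True)
        a = stepping_stone_ml(three_tip, small_data, "independent", seed=1, **kw)
        b = stepping_stone_ml(three_tip, small_data, "independent", seed=2, **kw)
        assert abs(a.log_ml - b.log_ml) < max(3 * math.hypot(a.se, b.se), 0.15)


class TestBayesFactor:
    @pytest.mark.parametrize("delta,bf,label", [
        (3.0, 6.0, "strong"),
        (0.0, 0.0, "none"),
        (5.5, 11.0, "very strong"),
        (1.5, 3.0, "positive"),
        (0.9, 1.8, "none"),
    ])
    def test_thresholds(self, delta, bf, label):
        out = bayes_factor(delta, 0.0, "dep", "ind")
        assert out["bf"] == pytest.approx(bf)
        assert out["evidence"] == label

    def test_winner_and_symmetry(self):
        out = bayes_factor(-2.0, 1.0, "dep", "ind")
        assert out["winner"] == "ind"
        assert out["bf"] == pytest.approx(6.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("nan"), 0.0)


class TestZScores:
    def _posterior(self, zero_mask, rates):
        n, r = rates.shape
        return pagel.RJPosterior("dependent", pagel.DEP_RATE_NAMES[:r], rates,
                                 zero_mask, np.full(n, 5.0), np.zeros(n),
                                 np.zeros(n, dtype=int), RJConfig(), 0, {})

    def test_percentage_of_zero_samples(self):
        rng = np.random.default_rng(0)
        rates = rng.exponential(1.0, size=(100, 2))
        mask = np.zeros((100, 2), dtype=bool)
        mask[:30, 0] = True
        rates[mask] = 0.0
        tab = z_scores(self._posterior(mask, rates))
        assert tab.loc["q12", "Z"] == pytest.approx(30.0)
        assert not tab.loc["q12", "supported"]

    @pytest.mark.parametrize("z,supported", [(1, True), (80, False)])
    def test_support_rule(self, z, supported):
        n = 200
        mask = np.zeros((n, 1), dtype=bool)
        mask[: int(n * z / 100), 0] = True
        rates = np.ones((n, 1))
        rates[mask] = 0.0
        tab = z_scores(self._posterior(mask, rates))
        assert bool(tab.loc["q12", "supported"]) is supported

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            z_scores(self._posterior(np.zeros((50, 1), dtype=bool),
                                     np.ones((50, 1))))


def test_contingent_evolution_detected_by_bayes_factor():
    """Traits simulated with strongly contingent gains should favor the
    dependent model (BF > 2) in most replicates; independently simulated
    traits should rarely do so."""
    n_rep = 6
    dep_wins = ind_wins = 0
    for s in range(n_rep):
        tree, _ = simulate_bd_tree(0.4, 0.0, ("n_tips", 120), seed=300 + s)
        scale = 1.0 / tree.tip_depths().mean()
        # trait2 gains almost exclusively on the trait1-present background
        contingent = PagelDependentModel(np.array(
            [0.02, 0.8, 0.3, 0.8, 0.3, 3.0, 0.3, 0.3]) * scale)
        data, _ = simulate_dependent_traits(tree, contingent, 1, seed=400 + s)
        kw = dict(n_stones=20, iters_per_stone=300, fixed_prior_mean=2 * scale)
        dep = stepping_stone_ml(tree, data, "dependent", seed=s, **kw)
        ind = stepping_stone_ml(tree, data, "independent", seed=s + 50, **kw)
        if bayes_factor(dep, ind, "dep", "ind")["winner"] == "dep" and \
                bayes_factor(dep, ind)["bf"] > 2:
            dep_wins += 1
        indep = PagelIndependentModel(np.array([0.5, 0.3, 0.5, 0.3]) * scale)
        data2, _ = simulate_dependent_traits(
            tree, PagelDependentModel(_indep_to_dep(indep.rates)), 1,
            seed=500 + s)
        dep2 = stepping_stone_ml(tree, data2, "dependent", seed=s + 100, **kw)
        ind2 = stepping_stone_ml(tree, data2, "independent", seed=s + 150, **kw)
        bf2 = bayes_factor(dep2, ind2, "dep", "ind")
        if bf2["winner"] == "dep" and bf2["bf"] > 2:
            ind_wins += 1
    assert dep_wins >= math.ceil(0.7 * n_rep)
    assert ind_wins <= math.floor(0.34 * n_rep)
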