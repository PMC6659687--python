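"""Correlated evolution of two binary traits (Discrete-style models).

Two binary traits define four joint states, numbered 1=(0,0), 2=(0,1),
3=(1,0), 4=(1,1); trait 1 is conventionally the female trait (e.g.
placentotrophy) and trait 2 the male trait.  Under the *independent* model
each trait gains and loses on its own 2-state chain (four free rates);
under the *dependent* model each single-trait transition rate may depend
on the background state of the other trait (eight free rates
q12,q13,q21,q24,q31,q34,q42,q43).  Dual transitions - both traits changing
in the same instant - have rate zero in both models, the standard Discrete
formulation.

Inference is Bayesian: reversible-jump MCMC in which each rate can be
pinned exactly to zero (the "zero bin"), an exponential rate prior whose
mean is itself sampled from a U(0, 20) hyperprior, stepping-stone marginal
likelihoods for model comparison via Bayes factors, and Z-scores (the
percentage of posterior models in which a rate is zero) to read off
supported evolutionary pathways.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _pruning
from ._mcmc import effective_sample_size, mc_se
from .mk import tip_partials_matrix
from .trees import TimeTree, prune_to_taxa

logger = logging.getLogger(__name__)

__all__ = [
    "JOINT_STATES",
    "DEP_RATE_NAMES",
    "INDEP_RATE_NAMES",
    "PagelDependentModel",
    "PagelIndependentModel",
    "RJConfig",
    "RJPosterior",
    "MarginalLikelihoodEstimate",
    "encode_joint_states",
    "dependent_loglik",
    "independent_loglik",
    "rjmcmc_sample",
    "stepping_stone_ml",
    "bayes_factor",
    "z_scores",
]

# joint state index (1-based) -> (trait1, trait2)
JOINT_STATES = {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}
DEP_RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")
INDEP_RATE_NAMES = ("alpha1", "beta1", "alpha2", "beta2")


def _dep_Q(rates: Sequence[float]) -> np.ndarray:
    q12, q13, q21, q24, q31, q34, q42, q43 = rates
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = q12, q13
    Q[1, 0], Q[1, 3] = q21, q24
    Q[2, 0], Q[2, 3] = q31, q34
    Q[3, 1], Q[3, 2] = q42, q43
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _indep_to_dep(rates: Sequence[float]) -> np.ndarray:
    """Embed (alpha1,beta1,alpha2,beta2) into the 8 dependent-model rates."""
    a1, b1, a2, b2 = rates
    #            q12 q13 q21 q24 q31 q34 q42 q43
    return np.array([a2, a1, b2, a1, b1, a2, b1, b2])


@dataclasses.dataclass
class PagelDependentModel:
    """Eight-rate joint chain; dual transitions fixed at zero."""

    rates: np.ndarray  # order DEP_RATE_NAMES

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (8,) or np.any(self.rates < 0):
            raise ValueError("need 8 nonnegative rates")

    @property
    def Q(self) -> np.ndarray:
        return _dep_Q(self.rates)


@dataclasses.dataclass
class PagelIndependentModel:
    """Each trait on its own 2-state chain: gains alpha, losses beta."""

    rates: np.ndarray  # (alpha1, beta1, alpha2, beta2)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (4,) or np.any(self.rates < 0):
            raise ValueError("need 4 nonnegative rates")

    @property
    def Q(self) -> np.ndarray:
        return _dep_Q(_indep_to_dep(self.rates))


def encode_joint_states(trait1: Mapping, trait2: Mapping) -> dict:
    """Map two binary trait dicts to joint states 1-4.

    Species missing either trait are excluded (logged), mirroring the
    removal of species lacking paired male and female data.
    """
    def ok(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    out = {}
    dropped = []
    for sp in set(trait1) | set(trait2):
        a, b = trait1.get(sp), trait2.get(sp)
        if not (ok(a) and ok(b)):
            dropped.append(sp)
            continue
        a, b = int(a), int(b)
        if a not in (0, 1) or b not in (0, 1):
            raise ValueError(f"{sp}: traits must be binary, got ({a}, {b})")
        out[sp] = 1 + 2 * a + b
    if dropped:
        logger.info("excluded %d species lacking paired trait data", len(dropped))
    return out


def _joint_partials(tree: TimeTree, data: Mapping) -> np.ndarray:
    zero_based = {sp: s - 1 for sp, s in data.items()}
    return tip_partials_matrix(tree, zero_based, (0, 1, 2, 3))


def _pruned(tree: TimeTree, data: Mapping) -> TimeTree:
    keep = set(data) & set(tree.tip_labels)
    if keep != set(tree.tip_labels):
        tree = prune_to_taxa(tree, keep)
    return tree


def dependent_loglik(tree: TimeTree, data: Mapping,
                     model: PagelDependentModel, root="uniform") -> float:
    """4-state pruning log-likelihood under the dependent model."""
    tree = _pruned(tree, data)
    return _pruning.prune_loglik(tree, model.Q, _joint_partials(tree, data), root)


def independent_loglik(tree: TimeTree, data: Mapping,
                       model: PagelIndependentModel, root="uniform") -> float:
    """Independent-model log-likelihood via its 4-state embedding.

    Equals the sum of the two separate 2-state prunings under a matching
    (uniform-per-trait) root.
    """
    tree = _pruned(tree, data)
    return _pruning.prune_loglik(tree, model.Q, _joint_partials(tree, data), root)


# -- reversible-jump MCMC --------------------------------------------------


@dataclasses.dataclass
class RJConfig:
    """Desk-scale defaults; `paper_scale` preserves the published run length."""

    n_iter: int = 2_000_000
    burnin: int = 100_000
    thin: int = 200
    n_chains: int = 3
    rj: bool = True
    hyperprior_max: float = 20.0
    hierarchical: bool = True     # hyperprior mean re-sampled along the chain
    fixed_prior_mean: float | None = None
    proposal_sd: float = 0.6      # log-scale rate proposal
    m_proposal_sd: float = 1.5
    root: object = "uniform"
    ess_threshold: float = 1000.0
    tie_all_rates: bool = False  # single shared rate (validation runs)

    @classmethod
    def paper_scale(cls) -> "RJConfig":
        return cls(n_iter=400_000_000, burnin=500_000, thin=200_000)


@dataclasses.dataclass
class RJPosterior:
    model_family: str
    rate_names: tuple
    rates: np.ndarray       # (n_samples, R); exact zeros where zero-binned
    in_zero_bin: np.ndarray  # (n_samples, R) bool
    hyper_mean: np.ndarray  # (n_samples,)
    loglik: np.ndarray
    chain_id: np.ndarray
    config: RJConfig
    seed: int
    ess: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=list(self.rate_names))
        df.insert(0, "chain", self.chain_id)
        df["hyper_mean"] = self.hyper_mean
        df["loglik"] = self.loglik
        return df


def _family_rate_names(model_family: str) -> tuple:
    if model_family == "dependent":
        return DEP_RATE_NAMES
    if model_family == "independent":
        return INDEP_RATE_NAMES
    raise ValueError("model_family must be 'independent' or 'dependent'")


def _make_loglik(tree, data, model_family, root):
    """Return rates -> loglik closure (rates in family order)."""
    if tree is None or data is None:
        return lambda rates: 0.0
    tree = _pruned(tree, data)
    tp = _joint_partials(tree, data)
    if model_family == "dependent":
        def f(rates):
            return _pruning.prune_loglik(tree, _dep_Q(rates), tp, root)
    else:
        def f(rates):
            return _pruning.prune_loglik(tree, _dep_Q(_indep_to_dep(rates)), tp, root)
    return f


def _exp_logpdf(x, mean):
    return -np.log(mean) - x / mean


def rjmcmc_sample(tree: TimeTree | None, data: Mapping | None,
                  model_family: str, config: RJConfig | None = None,
                  seed: int = 0) -> RJPosterior:
    """Reversible-jump MCMC over transition rates.

    Moves: multiplicative update of one free rate; a jump toggling a rate
    between the zero bin and a fresh value drawn from the exponential prior
    (prior-as-proposal, so the jump acceptance is the bare likelihood
    ratio under a uniform prior over zero-bin configurations); and a
    random-walk update of the exponential prior mean on (0, hyperprior_max).
    Passing ``tree=None``/``data=None`` switches the likelihood off, which
    samples the prior (used for validation).

    Chains run in replicate (``config.n_chains``); low effective sample
    sizes are warned about, never fatal.
    """
    config = config or RJConfig()
    names = _family_rate_names(model_family)
    base_loglik = _make_loglik(tree, data, model_family, config.root)
    if config.tie_all_rates:
        n_full = len(names)
        names = ("q_shared",)
        loglik = lambda r: base_loglik(np.repeat(r, n_full))
    else:
        loglik = base_loglik
    R = len(names)

    all_rates, all_zero, all_m, all_ll, all_chain = [], [], [], [], []
    for chain in range(config.n_chains):
        rng = np.random.default_rng((seed, chain))
        if config.fixed_prior_mean is not None:
            m = config.fixed_prior_mean
        else:
            m = rng.uniform(0, config.hyperprior_max)
        free = np.ones(R, dtype=bool)
        r = rng.exponential(m, size=R)
        ll = loglik(r)
        for it in range(config.n_iter):
            u = rng.random()
            if config.rj and u < 0.3:
                i = rng.integers(R)
                if free[i]:
                    r2 = r.copy()
                    r2[i] = 0.0
                    ll2 = loglik(r2)
                    if np.log(rng.random()) < ll2 - ll:
                        r, ll = r2, ll2
                        free[i] = False
                else:
                    r2 = r.copy()
                    r2[i] = rng.exponential(m)
                    ll2 = loglik(r2)
                    if np.log(rng.random()) < ll2 - ll:
                        r, ll = r2, ll2
                        free[i] = True
            elif u < 0.9 and free.any():
                i = rng.choice(np.flatnonzero(free))
                prop = r[i] * np.exp(config.proposal_sd * rng.standard_normal())
                r2 = r.copy()
                r2[i] = prop
                ll2 = loglik(r2)
                log_acc = (ll2 - ll
                           + _exp_logpdf(prop, m) - _exp_logpdf(r[i], m)
                           + np.log(prop) - np.log(r[i]))
                if np.log(rng.random()) < log_acc:
                    r, ll = r2, ll2
            elif config.hierarchical and config.fixed_prior_mean is None:
                m2 = m + config.m_proposal_sd * rng.standard_normal()
                if 0 < m2 < config.hyperprior_max:
                    log_acc = sum(_exp_logpdf(r[j], m2) - _exp_logpdf(r[j], m)
                                  for j in np.flatnonzero(free))
                    if np.log(rng.random()) < log_acc:
                        m = m2
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                all_rates.append(r.copy())
                all_zero.append(~free.copy())
                all_m.append(m)
                all_ll.append(ll)
                all_chain.append(chain)

    rates = np.array(all_rates)
    post = RJPosterior(model_family, names, rates,
                       np.array(all_zero), np.array(all_m), np.array(all_ll),
                       np.array(all_chain), config, seed,
                       ess={})
    for j, nm in enumerate(names):
        post.ess[nm] = effective_sample_size(rates[:, j])
    post.ess["hyper_mean"] = effective_sample_size(post.hyper_mean)
    low = {k: v for k, v in post.ess.items() if v < config.ess_threshold}
    if low:
        logger.warning("effective sample sizes below %.0f: %s",
                       config.ess_threshold,
                       {k: round(v) for k, v in low.items()})
    return post


# -- stepping-stone marginal likelihood ------------------------------------


@dataclasses.dataclass
class MarginalLikelihoodEstimate:
    log_ml: float
    n_stones: int
    iters_per_stone: int
    per_stone: np.ndarray   # log contribution per stone
    se: float
    model_family: str


def stepping_stone_ml(tree: TimeTree | None, data: Mapping | None,
                      model_family: str, n_stones: int = 200,
                      iters_per_stone: int = 2000, seed: int = 0,
                      alpha: float = 0.3, fixed_prior_mean: float | None = None,
                      hyperprior_max: float = 20.0, tie_all_rates: bool = False,
                      proposal_sd: float = 0.6, root="uniform") -> MarginalLikelihoodEstimate:
    """Stepping-stone estimate of the log marginal likelihood.

    The power-posterior path uses Beta(alpha, 1)-quantile spacing
    beta_k = (k/K)^(1/alpha), which concentrates stones near the prior
    where the integrand varies fastest.  Each stone's chain is warm-started
    from the previous one; the prior stone (beta = 0) is sampled iid.
    ``tie_all_rates`` collapses the family to a single shared rate (used
    for one-dimensional validation against quadrature).
    """
    names = _family_rate_names(model_family)
    R = 1 if tie_all_rates else len(names)

    def expand(r):
        return np.repeat(r, len(names)) if tie_all_rates else r

    base_loglik = _make_loglik(tree, data, model_family, root)
    loglik = (lambda r: base_loglik(expand(r)))

    rng = np.random.default_rng(seed)
    betas = (np.arange(n_stones + 1) / n_stones) ** (1.0 / alpha)

    def draw_prior():
        m = (fixed_prior_mean if fixed_prior_mean is not None
             else rng.uniform(0, hyperprior_max))
        return m, rng.exponential(m, size=R)

    m, r = draw_prior()
    ll = loglik(r)
    per_stone = np.zeros(n_stones)
    per_stone_se = np.zeros(n_stones)
    for k in range(n_stones):
        b0, b1 = betas[k], betas[k + 1]
        lls = np.empty(iters_per_stone)
        for it in range(iters_per_stone):
            if b0 == 0.0:
                m2, r2 = draw_prior()
                ll2 = loglik(r2)
                m, r, ll = m2, r2, ll2  # iid prior draws
            else:
                i = int(rng.integers(R))
                prop = r[i] * np.exp(proposal_sd * rng.standard_normal())
                r2 = r.copy()
                r2[i] = prop
                ll2 = loglik(r2)
                log_acc = (b0 * (ll2 - ll)
                           + _exp_logpdf(prop, m) - _exp_logpdf(r[i], m)
                           + np.log(prop) - np.log(r[i]))
                if np.log(rng.random()) < log_acc:
                    r, ll = r2, ll2
                if fixed_prior_mean is None:
                    m2 = m + 1.5 * rng.standard_normal()
                    if 0 < m2 < hyperprior_max:
                        log_acc = sum(_exp_logpdf(r[j], m2) - _exp_logpdf(r[j], m)
                                      for j in range(R))
                        if np.log(rng.random()) < log_acc:
                            m = m2
            lls[it] = ll
        w = (b1 - b0) * lls
        wmax = w.max()
        if not np.isfinite(wmax):
            raise FloatingPointError(f"degenerate stone {k}: infinite weights")
        ew = np.exp(w - wmax)
        per_stone[k] = wmax + np.log(ew.mean())
        per_stone_se[k] = mc_se(ew) / max(ew.mean(), 1e-300)
    return MarginalLikelihoodEstimate(
        log_ml=float(per_stone.sum()),
        n_stones=n_stones, iters_per_stone=iters_per_stone,
        per_stone=per_stone,
        se=float(np.sqrt((per_stone_se ** 2).sum())),
        model_family=model_family)


def bayes_factor(ml_a: MarginalLikelihoodEstimate | float,
                 ml_b: MarginalLikelihoodEstimate | float,
                 name_a: str = "a", name_b: str = "b") -> dict:
    """2*|delta log marginal likelihood| with the conventional evidence labels.

    BF <= 2: no real evidence; 2-5: positive; 5-10: strong; >10 very strong.
    """
    la = ml_a.log_ml if isinstance(ml_a, MarginalLikelihoodEstimate) else float(ml_a)
    lb = ml_b.log_ml if isinstance(ml_b, MarginalLikelihoodEstimate) else float(ml_b)
    if not (np.isfinite(la) and np.isfinite(lb)):
        raise ValueError("marginal likelihoods must be finite")
    delta = la - lb
    bf = 2.0 * abs(delta)
    if bf > 10:
        label = "very strong"
    elif bf > 5:
        label = "strong"
    elif bf > 2:
        label = "positive"
    else:
        label = "none"
    winner = name_a if delta > 0 else (name_b if delta < 0 else "tie")
    return {"bf": bf, "evidence": label, "winner": winner,
            "delta_log_ml": delta}


def z_scores(posterior: RJPosterior, support_threshold: float = 5.0) -> pd.DataFrame:
    """Percentage of posterior samples in which each rate is exactly zero.

    Rates with Z below ``support_threshold`` percent mark supported
    evolutionary pathways (solid arrows in pathway diagrams).
    """
    n = posterior.rates.shape[0]
    if n < 100:
        raise ValueError("need at least 100 retained samples for Z-scores")
    rows = []
    for j, nm in enumerate(posterior.rate_names):
        z = 100.0 * posterior.in_zero_bin[:, j].mean()
        nonzero = posterior.rates[:, j][~posterior.in_zero_bin[:, j]]
        rows.append(dict(rate=nm, Z=z, supported=bool(z < support_threshold),
                         mean=float(posterior.rates[:, j].mean()),
                         mean_nonzero=float(nonzero.mean()) if nonzero.size else 0.0,
                         sd=float(posterior.rates[:, j].std(ddof=1))))
    return pd.DataFrame(rows).set_index("rate")
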