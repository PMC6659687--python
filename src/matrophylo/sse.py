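"""Trait-dependent diversification: BiSSE, MuSSE, and two-trait main-effects models.

A k-state SSE model couples a continuous-time Markov character (transition
rates q_ij) to a birth-death process whose speciation (lambda_i) and
extinction (mu_i) rates depend on the character state.  The likelihood on
an ultrametric tree integrates the standard coupled ODEs for E_i(t) (the
probability a lineage in state i leaves no sampled descendants) and
D_i(t) (the data likelihood) backward along every branch, multiplies
daughter likelihoods by lambda at nodes, and weights root states by their
share of the data likelihood (FitzJohn weighting) with conditioning on
survival of the two root lineages.  Incomplete sampling enters through a
global sampling fraction f via the tip conditions D = f * 1[state],
E(0) = 1 - f.

The two-trait "main effects" model expresses the four joint-state rates
as lambda(a,b) = lambda0 + a*lambdaA + b*lambdaB (same for mu) with four
single-trait transition rates and no dual transitions: 10 free parameters
that separate each trait's marginal association with diversification.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _sse_core
from .mk import tip_partials_matrix
from .trees import TimeTree, check_ultrametric, prune_to_taxa

logger = logging.getLogger(__name__)

__all__ = [
    "SSEParams",
    "MultiTraitSSEParams",
    "SSEModelSpec",
    "SSEFit",
    "SSEPosterior",
    "bisse_loglik",
    "musse_loglik",
    "multitrait_sse_loglik",
    "bisse_spec",
    "musse_spec",
    "multitrait_spec",
    "fit_sse_ml",
    "likelihood_ratio_test",
    "sse_mcmc",
    "net_diversification",
    "sampling_fraction",
    "encode_two_traits",
]

_ROOT_MODES = {"fitzjohn": _sse_core.ROOT_FITZJOHN, "equal": _sse_core.ROOT_EQUAL}


@dataclasses.dataclass
class SSEParams:
    """Per-state speciation/extinction rates, transition matrix, sampling fraction."""

    lam: np.ndarray
    mu: np.ndarray
    Q: np.ndarray   # off-diagonal transition rates; diagonal ignored
    f: float = 1.0

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.lam)
        if len(self.mu) != k or self.Q.shape != (k, k):
            raise ValueError("inconsistent parameter dimensions")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(self.lam < 0) or np.any(self.mu < 0) or np.any(off < 0):
            raise ValueError("rates must be nonnegative")
        if not (0 < self.f <= 1):
            raise ValueError("sampling fraction must be in (0, 1]")

    @property
    def k(self) -> int:
        return len(self.lam)

    def net_diversification(self) -> np.ndarray:
        return self.lam - self.mu


@dataclasses.dataclass
class MultiTraitSSEParams:
    """Additive main-effects parameterization over two binary traits.

    Implied joint-state rates lambda(a,b) = lambda0 + a*lambdaA + b*lambdaB
    (likewise mu) must be nonnegative over all four states.
    """

    lambda0: float
    lambdaA: float
    lambdaB: float
    mu0: float
    muA: float
    muB: float
    qA01: float
    qA10: float
    qB01: float
    qB10: float
    f: float = 1.0

    # joint states ordered (a,b) = (0,0), (0,1), (1,0), (1,1)
    STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

    def expand(self) -> SSEParams:
        lam = np.array([self.lambda0 + a * self.lambdaA + b * self.lambdaB
                        for a, b in self.STATES])
        mu = np.array([self.mu0 + a * self.muA + b * self.muB
                       for a, b in self.STATES])
        if np.any(lam < 0) or np.any(mu < 0):
            raise ValueError("main effects imply a negative per-state rate")
        Q = np.zeros((4, 4))
        for i, (a, b) in enumerate(self.STATES):
            for j, (a2, b2) in enumerate(self.STATES):
                if a != a2 and b != b2:
                    continue  # dual transitions excluded
                if a != a2:
                    Q[i, j] = self.qA01 if a == 0 else self.qA10
                elif b != b2:
                    Q[i, j] = self.qB01 if b == 0 else self.qB10
        return SSEParams(lam, mu, Q, f=self.f)


def _require_ultrametric(tree: TimeTree, rel_tol: float = 1e-4):
    ok, dev = check_ultrametric(tree, rel_tol)
    if not ok:
        raise ValueError(f"SSE likelihood needs an ultrametric tree "
                         f"(max relative depth deviation {dev:.3g})")


def _sse_loglik(tree: TimeTree, tip_states: Mapping, params: SSEParams,
                states: Sequence, root: object, condition_on_survival: bool,
                steps_mult: float) -> float:
    _require_ultrametric(tree)
    tp = tip_partials_matrix(tree, tip_states, states)
    Qoff = params.Q.copy()
    np.fill_diagonal(Qoff, 0.0)
    if isinstance(root, str):
        mode = _ROOT_MODES[root]
        vec = np.zeros(params.k)
    else:
        mode = _sse_core.ROOT_GIVEN
        vec = np.asarray(root, dtype=float)
        vec = vec / vec.sum()
    return float(_sse_core.sse_loglik_kernel(
        tree.postorder, tree.children, tree.edge_length, tree.n_tips,
        tp, params.lam, params.mu, Qoff, float(params.f), float(steps_mult),
        mode, condition_on_survival, vec))


def bisse_loglik(tree: TimeTree, tip_states: Mapping, params: SSEParams,
                 root="fitzjohn", condition_on_survival: bool = True,
                 steps_mult: float = 1.0) -> float:
    """Binary-state speciation/extinction log-likelihood (6 parameters)."""
    if params.k != 2:
        raise ValueError("bisse_loglik needs 2-state parameters")
    return _sse_loglik(tree, tip_states, params, (0, 1), root,
                       condition_on_survival, steps_mult)


def musse_loglik(tree: TimeTree, tip_states: Mapping, params: SSEParams,
                 root="fitzjohn", condition_on_survival: bool = True,
                 steps_mult: float = 1.0) -> float:
    """k-state generalization; for k = 4 the model has 4+4+12 = 20 free rates."""
    if params.k < 2:
        raise ValueError("need at least 2 states")
    return _sse_loglik(tree, tip_states, params, tuple(range(params.k)), root,
                       condition_on_survival, steps_mult)


def encode_two_traits(traitA: Mapping, traitB: Mapping) -> dict:
    """Joint 0-3 coding over (a,b) pairs, ordered (0,0),(0,1),(1,0),(1,1)."""
    out = {}
    for sp in set(traitA) & set(traitB):
        a, b = traitA[sp], traitB[sp]
        if a is None or b is None or (isinstance(a, float) and np.isnan(a)) \
                or (isinstance(b, float) and np.isnan(b)):
            continue
        out[sp] = 2 * int(a) + int(b)
    return out


def multitrait_sse_loglik(tree: TimeTree, traitA: Mapping, traitB: Mapping,
                          params: MultiTraitSSEParams, root="fitzjohn",
                          condition_on_survival: bool = True,
                          steps_mult: float = 1.0) -> float:
    """Main-effects model likelihood via expansion to a 4-state MuSSE."""
    joint = encode_two_traits(traitA, traitB)
    keep = set(joint) & set(tree.tip_labels)
    if keep != set(tree.tip_labels):
        tree = prune_to_taxa(tree, keep)
    return musse_loglik(tree, joint, params.expand(), root,
                        condition_on_survival, steps_mult)


# -- declarative model specs and ML fitting --------------------------------


@dataclasses.dataclass
class SSEModelSpec:
    """Names the free parameters of an SSE model and any tying/fixing.

    ``constraints`` are strings: ``"lambda1==lambda0"`` ties a parameter to
    another; ``"muA==0"`` (or any float) fixes it.  Rate-type parameters
    are optimized on a log scale; main-effect deltas are unbounded.
    """

    kind: str                 # bisse | musse | multitrait
    k: int
    param_names: tuple
    constraints: tuple = ()
    f: float = 1.0

    def __post_init__(self):
        self._fixed, self._tied = {}, {}
        for c in self.constraints:
            left, right = (s.strip() for s in c.split("=="))
            if left not in self.param_names:
                raise ValueError(f"unknown parameter {left!r}")
            try:
                self._fixed[left] = float(right)
            except ValueError:
                if right not in self.param_names:
                    raise ValueError(f"unknown parameter {right!r}")
                self._tied[left] = right

    @property
    def free_names(self) -> tuple:
        return tuple(p for p in self.param_names
                     if p not in self._fixed and p not in self._tied)

    def n_free(self) -> int:
        return len(self.free_names)

    def is_delta(self, name: str) -> bool:
        return self.kind == "multitrait" and name in (
            "lambdaA", "lambdaB", "muA", "muB")

    def full_dict(self, free_values: Mapping) -> dict:
        d = dict(self._fixed)
        for nm in self.free_names:
            d[nm] = float(free_values[nm])
        for nm, ref in self._tied.items():
            if ref in self._tied:
                raise ValueError("chained ties are not supported")
            d[nm] = d[ref]
        return d

    def build(self, free_values: Mapping):
        d = self.full_dict(free_values)
        if self.kind == "multitrait":
            return MultiTraitSSEParams(f=self.f, **d)
        k = self.k
        lam = np.array([d[f"lambda{i}"] for i in range(k)])
        mu = np.array([d[f"mu{i}"] for i in range(k)])
        Q = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = d[f"q{i}{j}"]
        return SSEParams(lam, mu, Q, f=self.f)


def bisse_spec(constraints=(), f: float = 1.0) -> SSEModelSpec:
    return SSEModelSpec("bisse", 2,
                        ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"),
                        tuple(constraints), f)


def musse_spec(k: int, constraints=(), f: float = 1.0) -> SSEModelSpec:
    names = tuple([f"lambda{i}" for i in range(k)]
                  + [f"mu{i}" for i in range(k)]
                  + [f"q{i}{j}" for i in range(k) for j in range(k) if i != j])
    return SSEModelSpec("musse", k, names, tuple(constraints), f)


def multitrait_spec(constraints=(), f: float = 1.0) -> SSEModelSpec:
    return SSEModelSpec("multitrait", 4,
                        ("lambda0", "lambdaA", "lambdaB", "mu0", "muA", "muB",
                         "qA01", "qA10", "qB01", "qB10"),
                        tuple(constraints), f)


@dataclasses.dataclass
class SSEFit:
    spec: SSEModelSpec
    params: dict            # full parameter dict
    loglik: float
    aic: float
    converged: bool
    n_starts_used: int

    def net_diversification(self) -> dict:
        if self.spec.kind == "multitrait":
            p = MultiTraitSSEParams(f=self.spec.f, **self.params).expand()
        else:
            p = self.spec.build(self.params)
        return {f"d{i}": float(v) for i, v in enumerate(p.net_diversification())}


def _spec_loglik_fn(tree, tip_states_or_pair, spec, root, cond_surv, steps_mult):
    if spec.kind == "multitrait":
        a, b = tip_states_or_pair
        joint = encode_two_traits(a, b)
        keep = set(joint) & set(tree.tip_labels)
        if keep != set(tree.tip_labels):
            tree = prune_to_taxa(tree, keep)

        def f(d):
            try:
                p = MultiTraitSSEParams(f=spec.f, **d)
                return musse_loglik(tree, joint, p.expand(), root, cond_surv,
                                    steps_mult)
            except ValueError:
                return -np.inf
    else:
        def f(d):
            try:
                return _sse_loglik(tree, tip_states_or_pair, spec.build(d),
                                   tuple(range(spec.k)), root, cond_surv,
                                   steps_mult)
            except ValueError:
                return -np.inf
    return f


def _heuristic_start(tree: TimeTree, spec: SSEModelSpec) -> dict:
    """Character-independent starting point: Yule-ish speciation estimate."""
    T = tree.tip_depths().mean()
    lam0 = max(np.log(max(tree.n_tips, 3) / 2.0) / T, 1e-4)
    start = {}
    for nm in spec.free_names:
        if nm.startswith("lambda0") or (nm.startswith("lambda") and not spec.is_delta(nm)):
            start[nm] = lam0
        elif nm.startswith("mu") and not spec.is_delta(nm):
            start[nm] = lam0 * 0.2
        elif nm.startswith("q"):
            start[nm] = lam0 * 0.1
        else:  # main-effect deltas
            start[nm] = 0.0
    return start


def fit_sse_ml(tree: TimeTree, tip_states, spec: SSEModelSpec,
               root="fitzjohn", condition_on_survival: bool = True,
               n_starts: int = 3, seed: int = 0, steps_mult: float = 1.0,
               maxiter: int = 200) -> SSEFit:
    """Bounded multistart maximum likelihood for an SSE model spec.

    ``tip_states`` is a species->state mapping, or a ``(traitA, traitB)``
    pair of mappings for the multitrait kind.
    """
    ll_fn = _spec_loglik_fn(tree, tip_states, spec, root,
                            condition_on_survival, steps_mult)
    names = spec.free_names
    start = _heuristic_start(tree, spec)
    rng = np.random.default_rng(seed)

    def pack(d):
        return np.array([d[nm] if spec.is_delta(nm) else np.log(max(d[nm], 1e-9))
                         for nm in names])

    def unpack(x):
        return {nm: (x[i] if spec.is_delta(nm) else float(np.exp(x[i])))
                for i, nm in enumerate(names)}

    def nll(x):
        v = ll_fn(unpack(x))
        return 1e10 if not np.isfinite(v) else -v

    scale = 1.0 / max(tree.tip_depths().mean(), 1e-12)
    bounds = [(None, None) if spec.is_delta(nm)
              else (np.log(1e-7 * scale) - 0.0, np.log(1e3 * scale))
              for nm in names]
    best = None
    used = 0
    for s in range(n_starts):
        x0 = pack(start)
        if s > 0:
            for i, nm in enumerate(names):
                x0[i] += (0.05 * rng.standard_normal() if spec.is_delta(nm)
                          else rng.normal(0, 1.0))
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options=dict(maxiter=maxiter))
        used += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e9:
        raise RuntimeError("SSE optimizer failed from all restarts")
    full = spec.full_dict(unpack(best.x))
    ll = -best.fun
    return SSEFit(spec=spec, params=full, loglik=ll,
                  aic=2 * spec.n_free() - 2 * ll,
                  converged=bool(best.success), n_starts_used=used)


def likelihood_ratio_test(full: SSEFit, constrained: SSEFit) -> dict:
    """Chi-square LRT of nested SSE fits (df = difference in free params)."""
    df = full.spec.n_free() - constrained.spec.n_free()
    if df <= 0:
        raise ValueError("'full' must have more free parameters")
    stat = max(2.0 * (full.loglik - constrained.loglik), 0.0)
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df)),
            "aic_full": full.aic, "aic_constrained": constrained.aic}


# -- Bayesian MCMC ---------------------------------------------------------


@dataclasses.dataclass
class SSEPosterior:
    spec: SSEModelSpec
    samples: pd.DataFrame   # post burn-in, one column per free parameter
    r: float
    n_gen: int
    burnin: int
    seed: int
    acceptance: float

    def credibility_intervals(self, level: float = 0.95) -> dict:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return {c: (float(self.samples[c].quantile(lo)),
                    float(self.samples[c].quantile(hi)))
                for c in self.samples.columns}


def sse_mcmc(tree: TimeTree | None, tip_states, spec: SSEModelSpec,
             r: float, n_gen: int = 10_000, seed: int = 0,
             start: Mapping | None = None, proposal_sd: float = 0.3,
             root="fitzjohn", condition_on_survival: bool = True,
             steps_mult: float = 1.0) -> SSEPosterior:
    """Metropolis sampling of SSE parameters under Exp(rate 1/(2r)) priors.

    ``r`` is the character-independent net diversification rate, so every
    rate's prior mean is 2r.  Main-effect deltas get the same exponential
    log-density without a positivity constraint (their sign is the question
    of interest), subject to the implied per-state rates staying
    nonnegative.  The first 10% of generations are discarded as burn-in.
    ``tree=None`` disables the likelihood (prior sampling, for checks).
    Start from ML estimates (``start``) for well-behaved chains.
    """
    if r <= 0:
        raise ValueError("character-independent diversification rate r must be > 0")
    names = spec.free_names
    if tree is None:
        ll_fn = lambda d: 0.0
    else:
        ll_fn = _spec_loglik_fn(tree, tip_states, spec, root,
                                condition_on_survival, steps_mult)
    prior_mean = 2.0 * r

    def log_prior(d):
        lp = 0.0
        for nm in names:
            v = d[nm]
            if spec.is_delta(nm):
                lp += -abs(v) / prior_mean  # symmetric (Laplace-shaped) on deltas
            else:
                if v < 0:
                    return -np.inf
                lp += -v / prior_mean
        return lp

    rng = np.random.default_rng(seed)
    cur = dict(start) if start is not None else _heuristic_start(tree or TimeTree.from_newick("(A:1,B:1);"), spec)
    cur = {nm: cur.get(nm, prior_mean) for nm in names}
    ll = ll_fn(cur)
    lp = log_prior(cur)
    rows = []
    accepted = proposed = 0
    for g in range(n_gen):
        for nm in names:
            prop = dict(cur)
            if spec.is_delta(nm):
                prop[nm] = cur[nm] + proposal_sd * prior_mean * rng.standard_normal()
                log_hastings = 0.0
            else:
                prop[nm] = cur[nm] * np.exp(proposal_sd * rng.standard_normal())
                log_hastings = np.log(prop[nm]) - np.log(cur[nm])
            lp2 = log_prior(prop)
            if not np.isfinite(lp2):
                proposed += 1
                continue
            ll2 = ll_fn(prop)
            proposed += 1
            if np.log(rng.random()) < (ll2 + lp2) - (ll + lp) + log_hastings:
                cur, ll, lp = prop, ll2, lp2
                accepted += 1
        rows.append(dict(cur, loglik=ll))
    burnin = n_gen // 10
    df = pd.DataFrame(rows[burnin:])
    return SSEPosterior(spec=spec, samples=df, r=r, n_gen=n_gen, burnin=burnin,
                        seed=seed, acceptance=accepted / max(proposed, 1))


def net_diversification(obj, level: float = 0.95):
    """Per-state net diversification d_i = lambda_i - mu_i.

    For an :class:`SSEFit` returns point estimates; for an
    :class:`SSEPosterior` returns posterior means with credibility
    intervals computed elementwise on the lambda - mu samples.
    """
    if isinstance(obj, SSEFit):
        return obj.net_diversification()
    if isinstance(obj, SSEPosterior):
        spec = obj.spec
        out = {}
        k = spec.k if spec.kind != "bisse" else 2
        for i in range(k):
            lam_c, mu_c = f"lambda{i}", f"mu{i}"
            if lam_c in obj.samples.columns and mu_c in obj.samples.columns:
                d = obj.samples[lam_c] - obj.samples[mu_c]
            else:
                continue
            lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
            out[f"d{i}"] = dict(mean=float(d.mean()),
                                median=float(d.median()),
                                ci=(float(d.quantile(lo)), float(d.quantile(hi))))
        return out
    raise TypeError("expected SSEFit or SSEPosterior")


def sampling_fraction(n_scored: int, n_described: int) -> float:
    """Proportion of described species that are scored in the tree."""
    if not (0 < n_scored <= n_described):
        raise ValueError("need 0 < n_scored <= n_described")
    return n_scored / n_described
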