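"""Mk (continuous-time Markov) models of discrete character evolution.

Likelihood by Felsenstein pruning, ML fitting of equal-rates (ER) and
all-rates-different (ARD) generators with AIC model choice, marginal
ancestral-state reconstruction, Fitch/Sankoff parsimony, stochastic
character mapping, and origin/loss counting on reconstructions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from . import _pruning
from .trees import TimeTree

logger = logging.getLogger(__name__)

__all__ = [
    "MkModel",
    "MkFit",
    "AncestralReconstruction",
    "StochasticMapSet",
    "mk_loglik",
    "fit_mk_ml",
    "marginal_ancestral_states",
    "fitch_parsimony",
    "sample_stochastic_maps",
    "count_origins",
    "tip_partials_matrix",
]


@dataclasses.dataclass
class MkModel:
    """A k-state generator with off-diagonal rates >= 0 and zero row sums."""

    states: tuple
    Q: np.ndarray
    model_class: str = "custom"  # ER | ARD | custom
    root_policy: object = "uniform"  # uniform | stationary | fitzjohn | vector

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match number of states")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-12 * max(1.0, np.abs(self.Q).max()):
            raise ValueError("Q rows must sum to 0")

    @classmethod
    def er(cls, rate: float, states=(0, 1), **kw) -> "MkModel":
        k = len(states)
        Q = np.full((k, k), rate, dtype=float)
        np.fill_diagonal(Q, -(k - 1) * rate)
        return cls(tuple(states), Q, model_class="ER", **kw)

    @classmethod
    def ard(cls, rates: np.ndarray, states=(0, 1), **kw) -> "MkModel":
        """rates: flat off-diagonal rates in row-major (i,j), i != j order."""
        k = len(states)
        Q = np.zeros((k, k))
        it = iter(np.asarray(rates, dtype=float))
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(tuple(states), Q, model_class="ARD", **kw)

    @property
    def k(self) -> int:
        return len(self.states)

    def n_free_rates(self) -> int:
        return 1 if self.model_class == "ER" else self.k * (self.k - 1)


def tip_partials_matrix(tree: TimeTree, tip_states: Mapping, states: Sequence) -> np.ndarray:
    """Partial-likelihood rows per tip; missing/None/NaN = fully ambiguous."""
    k = len(states)
    state_pos = {s: i for i, s in enumerate(states)}
    out = np.zeros((tree.n_tips, k))
    for i, lab in enumerate(tree.tip_labels):
        v = tip_states.get(lab, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = 1.0
            continue
        if isinstance(v, float) and v in (0.0, 1.0, 2.0, 3.0):
            v = int(v)
        if v not in state_pos:
            raise KeyError(f"tip {lab}: state {v!r} not in model states {states}")
        out[i, state_pos[v]] = 1.0
    return out


def mk_loglik(tree: TimeTree, tip_states: Mapping, model: MkModel) -> float:
    """Pruning log-likelihood of tip data under ``model``.

    Impossible data (e.g. conflicting states across zero-length edges)
    returns ``-inf`` rather than raising.
    """
    tp = tip_partials_matrix(tree, tip_states, model.states)
    return _pruning.prune_loglik(tree, model.Q, tp, model.root_policy)


@dataclasses.dataclass
class MkFit:
    er: MkModel
    ard: MkModel
    loglik_er: float
    loglik_ard: float
    aic: dict
    selected: str          # "ER" or "ARD"
    selected_model: MkModel


def _optimize_rates(fun, n_par, bounds_log, rng, n_starts, center=0.0):
    best = None
    starts = [center + rng.uniform(np.log(1e-2), np.log(1e1), size=n_par)
              for _ in range(n_starts)]
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="L-BFGS-B",
                                bounds=[bounds_log] * n_par)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Mk optimizer failed to converge from all restarts")
    return best


def fit_mk_ml(tree: TimeTree, tip_states: Mapping, states=None, seed: int = 0,
              n_starts: int = 5, root_policy="uniform") -> MkFit:
    """ML fit of ER and ARD generators; AIC picks the working model.

    Rates are optimized in log space (bounded) with multistart; rate units
    follow the tree's branch-length unit.  With fewer than two observed
    states the rates are unidentifiable and a zero-rate model is returned
    with a warning.
    """
    if states is None:
        observed = sorted({v for v in tip_states.values()
                           if v is not None and not (isinstance(v, float) and np.isnan(v))})
        states = tuple(int(v) if isinstance(v, float) else v for v in observed)
        if len(states) == 1:
            states = tuple(sorted({states[0], 0, 1}))[:2] if states[0] in (0, 1) else states
    k = len(states)
    observed_states = {v for v in tip_states.values()
                       if v is not None and not (isinstance(v, float) and np.isnan(v))}
    tp = tip_partials_matrix(tree, tip_states, states)
    if len(observed_states) < 2:
        logger.warning("fewer than 2 observed states: returning rate-0 ER model")
        er = MkModel.er(0.0, states, root_policy=root_policy)
        ll = _pruning.prune_loglik(tree, er.Q, tp, root_policy)
        return MkFit(er, er, ll, ll, {"ER": 2 - 2 * ll, "ARD": 2 * k * (k - 1) - 2 * ll},
                     "ER", er)

    rate_unit = 0.1 / tree.mean_edge_length()
    bounds_log = (np.log(1e-8 * rate_unit), np.log(1e3 * rate_unit))
    rng = np.random.default_rng(seed)

    def nll_er(x):
        return -_pruning.prune_loglik(tree, MkModel.er(np.exp(x[0]), states).Q,
                                      tp, root_policy)

    def nll_ard(x):
        return -_pruning.prune_loglik(tree, MkModel.ard(np.exp(x), states).Q,
                                      tp, root_policy)

    center = np.log(rate_unit)
    res_er = _optimize_rates(nll_er, 1, bounds_log, rng, n_starts, center)
    res_ard = _optimize_rates(nll_ard, k * (k - 1), bounds_log, rng, n_starts, center)
    er = MkModel.er(float(np.exp(res_er.x[0])), states, root_policy=root_policy)
    ard = MkModel.ard(np.exp(res_ard.x), states, root_policy=root_policy)
    ll_er, ll_ard = -res_er.fun, -res_ard.fun
    aic = {"ER": 2 * 1 - 2 * ll_er, "ARD": 2 * k * (k - 1) - 2 * ll_ard}
    selected = "ER" if aic["ER"] <= aic["ARD"] else "ARD"
    return MkFit(er, ard, ll_er, ll_ard, aic, selected,
                 er if selected == "ER" else ard)


@dataclasses.dataclass
class AncestralReconstruction:
    """Marginal (scaled-likelihood) state posteriors at every node."""

    tree: TimeTree
    states: tuple
    node_probs: np.ndarray  # (n_nodes, k); tips are degenerate at observed states
    model: MkModel
    loglik: float

    def map_states(self, tie_state_index: int = 0) -> np.ndarray:
        """Max-probability state index per node; exact ties -> ``tie_state_index``."""
        p = self.node_probs
        best = p.argmax(axis=1)
        tied = np.isclose(p.max(axis=1), p[:, tie_state_index])
        best[tied] = tie_state_index
        return best

    def to_table(self):
        import pandas as pd
        rows = []
        for i in range(self.tree.n_nodes):
            for j, s in enumerate(self.states):
                rows.append(dict(node_id=i, state=s,
                                 probability=self.node_probs[i, j]))
        return pd.DataFrame(rows)


def marginal_ancestral_states(tree: TimeTree, tip_states: Mapping,
                              model: MkModel) -> AncestralReconstruction:
    tp = tip_partials_matrix(tree, tip_states, model.states)
    probs, ll = _pruning.marginal_node_posteriors(tree, model.Q, tp,
                                                  model.root_policy)
    return AncestralReconstruction(tree, tuple(model.states), probs, model, ll)


def fitch_parsimony(tree: TimeTree, tip_states: Mapping, states=None):
    """Minimum change count and per-node MPR state sets (unit-cost Sankoff).

    Missing tips are treated as fully ambiguous.  Returns
    ``(min_changes, node_state_sets)`` where ``node_state_sets[i]`` is the
    set of states at node ``i`` occurring in at least one most-parsimonious
    reconstruction.
    """
    if states is None:
        states = tuple(sorted({v for v in tip_states.values()
                               if v is not None and not (isinstance(v, float) and np.isnan(v))}))
    k = len(states)
    INF = 1e18
    tp = tip_partials_matrix(tree, tip_states, states)
    down = np.zeros((tree.n_nodes, k))
    down[: tree.n_tips] = np.where(tp > 0, 0.0, INF)
    cost = 1.0 - np.eye(k)  # unit substitution cost

    def msg(child):
        # min over child states of (cost + down cost)
        return (cost + down[child][None, :]).min(axis=1)

    for i in tree.postorder:
        if i < tree.n_tips:
            continue
        l, r = tree.children[i]
        down[i] = msg(l) + msg(r)
    min_changes = float(down[tree.root].min())

    up = np.zeros((tree.n_nodes, k))
    up[tree.root] = 0.0
    for v in tree.preorder:
        if v < tree.n_tips:
            continue
        l, r = tree.children[v]
        for c, b in ((l, r), (r, l)):
            # cost of everything outside c, per state of c
            through_parent = up[v] + msg(b)  # per parent state
            up[c] = (cost.T + through_parent[None, :]).min(axis=1)
    total = down + up
    sets = []
    for i in range(tree.n_nodes):
        m = total[i].min()
        sets.append({states[j] for j in range(k) if total[i, j] <= m + 1e-9})
    return int(round(min_changes)), sets


# -- stochastic character mapping -----------------------------------------


@dataclasses.dataclass
class StochasticMapSet:
    """Posterior sample of full character histories on the tree."""

    tree: TimeTree
    states: tuple
    node_states: np.ndarray        # (n_maps, n_nodes) state indices
    histories: list                # per map: {node_id: [(state_idx, duration), ...]}
    transitions: np.ndarray        # (n_maps, k, k) realized change counts
    uniformization_fallbacks: int

    @property
    def n_maps(self) -> int:
        return self.node_states.shape[0]

    def node_frequencies(self) -> np.ndarray:
        k = len(self.states)
        freq = np.zeros((self.tree.n_nodes, k))
        for j in range(k):
            freq[:, j] = (self.node_states == j).mean(axis=0)
        return freq

    def edge_state_frequencies(self) -> np.ndarray:
        """Mean fraction of each edge's duration spent in each state."""
        k = len(self.states)
        out = np.zeros((self.tree.n_nodes, k))
        for hist in self.histories:
            for node, segs in hist.items():
                tot = sum(d for _, d in segs)
                if tot <= 0:
                    # zero-length edge: attribute to the (single) end state
                    out[node, segs[-1][0]] += 1.0
                    continue
                for s, d in segs:
                    out[node, s] += d / tot
        return out / len(self.histories)

    def change_counts(self) -> np.ndarray:
        """Per-map total number of state changes."""
        return self.transitions.sum(axis=(1, 2))

    def mean_gains_losses(self, gain=(0, 1)) -> tuple:
        """Posterior mean count of gain (0->1) and loss (1->0) events."""
        a, b = gain
        return (float(self.transitions[:, a, b].mean()),
                float(self.transitions[:, b, a].mean()))


def _sample_path_rejection(rng, Q, a, b, t, max_rej=10_000):
    """Endpoint-conditioned CTMC path by (forced-first-jump) rejection."""
    k = Q.shape[0]
    rates = -np.diag(Q)
    for _ in range(max_rej):
        path = [(a, 0.0)]  # (state, time entered)
        s, tau = a, 0.0
        if a != b:
            if rates[a] <= 0:
                break
            u = rng.random()
            tau = -np.log1p(-u * (1 - np.exp(-rates[a] * t))) / rates[a]
            probs = Q[a].copy()
            probs[a] = 0.0
            s = rng.choice(k, p=probs / probs.sum())
            path.append((s, tau))
        while True:
            if rates[s] <= 0:
                break
            tau = tau + rng.exponential(1.0 / rates[s])
            if tau >= t:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            path.append((s, tau))
        if s == b:
            return _segments(path, t), len(path) - 1
    return None


def _segments(path, t):
    segs = []
    for idx, (s, start) in enumerate(path):
        end = path[idx + 1][1] if idx + 1 < len(path) else t
        segs.append((int(s), float(end - start)))
    return segs


def _sample_path_uniformization(rng, Q, a, b, t):
    """Exact endpoint-conditioned path via uniformization (Fearnhead & Sherlock)."""
    k = Q.shape[0]
    R = max(-Q.diagonal().min(), 1e-12)
    U = np.eye(k) + Q / R
    # n | endpoints: P(n) propto Poisson(Rt)(n) * U^n[a,b]
    powers = [np.eye(k)]
    log_pois = -R * t
    weights = []
    n = 0
    total = 0.0
    target_tail = 1e-12
    pmat = _pruning.expm_batch(Q, np.array([t]))[0]
    denom = max(pmat[a, b], 1e-300)
    while True:
        w = np.exp(log_pois) * powers[n][a, b]
        weights.append(w)
        total += w
        if n > 2 and total >= denom * (1 - target_tail):
            break
        n += 1
        powers.append(powers[-1] @ U)
        log_pois += np.log(R * t) - np.log(n)
        if n > 10_000:
            break
    weights = np.array(weights)
    weights /= weights.sum()
    n_jumps = int(rng.choice(len(weights), p=weights))
    times = np.sort(rng.uniform(0, t, size=n_jumps))
    states = [a]
    for i in range(n_jumps):
        remaining = n_jumps - i - 1
        probs = U[states[-1]] * powers[remaining][:, b]
        ssum = probs.sum()
        if ssum <= 0:
            probs = U[states[-1]]
            ssum = probs.sum()
        states.append(int(rng.choice(k, p=probs / ssum)))
    # drop virtual (self) jumps
    path = [(a, 0.0)]
    for s, tt in zip(states[1:], times):
        if s != path[-1][0]:
            path.append((s, float(tt)))
    return _segments(path, t)


def sample_stochastic_maps(tree: TimeTree, tip_states: Mapping, model: MkModel,
                           n_maps: int = 1000, seed: int = 0) -> StochasticMapSet:
    """Sample full character histories from their joint posterior.

    Node states are drawn jointly (root from its conditional, then each
    child given its parent); branch histories are endpoint-conditioned CTMC
    paths drawn by rejection with a uniformization fallback, so sampling
    always terminates.
    """
    rng = np.random.default_rng(seed)
    k = model.k
    tp = tip_partials_matrix(tree, tip_states, model.states)
    P = _pruning.edge_pmatrices(tree, model.Q)
    part, log_scale = _pruning.downpass_partials(tree, P, tp)
    if not np.isfinite(log_scale):
        raise ValueError("data impossible under this model")
    pi = _pruning.root_prior(model.root_policy, part[tree.root], model.Q)

    node_states = np.zeros((n_maps, tree.n_nodes), dtype=np.int64)
    histories = []
    transitions = np.zeros((n_maps, k, k))
    fallbacks = 0
    rates_off = np.abs(np.diag(model.Q)).max()
    for m in range(n_maps):
        st = np.zeros(tree.n_nodes, dtype=np.int64)
        w = pi * part[tree.root]
        st[tree.root] = rng.choice(k, p=w / w.sum())
        for v in tree.preorder:
            if v < tree.n_tips:
                continue
            for c in tree.children[v]:
                w = P[c][st[v]] * part[c]
                st[c] = rng.choice(k, p=w / w.sum())
        node_states[m] = st
        hist = {}
        for c in range(tree.n_nodes):
            if c == tree.root:
                continue
            a, b = int(st[tree.parent[c]]), int(st[c])
            t = float(tree.edge_length[c])
            if t <= 0 or rates_off == 0:
                segs = [(b, t)]
                if a != b and t <= 0:
                    transitions[m, a, b] += 1
                    segs = [(a, 0.0), (b, 0.0)]
            else:
                drawn = _sample_path_rejection(rng, model.Q, a, b, t)
                if drawn is None:
                    fallbacks += 1
                    segs = _sample_path_uniformization(rng, model.Q, a, b, t)
                else:
                    segs = drawn[0]
            hist[c] = segs
            for (s0, _), (s1, _) in zip(segs[:-1], segs[1:]):
                transitions[m, s0, s1] += 1
        histories.append(hist)
    return StochasticMapSet(tree, tuple(model.states), node_states, histories,
                            transitions, fallbacks)


def count_origins(obj, gain=(0, 1)) -> tuple:
    """Count gains (0->1) and losses (1->0) of a binary trait.

    For an :class:`AncestralReconstruction`, nodes take their
    max-probability state (exact ties broken toward absence) and changes
    are read off parent->child edges.  For a :class:`StochasticMapSet`, the
    posterior mean realized gain/loss counts are returned.
    """
    if isinstance(obj, StochasticMapSet):
        return obj.mean_gains_losses(gain=gain)
    if not isinstance(obj, AncestralReconstruction):
        raise TypeError("expected AncestralReconstruction or StochasticMapSet")
    tree = obj.tree
    st = obj.map_states(tie_state_index=gain[0])
    gains = losses = 0
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p == -1:
            continue
        if st[p] == gain[0] and st[i] == gain[1]:
            gains += 1
        elif st[p] == gain[1] and st[i] == gain[0]:
            losses += 1
    return gains, losses
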