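"""Independent oracles used by the tests.

These deliberately avoid the package's pruning/ODE code paths: state
enumeration sums over every internal-node assignment, and the birth-death
likelihood is the classical closed form for a reconstructed ultrametric
tree.
"""

import itertools

import numpy as np
import scipy.linalg as sla

from matrophylo.mk import tip_partials_matrix


def enum_loglik(tree, tip_states, Q, pi):
    """Brute-force likelihood: sum over all internal state assignments,
    with each tip's (possibly ambiguous) state marginalized directly."""
    k = Q.shape[0]
    P = [sla.expm(Q * l) for l in tree.edge_length]
    tp = tip_partials_matrix(tree, tip_states, tuple(range(k)))
    internals = [i for i in tree.postorder if i >= tree.n_tips]
    total = 0.0
    for int_assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, int_assign))
        pr = pi[st[tree.root]]
        for i in internals:
            if i != tree.root:
                pr *= P[i][st[tree.parent[i]], st[i]]
        for t in range(tree.n_tips):
            pr *= float(P[t][st[tree.parent[t]]] @ tp[t])
        total += pr
    return np.log(total)


def enum_node_marginals(tree, tip_states, Q, pi):
    """Marginal node posteriors by full enumeration."""
    k = Q.shape[0]
    P = [sla.expm(Q * l) for l in tree.edge_length]
    tp = tip_partials_matrix(tree, tip_states, tuple(range(k)))
    acc = np.zeros((tree.n_nodes, k))
    nodes = list(tree.postorder)
    for assign in itertools.product(range(k), repeat=len(nodes)):
        st = dict(zip(nodes, assign))
        pr = pi[st[tree.root]]
        for t in range(tree.n_tips):
            pr *= tp[t, st[t]]
        if pr == 0.0:
            continue
        for i in range(tree.n_nodes):
            if i != tree.root:
                pr *= P[i][st[tree.parent[i]], st[i]]
        for i in nodes:
            acc[i, st[i]] += pr
    return acc / acc.sum(axis=1, keepdims=True)


def enum_min_changes(tree, tip_states):
    """Brute-force parsimony minimum over all internal assignments."""
    states = sorted({v for v in tip_states.values() if v is not None})
    k = len(states)
    tip_idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    internals = [i for i in tree.postorder if i >= tree.n_tips]
    best = np.inf
    fixed = {tip_idx[lab]: states.index(v) for lab, v in tip_states.items()
             if v is not None}
    amb = [i for i in range(tree.n_tips) if i not in fixed]
    for int_assign in itertools.product(range(k), repeat=len(internals)):
        for amb_assign in itertools.product(range(k), repeat=len(amb)):
            st = dict(fixed)
            st.update(zip(internals, int_assign))
            st.update(zip(amb, amb_assign))
            changes = sum(1 for i in range(tree.n_nodes)
                          if i != tree.root and st[i] != st[tree.parent[i]])
            best = min(best, changes)
    return int(best)


def bd_loglik_closed(tree, lam, mu, condition_on_survival=True):
    """Constant-rate birth-death likelihood of a reconstructed ultrametric
    tree (complete sampling), with the same lambda-per-node and
    survival-conditioning conventions as the SSE pruning."""
    r = lam - mu
    depths = tree.node_depths()
    T = tree.tip_depths().mean()
    heights = T - depths

    def log_psi(t):
        return -r * t + 2 * (np.log(lam - mu) - np.log(lam - mu * np.exp(-r * t)))

    ll = 0.0
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p == -1:
            continue
        ll += log_psi(heights[p]) - log_psi(heights[i])
    ll += (tree.n_nodes - tree.n_tips) * np.log(lam)
    if condition_on_survival:
        one_minus_e = (lam - mu) / (lam - mu * np.exp(-r * T))
        ll -= np.log(lam) + 2 * np.log(one_minus_e)
    return ll


def random_q(rng, k, lo=0.05, hi=2.0):
    Q = rng.uniform(lo, hi, size=(k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
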