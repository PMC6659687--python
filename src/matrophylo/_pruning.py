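"""Shared numerics for discrete-character likelihoods on trees.

Batched matrix exponentials plus Felsenstein pruning with per-node
rescaling; used by the Mk ancestral-state code and the correlated-evolution
(4-state) models, which must agree on these primitives exactly.
"""

from __future__ import annotations

import numpy as np

from .trees import TimeTree

_TAYLOR_TERMS = 16


def expm_batch(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(Q * t) for a batch of times; scaling-and-squaring with Taylor core.

    Accurate to ~1e-15 for the scaled norm <= 0.5 used here; adequate for
    generator matrices whose entries are bounded by the optimizer/sampler.
    """
    times = np.asarray(times, dtype=float)
    A = Q[None, :, :] * times[:, None, None]
    k = Q.shape[0]
    nrm = np.abs(A).sum(axis=2).max(initial=0.0)
    s = max(0, int(np.ceil(np.log2(max(nrm, 1e-300) / 0.5))))
    A = A / (2.0 ** s)
    P = np.broadcast_to(np.eye(k), A.shape).copy()
    term = np.broadcast_to(np.eye(k), A.shape).copy()
    for j in range(1, _TAYLOR_TERMS):
        term = term @ A / j
        P += term
    for _ in range(s):
        P = P @ P
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def edge_pmatrices(tree: TimeTree, Q: np.ndarray) -> np.ndarray:
    """Transition matrix along the edge subtending each node (root: identity)."""
    P = expm_batch(Q, tree.edge_length)
    P[tree.root] = np.eye(Q.shape[0])
    return P


def downpass_partials(tree: TimeTree, P: np.ndarray, tip_partials: np.ndarray):
    """Conditional likelihoods of the data below each node.

    Returns ``(partials, log_scale)`` where ``partials[i]`` is rescaled to
    sum 1 at internal nodes and ``log_scale`` is the total log of the
    factors removed (so the root likelihood is recoverable).
    """
    k = P.shape[1]
    n = tree.n_nodes
    part = np.zeros((n, k))
    part[: tree.n_tips] = tip_partials
    log_scale = 0.0
    for i in tree.postorder:
        if i < tree.n_tips:
            continue
        l, r = tree.children[i]
        v = (P[l] @ part[l]) * (P[r] @ part[r])
        s = v.sum()
        if s <= 0:
            return part, -np.inf
        part[i] = v / s
        log_scale += np.log(s)
    return part, log_scale


def root_prior(policy, root_partial: np.ndarray, Q: np.ndarray) -> np.ndarray:
    k = len(root_partial)
    if isinstance(policy, str):
        if policy == "uniform":
            return np.full(k, 1.0 / k)
        if policy == "stationary":
            return stationary_distribution(Q)
        if policy == "fitzjohn":
            s = root_partial.sum()
            if s <= 0:
                return np.full(k, 1.0 / k)
            return root_partial / s
        raise ValueError(f"unknown root policy {policy!r}")
    p = np.asarray(policy, dtype=float)
    if p.shape != (k,) or np.any(p < 0):
        raise ValueError("root prior must be a nonnegative length-k vector")
    return p / p.sum()


def prune_loglik(tree: TimeTree, Q: np.ndarray, tip_partials: np.ndarray,
                 policy="uniform") -> float:
    P = edge_pmatrices(tree, Q)
    part, log_scale = downpass_partials(tree, P, tip_partials)
    if not np.isfinite(log_scale):
        return -np.inf
    pi = root_prior(policy, part[tree.root], Q)
    L = float(pi @ part[tree.root])
    if L <= 0:
        return -np.inf
    return np.log(L) + log_scale


def marginal_node_posteriors(tree: TimeTree, Q: np.ndarray,
                             tip_partials: np.ndarray, policy="uniform"):
    """Marginal posterior state probabilities at every node.

    Standard two-pass (inside/outside) algorithm: the outside vector
    ``U[v]`` carries the likelihood of all data not below ``v`` jointly
    with the state at ``v``; marginals are ``U * D`` renormalized.
    Returns ``(node_probs, loglik)``.
    """
    P = edge_pmatrices(tree, Q)
    part, log_scale = downpass_partials(tree, P, tip_partials)
    if not np.isfinite(log_scale):
        raise ValueError("data impossible under this model")
    k = Q.shape[0]
    pi = root_prior(policy, part[tree.root], Q)
    L = float(pi @ part[tree.root])
    loglik = np.log(L) + log_scale

    U = np.zeros((tree.n_nodes, k))
    U[tree.root] = pi
    for v in tree.preorder:
        if v < tree.n_tips:
            continue
        l, r = tree.children[v]
        Sl = P[l] @ part[l]  # sibling message when visiting r
        Sr = P[r] @ part[r]
        U[l] = (U[v] * Sr) @ P[l]
        U[r] = (U[v] * Sl) @ P[r]
        for c in (l, r):
            s = U[c].sum()
            if s > 0:
                U[c] /= s
    post = U * part
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return post / norm, loglik
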