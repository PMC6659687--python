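"""Synthetic-data generators with recorded ground truth.

Every generator is deterministic given its seed and returns, alongside the
realized data, a :class:`SimulationRecord` carrying the generator name,
the true parameters and the full latent history, so parameter-recovery and
calibration tests can compare estimates with truth.

Trees are grown forward from a crown (two-lineage) start.  Stopping on a
target tip count cuts the process between the n-th birth among extant
lineages and the next event (simple forward stopping, not the
generalized-sampling algorithm; a known small-n bias acceptable because
all internal comparisons are like-with-like).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .pagel import PagelDependentModel
from .scoring import STAGE_SPAN
from .sse import SSEParams
from .trees import TimeTree, _N

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationRecord",
    "simulate_bd_tree",
    "simulate_bisse_tree",
    "simulate_mk_trait",
    "simulate_dependent_traits",
    "simulate_brood_data",
    "decode_joint_states",
]


@dataclasses.dataclass
class SimulationRecord:
    generator: str
    seed: int
    params: dict
    history: dict

    def to_json(self) -> str:
        import json

        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=1)


class _Lineage:
    __slots__ = ("lid", "parent", "t0", "t1", "fate", "children", "state",
                 "state_history")

    def __init__(self, lid, parent, t0, state):
        self.lid = lid
        self.parent = parent
        self.t0 = t0
        self.t1 = None
        self.fate = None           # speciation | extinction | extant
        self.children = []
        self.state = state
        self.state_history = [(t0, state)]


def _grow(rng, lam, mu, Q, root_state, stop, max_events=2_000_000):
    """One forward pass; returns lineages or None on total extinction."""
    k = len(lam)
    qtot = Q.sum(axis=1)
    mode, target = stop
    lineages = [_Lineage(0, -1, 0.0, root_state), _Lineage(1, -1, 0.0, root_state)]
    extant = [0, 1]
    t = 0.0
    events = 0
    while True:
        if not extant:
            return None, None
        rates = np.array([lam[lineages[i].state] + mu[lineages[i].state]
                          + qtot[lineages[i].state] for i in extant])
        total = rates.sum()
        dt = rng.exponential(1.0 / total)
        if mode == "age" and t + dt >= target:
            t_end = target
            break
        if mode == "n_tips" and len(extant) >= target:
            # cut strictly inside the waiting interval: no further event occurs
            t_end = t + rng.uniform(0.0, dt)
            break
        t += dt
        events += 1
        if events > max_events:
            raise RuntimeError("simulation exceeded event budget")
        idx = rng.choice(len(extant), p=rates / rates.sum())
        lin = lineages[extant[idx]]
        s = lin.state
        u = rng.random() * rates[idx]
        if u < lam[s]:  # speciation
            lin.t1 = t
            lin.fate = "speciation"
            for _ in range(2):
                child = _Lineage(len(lineages), lin.lid, t, s)
                lin.children.append(child.lid)
                lineages.append(child)
            extant.pop(idx)
            extant.extend([lineages[-2].lid, lineages[-1].lid])
        elif u < lam[s] + mu[s]:  # extinction
            lin.t1 = t
            lin.fate = "extinction"
            extant.pop(idx)
        else:  # character transition
            w = Q[s].copy()
            new = rng.choice(k, p=w / w.sum())
            lin.state = int(new)
            lin.state_history.append((t, int(new)))
    for i in extant:
        lineages[i].t1 = t_end
        lineages[i].fate = "extant"
    return lineages, t_end


def _reconstructed_tree(lineages):
    """Prune extinct lineages and build the TimeTree of survivors."""
    lmap = {l.lid: l for l in lineages}

    def build(lin) -> _N | None:
        if lin.fate == "extant":
            return _N(label=f"t{lin.lid}", length=lin.t1 - lin.t0)
        if lin.fate == "extinction":
            return None
        kids = [build(lmap[c]) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            # unifurcation collapsed by TimeTree._from_nodes
            pass
        return _N(length=lin.t1 - lin.t0, children=kids)

    roots = [build(l) for l in lineages if l.parent == -1]
    roots = [r for r in roots if r is not None]
    if len(roots) == 0:
        return None, None
    if len(roots) == 1:
        # one crown lineage died out entirely: not a crown tree; signal retry
        return None, None
    crown = _N(length=0.0, children=roots)
    tree = TimeTree._from_nodes(crown)
    tip_states = {f"t{l.lid}": l.state for l in lineages if l.fate == "extant"}
    return tree, tip_states


def simulate_bd_tree(lam: float, mu: float, stop, seed: int = 0,
                     max_retries: int = 1000):
    """Constant-rate birth-death tree; ``stop=("n_tips", n)`` or ``("age", t)``.

    Extinct lineages are pruned; the returned tree is ultrametric.  Total
    extinction triggers a retry (count recorded in the SimulationRecord).
    """
    if not (lam > mu >= 0):
        raise ValueError("need lam > mu >= 0")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        lineages, t_end = _grow(rng, np.array([lam]), np.array([mu]),
                                np.zeros((1, 1)), 0, stop)
        if lineages is None:
            continue
        tree, _ = _reconstructed_tree(lineages)
        if tree is None:
            continue
        if stop[0] == "n_tips" and tree.n_tips != stop[1]:
            continue
        rec = SimulationRecord(
            "bd_tree", seed, dict(lam=lam, mu=mu, stop=list(stop)),
            dict(retries=attempt, age=t_end,
                 events=[(l.lid, l.parent, l.t0, l.t1, l.fate) for l in lineages]))
        if attempt:
            logger.info("birth-death simulation retried %d times", attempt)
        return tree, rec
    raise RuntimeError("birth-death simulation failed after max retries")


def simulate_bisse_tree(params: SSEParams, stop, root_state: int = 0,
                        seed: int = 0, max_retries: int = 1000):
    """State-dependent birth-death tree with character transitions.

    Returns ``(tree, tip_states, record)`` for the pruned (reconstructed)
    tree of extant lineages.
    """
    rng = np.random.default_rng(seed)
    Qoff = params.Q.copy()
    np.fill_diagonal(Qoff, 0.0)
    for attempt in range(max_retries):
        lineages, t_end = _grow(rng, params.lam, params.mu, Qoff,
                                int(root_state), stop)
        if lineages is None:
            continue
        tree, tip_states = _reconstructed_tree(lineages)
        if tree is None:
            continue
        if stop[0] == "n_tips" and tree.n_tips != stop[1]:
            continue
        rec = SimulationRecord(
            "bisse_tree", seed,
            dict(lam=params.lam, mu=params.mu, Q=Qoff, f=params.f,
                 root_state=root_state, stop=list(stop)),
            dict(retries=attempt, age=t_end,
                 state_histories={l.lid: l.state_history for l in lineages}))
        return tree, tip_states, rec
    raise RuntimeError("SSE simulation failed after max retries")


def simulate_mk_trait(tree: TimeTree, Q: np.ndarray, root_state: int = 0,
                      seed: int = 0):
    """Simulate a discrete character down a fixed tree under generator Q.

    Returns ``(tip_states, record)``; the record's history holds per-edge
    change times and the realized total change count.
    """
    rng = np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    Qoff = Q.copy()
    np.fill_diagonal(Qoff, 0.0)
    qrates = Qoff.sum(axis=1)
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = int(root_state)
    changes = {}
    n_changes = 0
    for v in tree.preorder:
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        t = 0.0
        edge = []
        T = tree.edge_length[v]
        while True:
            if qrates[s] <= 0:
                break
            t += rng.exponential(1.0 / qrates[s])
            if t >= T:
                break
            s = int(rng.choice(k, p=Qoff[s] / Qoff[s].sum()))
            edge.append((float(t), s))
            n_changes += 1
        node_state[v] = s
        if edge:
            changes[int(v)] = edge
    tip_states = {lab: int(node_state[i]) for i, lab in enumerate(tree.tip_labels)}
    rec = SimulationRecord("mk_trait", seed,
                           dict(Q=Q, root_state=int(root_state)),
                           dict(edge_changes=changes, n_changes=n_changes,
                                node_states=node_state))
    return tip_states, rec


def simulate_dependent_traits(tree: TimeTree, model: PagelDependentModel,
                              root_joint_state: int = 1, seed: int = 0):
    """Joint 4-state simulation of two binary traits on a fixed tree.

    ``root_joint_state`` uses the 1-4 joint coding.  Returns
    ``(joint_data, record)`` with joint states 1-4 per tip.
    """
    if root_joint_state not in (1, 2, 3, 4):
        raise ValueError("root_joint_state must be 1..4")
    tips, rec = simulate_mk_trait(tree, model.Q, root_joint_state - 1, seed)
    rec.generator = "dependent_traits"
    rec.params["rates"] = model.rates
    return {sp: s + 1 for sp, s in tips.items()}, rec


def decode_joint_states(data: Mapping) -> tuple:
    """Split joint states 1-4 back into the two marginal binary traits."""
    t1 = {sp: (s - 1) // 2 for sp, s in data.items()}
    t2 = {sp: (s - 1) % 2 for sp, s in data.items()}
    return t1, t2


def simulate_brood_data(true_mi: float, n_broods: int = 12,
                        stage_span: float = 40.0, noise_sd: float = 0.15,
                        egg_mass_mg: float = 1.0, seed: int = 0,
                        species: str = "sp1", population: str = "pop1") -> pd.DataFrame:
    """Brood-level embryo dry-mass observations for one population.

    Stages are uniform on a window of width ``stage_span`` centered on the
    0-50 staging scale; ln dry mass follows
    ``ln(egg_mass) + (ln(true_mi)/50) * stage + N(0, noise_sd)``, so an MI
    of ``true_mi`` is the generating truth for the scoring regression.
    """
    if true_mi <= 0 or n_broods < 3:
        raise ValueError("need true_mi > 0 and n_broods >= 3")
    if not (0 < stage_span <= STAGE_SPAN):
        raise ValueError("stage_span must be in (0, 50]")
    rng = np.random.default_rng(seed)
    lo = (STAGE_SPAN - stage_span) / 2.0
    stages = lo + stage_span * np.linspace(0, 1, n_broods) \
        if noise_sd == 0 else rng.uniform(lo, lo + stage_span, size=n_broods)
    slope = np.log(true_mi) / STAGE_SPAN
    ln_mass = np.log(egg_mass_mg) + slope * stages \
        + rng.normal(0, noise_sd, size=n_broods)
    return pd.DataFrame(dict(
        species=species, population=population,
        brood_id=[f"b{i}" for i in range(n_broods)],
        stage=stages, dry_mass_mg=np.exp(ln_mass)))
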