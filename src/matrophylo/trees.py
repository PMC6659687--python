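"""Time-calibrated phylogenies: reading, writing, validation, pruning, rescaling.

The central type is :class:`TimeTree`, a rooted binary tree with branch
lengths in millions of years (Myr).  Internally the topology is stored in
flat arrays indexed by node id (tips first, then internal nodes in
postorder), which is what the pruning-algorithm and ODE code downstream
consumes.  Parsing of Newick and Nexus (including translate tables) is
delegated to dendropy.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeTree",
    "ScaledTree",
    "read_tree",
    "write_tree",
    "prune_to_taxa",
    "check_ultrametric",
    "scale_branch_lengths",
]


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class _N:
    """Light mutable node used while assembling a TimeTree."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = float(length) if length is not None else 0.0
        self.children = children if children is not None else []

    def min_tip_label(self) -> str:
        if not self.children:
            return self.label or ""
        return min(c.min_tip_label() for c in self.children)


class TimeTree:
    """Rooted binary ultrametric-capable tree over uniquely labelled tips.

    Attributes
    ----------
    n_tips : int
        Number of terminal taxa.  Node ids ``0..n_tips-1`` are tips.
    parent : ndarray of int
        Parent node id per node; the root has parent ``-1``.
    edge_length : ndarray of float
        Length (Myr) of the edge subtending each node; 0 at the root.
    postorder : ndarray of int
        Every node id, children strictly before parents.
    tip_labels : list of str
        Species identifiers, unique, in node-id order.
    """

    def __init__(self, parent, edge_length, children, tip_labels, postorder):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        # children[i] = (left, right) for internal nodes, (-1, -1) for tips
        self.children = np.asarray(children, dtype=np.int64)
        self.tip_labels = list(tip_labels)
        self.postorder = np.asarray(postorder, dtype=np.int64)
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def _from_nodes(cls, root: _N) -> "TimeTree":
        root = _suppress_unifurcations(root)
        _resolve_polytomies(root)
        tips: list[_N] = []
        internals: list[_N] = []

        def collect(n):
            for c in n.children:
                collect(c)
            (internals if n.children else tips).append(n)

        collect(root)
        labels = [t.label for t in tips]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        if len(tips) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        ids = {id(t): i for i, t in enumerate(tips)}
        for j, n in enumerate(internals):
            ids[id(n)] = len(tips) + j
        m = len(tips) + len(internals)
        parent = np.full(m, -1, dtype=np.int64)
        elen = np.zeros(m)
        children = np.full((m, 2), -1, dtype=np.int64)
        post = []

        def fill(n):
            for c in n.children:
                fill(c)
                parent[ids[id(c)]] = ids[id(n)]
            i = ids[id(n)]
            elen[i] = n.length
            if n.children:
                children[i] = [ids[id(c)] for c in n.children]
            post.append(i)

        fill(root)
        elen[ids[id(root)]] = 0.0
        return cls(parent, elen, children, labels, post)

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True)
        except Exception as exc:
            msg = str(exc)
            if "duplicate" in msg.lower() or "same taxa" in msg.lower():
                raise TreeValidationError(f"duplicate tip labels: {msg}") from exc
            raise TreeValidationError(f"failed to parse newick: {msg}") from exc
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "TimeTree":
        def conv(node) -> _N:
            label = None
            if node.is_leaf():
                label = (node.taxon.label if node.taxon is not None
                         else node.label)
                if label is None:
                    raise TreeValidationError("unlabelled tip in input tree")
            n = _N(label=label, length=node.edge.length or 0.0)
            n.children = [conv(c) for c in node.child_nodes()]
            return n

        return cls._from_nodes(conv(dt.seed_node))

    # -- invariants -------------------------------------------------------

    def _validate(self):
        if np.any(self.edge_length < 0):
            raise TreeValidationError("negative edge length")
        n_root = int(np.sum(self.parent == -1))
        if n_root != 1:
            raise TreeValidationError(f"expected 1 root, found {n_root}")

    # -- basic accessors --------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def tip_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        depth = np.zeros(self.n_nodes)
        for i in self.preorder[1:]:
            depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def mean_edge_length(self) -> float:
        # root has no subtending edge
        m = self.n_nodes - 1
        return self.total_length() / m

    def terminal_edge_lengths(self) -> np.ndarray:
        return self.edge_length[: self.n_tips].copy()

    def path_length_matrix(self) -> np.ndarray:
        """Pairwise tip-to-tip patristic distances (label order)."""
        d = self.node_depths()
        n = self.n_tips
        # lowest common ancestor by ancestor sets (fine at these sizes)
        anc = []
        for i in range(n):
            s = {}
            j = i
            while j != -1:
                s[j] = d[j]
                j = int(self.parent[j])
            anc.append(s)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                common = max(anc[i].keys() & anc[j].keys(),
                             key=lambda k: anc[i][k])
                out[i, j] = out[j, i] = d[i] + d[j] - 2 * anc[i][common]
        return out

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.edge_length.copy(),
                        self.children.copy(), list(self.tip_labels),
                        self.postorder.copy())

    # -- serialization ----------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def rec(i: int) -> str:
            if i < self.n_tips:
                lab = self.tip_labels[i]
                if any(ch in lab for ch in " (),:;[]'"):
                    lab = "'" + lab.replace("'", "''") + "'"
                core = lab
            else:
                l, r = self.children[i]
                core = f"({rec(l)},{rec(r)})"
            if self.parent[i] == -1:
                return core
            return f"{core}:{self.edge_length[i]:.{precision}g}"

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<TimeTree {self.n_tips} tips, total length {self.total_length():.4g}>"


def _suppress_unifurcations(root: _N) -> _N:
    while len(root.children) == 1:
        root = root.children[0]
        root.length = 0.0

    def walk(n: _N):
        new = []
        for c in n.children:
            while len(c.children) == 1:
                g = c.children[0]
                g.length += c.length
                c = g
            walk(c)
            new.append(c)
        n.children = new

    walk(root)
    return root


def _resolve_polytomies(root: _N):
    """Arbitrary but deterministic binary resolution with zero-length edges.

    Children are ordered by their smallest descendant tip label and merged
    pairwise, so the resolution depends only on tip labels, not input order.
    """
    resolved = 0

    def walk(n: _N):
        nonlocal resolved
        for c in n.children:
            walk(c)
        if len(n.children) > 2:
            resolved += 1
            kids = sorted(n.children, key=lambda c: c.min_tip_label())
            while len(kids) > 2:
                a = kids.pop(0)
                b = kids.pop(0)
                merged = _N(length=0.0, children=[a, b])
                kids.insert(0, merged)
                kids.sort(key=lambda c: c.min_tip_label())
            n.children = kids

    walk(root)
    if resolved:
        logger.warning("resolved %d polytomies to binary with zero-length edges",
                       resolved)


@dataclasses.dataclass
class ScaledTree:
    """A TimeTree with rescaled branch lengths.

    Rates estimated on ``tree`` multiplied by ``scale_factor`` recover
    rates in the original time unit.
    """

    tree: TimeTree
    scale_factor: float


# -- module-level operations ----------------------------------------------


def read_tree(path, format: str = "newick") -> TimeTree:
    """Read a rooted tree from ``path`` in ``newick`` or ``nexus`` dialect.

    Polytomies are resolved deterministically to binary with zero-length
    edges (logged).  Duplicate tip labels raise a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        dt = dendropy.Tree.get(path=str(path), schema=format,
                               preserve_underscores=True)
    except Exception as exc:  # dendropy raises various error classes
        raise TreeValidationError(f"failed to parse {path} as {format}: {exc}") from exc
    return TimeTree._from_dendropy(dt)


def write_tree(tree: TimeTree, path, format: str = "newick") -> None:
    """Write ``tree`` so that reparsing recovers topology and lengths."""
    newick = tree.to_newick()
    path = Path(path)
    if format == "newick":
        path.write_text(newick + "\n")
    elif format == "nexus":
        taxa = "\n".join(f"\t\t{_nexus_quote(l)}" for l in tree.tip_labels)
        path.write_text(
            "#NEXUS\n\nBEGIN TAXA;\n\tDIMENSIONS NTAX=%d;\n\tTAXLABELS\n%s\n\t;\nEND;\n\n"
            "BEGIN TREES;\n\tTREE timetree = [&R] %s\nEND;\n"
            % (tree.n_tips, taxa, newick)
        )
    else:
        raise ValueError(f"unknown tree format {format!r}")


def _nexus_quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def prune_to_taxa(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Induced subtree on ``keep``; collapsed degree-2 nodes sum their edges."""
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    def rec(i: int) -> _N | None:
        if i < tree.n_tips:
            if tree.tip_labels[i] in keep:
                return _N(label=tree.tip_labels[i], length=tree.edge_length[i])
            return None
        subs = [rec(c) for c in tree.children[i]]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            subs[0].length += tree.edge_length[i]
            return subs[0]
        return _N(length=tree.edge_length[i], children=subs)

    root = rec(tree.root)
    root.length = 0.0
    return TimeTree._from_nodes(root)


def check_ultrametric(tree: TimeTree, rel_tol: float = 1e-6):
    """Return ``(is_ultrametric, max_relative_deviation)``.

    Deviation is ``max |depth_i - mean depth| / mean depth`` over tips.
    """
    depths = tree.tip_depths()
    mean = depths.mean()
    if mean <= 0:
        return False, np.inf
    dev = float(np.max(np.abs(depths - mean)) / mean)
    return dev <= rel_tol, dev


def scale_branch_lengths(tree: TimeTree, target_mean_edge: float = 0.1) -> ScaledTree:
    """Rescale so the mean edge length equals ``target_mean_edge``.

    Rescaling a tree before MCMC keeps transition rates in a numerically
    comfortable range; rates back-transform by multiplying with
    ``scale_factor``.
    """
    mean = tree.mean_edge_length()
    if mean <= 0:
        raise ValueError("tree has zero total length; cannot rescale")
    factor = target_mean_edge / mean
    scaled = tree.copy()
    scaled.edge_length = scaled.edge_length * factor
    return ScaledTree(tree=scaled, scale_factor=factor)
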