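"""Phylogeny container and Newick I/O.

The package works on rooted, branch-length-bearing trees whose branch
lengths are in units of time (My).  ``Phylogeny`` is a small immutable
array-based container: every node has an integer index, a parent index
(-1 for the root) and the length of the branch above it.  Newick parsing
is delegated to dendropy; the container validates the structural
invariants every downstream rate estimator relies on (single root,
strictly positive branch lengths, unique tip labels).

A tree may carry a *root stem* (``root_length``): the length of the edge
above the root node, produced e.g. when pruning leaves a path between
the old root and the MRCA of the retained taxa.  Root-to-tip distances
include the stem, so pruning preserves them exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "NewickError",
    "TreeStructureError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "is_ultrametric",
]


class NewickError(ValueError):
    """Malformed or unsupported Newick input."""


class TreeStructureError(ValueError):
    """Tree violates a structural invariant."""


_NEWICK_SPECIALS = set("(),:;[]' \t\n")


class Phylogeny:
    """Rooted tree with branch lengths, indexed by integer node ids.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node index of node ``i``; exactly one
        entry is ``-1`` (the root).
    branch_length
        Length of the edge above each node, in My.  The root entry is
        ignored (conventionally 0).  All other entries must be > 0.
    labels
        Per-node labels; every tip (childless node) must carry a unique
        label, internal labels may be ``None``.
    root_length
        Length of the stem edge above the root (>= 0, default 0).
    """

    __slots__ = (
        "parent",
        "branch_length",
        "labels",
        "root_length",
        "children",
        "root",
        "_postorder",
        "_depths",
        "_tips",
    )

    def __init__(
        self,
        parent: np.ndarray,
        branch_length: np.ndarray,
        labels: Sequence[str | None],
        root_length: float = 0.0,
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64).copy()
        self.labels = list(labels)
        self.root_length = float(root_length)
        n = self.parent.shape[0]
        if not (len(self.labels) == n == self.branch_length.shape[0]):
            raise TreeStructureError("parent, branch_length and labels disagree in size")
        children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                children[p].append(i)
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children = children
        self.branch_length[self.root] = 0.0
        self._postorder: np.ndarray | None = None
        self._depths: np.ndarray | None = None
        self._tips: np.ndarray | None = None
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        # reachability: walk from root
        seen = np.zeros(n, dtype=bool)
        stack = [self.root]
        while stack:
            i = stack.pop()
            if seen[i]:
                raise TreeStructureError("cycle detected in parent links")
            seen[i] = True
            stack.extend(self.children[i])
        if not seen.all():
            raise TreeStructureError("nodes unreachable from the root")
        nonroot = np.arange(n) != self.root
        bad = nonroot & ~(self.branch_length > 0)
        if bad.any():
            raise TreeStructureError(
                f"non-positive branch lengths at nodes {np.flatnonzero(bad).tolist()}"
            )
        if self.root_length < 0:
            raise TreeStructureError("root stem length must be >= 0")
        tip_labels = [self.labels[i] for i in self.tip_indices]
        if any(lbl is None for lbl in tip_labels):
            raise TreeStructureError("every tip must carry a label")
        dup = {l for l in tip_labels if tip_labels.count(l) > 1}
        if dup:
            raise TreeStructureError(f"duplicate tip labels: {sorted(dup)}")

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def tip_indices(self) -> np.ndarray:
        if self._tips is None:
            self._tips = np.array(
                [i for i in range(self.n_nodes) if not self.children[i]], dtype=np.int64
            )
        return self._tips

    @property
    def n_tips(self) -> int:
        return self.tip_indices.shape[0]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def postorder(self) -> np.ndarray:
        """Node indices with every child before its parent."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for c in self.children[node]:
                        stack.append((c, False))
            self._postorder = np.array(order, dtype=np.int64)
        return self._postorder

    @property
    def node_depths(self) -> np.ndarray:
        """Distance from the root node to each node (stem excluded)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in self.postorder[::-1]:  # preorder
                if i != self.root:
                    d[i] = d[self.parent[i]] + self.branch_length[i]
            self._depths = d
        return self._depths

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip distances (stem included), ordered as ``tip_indices``."""
        return self.node_depths[self.tip_indices] + self.root_length

    @property
    def root_age(self) -> float:
        """Maximum root-to-tip distance (stem included)."""
        return float(self.tip_depths.max())

    def tip_index_of(self, label: str) -> int:
        try:
            return {self.labels[i]: i for i in self.tip_indices}[label]
        except KeyError:
            raise KeyError(f"unknown tip label {label!r}") from None

    def path_matrix(self) -> np.ndarray:
        """Binary (n_tips x n_nodes) matrix: edge above node j on root-to-tip path i.

        The root column is always 0 (the root has no edge below the stem);
        the stem itself is not a node and is handled separately where needed.
        """
        tips = self.tip_indices
        A = np.zeros((tips.shape[0], self.n_nodes))
        for r, t in enumerate(tips):
            i = t
            while i != self.root:
                A[r, i] = 1.0
                i = self.parent[i]
        return A

    def vcv(self) -> np.ndarray:
        """Shared-path-length (Brownian covariance, unit rate) matrix of tips.

        ``V[i, j]`` is the length of the path from the base of the stem to the
        MRCA of tips i and j; ``V[i, i]`` is the root-to-tip distance.
        """
        A = self.path_matrix()
        V = (A * self.branch_length) @ A.T
        return V + self.root_length

    def patristic_distances(self) -> np.ndarray:
        """Pairwise path lengths between tips."""
        d = self.tip_depths
        V = self.vcv()
        return d[:, None] + d[None, :] - 2 * V

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {self.n_tips} tips, root age {self.root_age:.3f}>"


class RegimePainting:
    """Assignment of every branch to a diversification/trait-rate regime.

    ``branch_regime[i]`` is the regime id of the edge above node ``i`` (the
    root entry gives the regime of the stem / root lineage).  Per-regime
    parameters: speciation rate ``lam`` (My^-1), extinction rate ``mu``
    (My^-1) and Brownian trait rate ``sigma2`` (trait-units^2 My^-1).
    """

    __slots__ = ("branch_regime", "lam", "mu", "sigma2")

    def __init__(
        self,
        branch_regime: np.ndarray,
        lam: np.ndarray,
        mu: np.ndarray,
        sigma2: np.ndarray,
    ):
        self.branch_regime = np.asarray(branch_regime, dtype=np.int64)
        self.lam = np.asarray(lam, dtype=np.float64)
        self.mu = np.asarray(mu, dtype=np.float64)
        self.sigma2 = np.asarray(sigma2, dtype=np.float64)
        if not (self.lam > 0).all():
            raise ValueError("regime speciation rates must be > 0")
        if not (self.mu >= 0).all():
            raise ValueError("regime extinction rates must be >= 0")
        if not (self.sigma2 >= 0).all():
            raise ValueError("regime trait rates must be >= 0")
        r = self.branch_regime
        if r.min() < 0 or r.max() >= self.lam.shape[0]:
            raise ValueError("branch regime id out of range")

    @property
    def n_regimes(self) -> int:
        return self.lam.shape[0]

    def validate_for(self, tree: Phylogeny) -> None:
        if self.branch_regime.shape[0] != tree.n_nodes:
            raise ValueError(
                "painting covers "
                f"{self.branch_regime.shape[0]} branches, tree has {tree.n_nodes} nodes"
            )

    def branch_sigma2(self) -> np.ndarray:
        return self.sigma2[self.branch_regime]

    def tip_lambda(self, tree: Phylogeny) -> np.ndarray:
        """True speciation rate of the regime each tip sits in."""
        self.validate_for(tree)
        return self.lam[self.branch_regime[tree.tip_indices]]


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are mandatory for every non-root edge (there is no
    unit-length defaulting: downstream rates carry My units).  Polytomies
    are accepted.  Malformed input raises :class:`NewickError` carrying
    dendropy's position diagnostics; duplicate tip labels are reported by
    name.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    bl = np.zeros(n)
    labels: list[str | None] = [None] * n
    root_length = 0.0
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is None:
            root_length = float(nd.edge.length or 0.0)
        else:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                where = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise NewickError(f"missing branch length above {where!r}")
            bl[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickError(f"unlabelled tip at node {i}")
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    try:
        return Phylogeny(parent, bl, labels, root_length=root_length)
    except TreeStructureError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(tree: Phylogeny, digits: int = 9) -> str:
    """Serialize to Newick with ``digits`` significant digits on lengths."""
    fmt = f"%.{digits}g"

    for lbl in tree.tip_labels:
        if any(ch in _NEWICK_SPECIALS for ch in lbl):
            raise NewickError(f"tip label {lbl!r} contains Newick metacharacters")

    out: dict[int, str] = {}
    for i in tree.postorder:
        if not tree.children[i]:
            out[i] = f"{tree.labels[i]}:{fmt % tree.branch_length[i]}"
        else:
            inner = ",".join(out.pop(c) for c in tree.children[i])
            if i == tree.root:
                stem = f":{fmt % tree.root_length}" if tree.root_length > 0 else ""
                out[i] = f"({inner}){stem};"
            else:
                out[i] = f"({inner}):{fmt % tree.branch_length[i]}"
    return out[tree.root]


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to the tips in ``keep``.

    Degree-2 internal nodes created by the pruning are suppressed, summing
    branch lengths, so patristic distances among retained tips (and their
    root-to-tip distances, counting the stem) are unchanged.  The new root
    is the MRCA of the retained taxa; the path from the old root down to it
    becomes the root stem.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    unknown = sorted(keep - have)
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    n = tree.n_nodes
    keep_node = np.zeros(n, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[i] in keep:
            keep_node[i] = True
    # propagate upward: a node is kept if any descendant tip is kept
    for i in tree.postorder:
        if tree.children[i]:
            keep_node[i] = any(keep_node[c] for c in tree.children[i])

    kept_children = [
        [c for c in tree.children[i] if keep_node[c]] for i in range(n)
    ]

    # descend from old root to the first node with >= 2 kept children
    new_root = tree.root
    stem = tree.root_length
    while len(kept_children[new_root]) == 1:
        child = kept_children[new_root][0]
        stem += tree.branch_length[child]
        new_root = child

    parent_out: list[int] = []
    bl_out: list[float] = []
    labels_out: list[str | None] = []

    def emit(node: int, parent_idx: int, acc: float) -> None:
        # acc carries the edge length above `node`; degree-2 chains merge in
        kids = kept_children[node]
        while len(kids) == 1:
            node = kids[0]
            acc += tree.branch_length[node]
            kids = kept_children[node]
        idx = len(parent_out)
        parent_out.append(parent_idx)
        bl_out.append(acc if parent_idx >= 0 else 0.0)
        labels_out.append(tree.labels[node])
        for c in kids:
            emit(c, idx, tree.branch_length[c])

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    try:
        emit(new_root, -1, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)

    pruned = Phylogeny(
        np.array(parent_out), np.array(bl_out), labels_out, root_length=stem
    )
    return pruned


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Check that all root-to-tip distances agree within ``rel_tol``.

    Returns ``(flag, max_relative_deviation)`` where the deviation is
    ``(d_max - d_min) / d_max``.
    """
    d = tree.tip_depths
    dmax = d.max()
    if dmax <= 0:
        raise TreeStructureError("tree has zero depth")
    dev = float((dmax - d.min()) / dmax)
    return dev <= rel_tol, dev
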