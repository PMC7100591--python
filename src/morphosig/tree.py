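"""Array-backed rooted time trees.

The tree is stored as flat arrays (parent pointers, edge lengths, a fixed
postorder) so that per-character pruning and repeated likelihood passes are
cheap.  Tips are nodes ``0..n_tips-1`` in the order of ``labels``; internal
nodes follow.  The edge length of a node is the length of the branch *above*
it (the root carries 0).  Polytomies are allowed everywhere.

I/O goes through :mod:`dendropy` (Newick and NEXUS, translate tables
included); :class:`TimeTree` only adds the array view and the operations the
analysis needs: pruning to a taxon subset, tip depths / ultrametricity, and
Pagel's lambda branch-length transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "TreeError", "read_tree"]


class TreeError(ValueError):
    """Raised for structurally invalid trees (lengths, labels, rooting)."""


@dataclass
class TimeTree:
    """Rooted tree with branch lengths in time units (Myr).

    Parameters
    ----------
    labels:
        Tip labels; tip ``i`` is node ``i``.
    parent:
        ``parent[v]`` is the parent node of ``v``; ``-1`` for the root.
    edge_length:
        Length of the edge above each node; 0 for the root.
    """

    labels: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]] = field(init=False, repr=False)
    postorder: np.ndarray = field(init=False, repr=False)
    root: int = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        n = self.parent.size
        if self.edge_length.size != n:
            raise TreeError("parent and edge_length size mismatch")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.edge_length < 0):
            bad = int(np.flatnonzero(self.edge_length < 0)[0])
            raise TreeError(f"negative branch length above node {bad}")
        self.children = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # iterative postorder (children before parents)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=np.int64)

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @property
    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder prefix sums)."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:  # preorder
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_length[v]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        dmax = d.max()
        return bool(dmax == 0 or (d.max() - d.min()) <= rel_tol * dmax)

    def require_ultrametric(self, rel_tol: float = 1e-6) -> None:
        if not self.is_ultrametric(rel_tol):
            d = self.tip_depths()
            worst = self.labels[int(np.argmin(d))]
            raise TreeError(
                f"tree is not ultrametric: tip depths range "
                f"[{d.min():.6g}, {d.max():.6g}] (e.g. tip {worst!r})"
            )

    # ------------------------------------------------------------------
    # construction / I/O
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        dnodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in dnodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            if nd.taxon is not None and nd.taxon.label is not None:
                labels.append(str(nd.taxon.label))
            elif nd.label:
                labels.append(str(nd.label))
            else:
                raise TreeError("unlabelled tip in input tree")
        index = {id(nd): i for i, nd in enumerate(tips)}
        nxt = len(tips)
        for nd in dnodes:
            if not nd.is_leaf():
                index[id(nd)] = nxt
                nxt += 1
        parent = np.full(nxt, -1, dtype=np.int64)
        elen = np.zeros(nxt)
        for nd in dnodes:
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = labels[v] if v < len(tips) else f"internal node {v}"
                    raise TreeError(f"missing branch length above {who}")
                elen[v] = float(nd.edge.length)
        return cls(labels, parent, elen)

    @classmethod
    def from_newick(cls, s: str) -> "TimeTree":
        try:
            dtree = dendropy.Tree.get(data=s, schema="newick")
        except Exception as exc:
            raise TreeError(f"failed to parse newick (duplicate tips or "
                            f"malformed input): {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self, precision: int = 12) -> str:
        def render(v: int) -> str:
            if self.is_tip(v):
                core = _quote_label(self.labels[v])
            else:
                core = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.edge_length[v]:.{precision}g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def write(self, path, schema: str = "newick") -> None:
        if schema == "newick":
            with open(path, "w") as fh:
                fh.write(self.to_newick() + "\n")
        elif schema == "nexus":
            dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick")
            dtree.write(path=str(path), schema="nexus")
        else:
            raise ValueError(f"unknown schema {schema!r}")

    # ------------------------------------------------------------------
    # operations
    # ------------------------------------------------------------------
    def prune_to(self, keep_labels) -> "TimeTree":
        """Restrict the tree to a subset of tips.

        Degree-2 nodes created by the pruning are suppressed and their edge
        lengths summed, so root-to-tip distances of surviving taxa are
        preserved.  The new root is the MRCA of the kept tips.
        """
        keep = set(keep_labels)
        missing = keep - set(self.labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("cannot prune to fewer than 2 tips")
        n = self.n_nodes
        alive = np.zeros(n, dtype=bool)
        for lab, i in self.tip_index.items():
            alive[i] = lab in keep
        n_kept_children = np.zeros(n, dtype=np.int64)
        for v in self.postorder:
            if not self.is_tip(v):
                alive[v] = n_kept_children[v] > 0
            p = self.parent[v]
            if p >= 0 and alive[v]:
                n_kept_children[p] += 1

        # new root = deepest alive node with >= 2 kept children
        new_root = self.root
        while not self.is_tip(new_root) and n_kept_children[new_root] == 1:
            (new_root,) = [c for c in self.children[new_root] if alive[c]]

        new_labels = [lab for lab in self.labels if lab in keep]
        new_idx = {lab: i for i, lab in enumerate(new_labels)}
        old2new = np.full(n, -1, dtype=np.int64)
        parent_new: list[int] = [-1] * len(new_labels)
        elen_new: list[float] = [0.0] * len(new_labels)

        def ensure(v: int) -> int:
            # map an alive old node (kept tip or branching node) to new id
            if old2new[v] >= 0:
                return int(old2new[v])
            if self.is_tip(v):
                nv = new_idx[self.labels[v]]
            else:
                nv = len(parent_new)
                parent_new.append(-1)
                elen_new.append(0.0)
            old2new[v] = nv
            return nv

        # preorder over alive nodes, skipping suppressed degree-2 chains
        stack = [(new_root, -1, 0.0)]
        while stack:
            v, new_parent, acc = stack.pop()
            if not self.is_tip(v) and n_kept_children[v] == 1 and v != new_root:
                (c,) = [x for x in self.children[v] if alive[x]]
                stack.append((c, new_parent, acc + self.edge_length[c]))
                continue
            nv = ensure(v)
            parent_new[nv] = new_parent
            elen_new[nv] = acc
            for c in self.children[v]:
                if alive[c]:
                    stack.append((c, nv, float(self.edge_length[c])))

        return TimeTree(new_labels, np.array(parent_new), np.array(elen_new))

    def lambda_transform(self, lam: float, rel_tol: float = 1e-6) -> "TimeTree":
        """Pagel's lambda transform.

        Internal edges are multiplied by ``lam``; each pendant edge is
        stretched to ``lam * pendant + (1 - lam) * tip_depth`` so every tip
        keeps its original distance from the root.  ``lam = 1`` is the
        identity; ``lam = 0`` collapses the tree to a star.
        """
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        self.require_ultrametric(rel_tol)
        depths = self.node_depths()
        elen = self.edge_length * lam
        tips = np.arange(self.n_tips)
        elen[tips] = lam * self.edge_length[tips] + (1.0 - lam) * depths[tips]
        elen[self.root] = 0.0
        out = TimeTree(list(self.labels), self.parent.copy(), elen)
        return out

    def scale(self, factor: float) -> "TimeTree":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return TimeTree(list(self.labels), self.parent.copy(), self.edge_length * factor)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_tips={self.n_tips} n_nodes={self.n_nodes}>"


def _quote_label(lab: str) -> str:
    if any(c in lab for c in " ()[]{}:;,'\t\n"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


def read_tree(path, schema: str = "newick", require_ultrametric: bool = False,
              rel_tol: float = 1e-6) -> TimeTree:
    """Read a rooted tree with branch lengths from Newick or NEXUS.

    Parameters
    ----------
    path:
        File path.
    schema:
        ``"newick"`` or ``"nexus"`` (NEXUS TREES blocks with translate
        tables are handled by dendropy).
    require_ultrametric:
        If true, reject trees whose tip depths differ by more than
        ``rel_tol`` relative to the maximum depth.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unknown tree schema {schema!r}")
    try:
        dtree = dendropy.Tree.get(path=str(path), schema=schema)
    except Exception as exc:
        raise TreeError(f"failed to parse {schema} tree {path}: {exc}") from exc
    tree = TimeTree.from_dendropy(dtree)
    if require_ultrametric:
        tree.require_ultrametric(rel_tol)
    return tree
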