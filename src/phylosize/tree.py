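"""Rooted phylogenies with branch lengths in time units (My).

The :class:`Phylogeny` is an immutable-ish array-backed rooted tree. It is
the container every analysis module consumes: it supplies the shared-ancestry
(Brownian) covariance matrix, pruning to tip subsets, and seeded resolution
of polytomies. Newick reading is delegated to dendropy, which handles the
standard dialect (quoted labels, bracketed comments) and reports parse errors
with line/column positions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "read_newick",
]


class TreeError(ValueError):
    """Invalid tree structure or query."""


class NewickParseError(TreeError):
    """Malformed Newick input (position reported by the parser)."""


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Nodes are integer ids ``0..n_nodes-1``; the root has parent ``-1`` and
    branch length 0. Tips are ordered as they appear in the source Newick
    (left-to-right), which fixes the default row order of covariance
    matrices.

    Parameters
    ----------
    parent : sequence of int
        Parent id per node; exactly one entry must be -1 (the root).
    branch_length : sequence of float
        Length of the branch subtending each node; root entry is 0.
    labels : sequence of str or None
        Tip labels (required, unique); internal labels optional.
    """

    def __init__(self, parent, branch_length, labels):
        self._parent = np.asarray(parent, dtype=np.int64)
        self._blen = np.asarray(branch_length, dtype=float)
        self._labels = list(labels)
        n = self._parent.size
        if n < 2:
            raise TreeError("tree must have at least 2 nodes")
        if self._blen.size != n or len(self._labels) != n:
            raise TreeError("parent, branch_length, labels must align")
        roots = np.flatnonzero(self._parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        self._root = int(roots[0])
        if np.any(self._blen < 0):
            raise TreeError("negative branch length")
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self._root:
                p = int(self._parent[i])
                if not (0 <= p < n):
                    raise TreeError(f"node {i} has invalid parent {p}")
                self._children[p].append(i)
        self._postorder = self._compute_postorder()
        if len(self._postorder) != n:
            raise TreeError("tree contains a cycle or unreachable node")
        # tips in source (preorder/left-to-right) appearance order
        self._tips = [i for i in self._preorder_ids() if not self._children[i]]
        if len(self._tips) < 2:
            raise TreeError("tree must have at least 2 tips")
        tip_labels = [self._labels[i] for i in self._tips]
        if any(lbl is None or lbl == "" for lbl in tip_labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {', '.join(dups)}")
        self._tip_index = {lbl: i for lbl, i in zip(tip_labels, self._tips)}

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, allow_missing_lengths: bool = False) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): k for k, nd in enumerate(nodes)}
        parent, blen, labels = [], [], []
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                blen.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    if not allow_missing_lengths:
                        lbl = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                        raise NewickParseError(
                            f"missing branch length on edge above {lbl!r} "
                            "(pass allow_missing_lengths=True to treat as 0)"
                        )
                    blen.append(0.0)
                else:
                    blen.append(float(nd.edge.length))
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, blen, labels)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def root(self) -> int:
        return self._root

    @property
    def n_nodes(self) -> int:
        return self._parent.size

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_ids(self) -> list[int]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self._labels[i] for i in self._tips]

    def label_of(self, node: int) -> str | None:
        return self._labels[node]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def parent(self, node: int) -> int:
        return int(self._parent[node])

    def children(self, node: int) -> list[int]:
        return list(self._children[node])

    def branch_length(self, node: int) -> float:
        return float(self._blen[node])

    @property
    def branch_lengths(self) -> np.ndarray:
        return self._blen.copy()

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def postorder(self) -> list[int]:
        """Node ids, children before parents."""
        return list(self._postorder)

    def preorder(self) -> list[int]:
        return self._preorder_ids()

    def _preorder_ids(self) -> list[int]:
        out, stack = [], [self._root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(reversed(self._children[nd]))
        return out

    def _compute_postorder(self) -> list[int]:
        out, stack = [], [self._root]
        seen = set()
        while stack:
            nd = stack.pop()
            if nd in seen:
                raise TreeError("cycle detected")
            seen.add(nd)
            out.append(nd)
            stack.extend(self._children[nd])
        out.reverse()
        return out

    def is_bifurcating(self) -> bool:
        return all(
            len(self._children[i]) == 2
            for i in range(self.n_nodes) if self._children[i]
        )

    # ------------------------------------------------------------------
    # depths / ultrametricity
    # ------------------------------------------------------------------
    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths, indexed by node id."""
        depth = np.zeros(self.n_nodes)
        for nd in self._preorder_ids():
            if nd != self._root:
                depth[nd] = depth[self._parent[nd]] + self._blen[nd]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self._tips]

    @property
    def depth(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        span = d.max() - d.min()
        return bool(span <= rtol * max(d.max(), 1e-300))

    # ------------------------------------------------------------------
    # covariance
    # ------------------------------------------------------------------
    def covariance(self, tips: Sequence[str] | None = None) -> np.ndarray:
        """Brownian shared-ancestry matrix C for the requested tips.

        ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
        diagonal holds root-to-tip depths. Symmetric positive semidefinite.
        """
        depth = self.node_depths()
        n_all = self.n_tips
        pos = {t: k for k, t in enumerate(self._tips)}
        C = np.zeros((n_all, n_all))
        # tips below each node, built bottom-up
        below: dict[int, np.ndarray] = {}
        for nd in self._postorder:
            if not self._children[nd]:
                below[nd] = np.array([pos[nd]], dtype=np.int64)
                C[pos[nd], pos[nd]] = depth[nd]
            else:
                groups = [below[c] for c in self._children[nd]]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        C[np.ix_(groups[a], groups[b])] = depth[nd]
                        C[np.ix_(groups[b], groups[a])] = depth[nd]
                below[nd] = np.concatenate(groups)
                for c in self._children[nd]:
                    del below[c]
        if tips is None:
            return C
        idx = [pos[self.tip_id(t)] for t in tips]
        return C[np.ix_(idx, idx)]

    def mrca(self, a: str, b: str) -> int:
        """Most recent common ancestor node id of two tips."""
        anc = set()
        nd = self.tip_id(a)
        while nd >= 0:
            anc.add(nd)
            nd = int(self._parent[nd])
        nd = self.tip_id(b)
        while nd not in anc:
            nd = int(self._parent[nd])
        return nd

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def prune_to_tips(self, keep: Iterable[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; root-to-tip covariance is preserved.

        Unifurcations created by the pruning are collapsed by summing branch
        lengths, except at the root: the old root is retained (possibly with
        a single child) so that shared-path depths, and hence the covariance
        submatrix, are unchanged.
        """
        keep = list(keep)
        if len(set(keep)) != len(keep):
            raise TreeError("duplicate labels in keep set")
        if len(keep) < 2:
            raise TreeError("need at least 2 tips to prune to")
        keep_ids = {self.tip_id(k) for k in keep}
        n_kept = np.zeros(self.n_nodes, dtype=np.int64)
        for nd in self._postorder:
            if not self._children[nd]:
                n_kept[nd] = 1 if nd in keep_ids else 0
            else:
                n_kept[nd] = sum(n_kept[c] for c in self._children[nd])
        # rebuild, collapsing chains with a single kept-descendant child
        parent, blen, labels = [], [], []

        def new_node(p: int, length: float, label: str | None) -> int:
            parent.append(p)
            blen.append(length)
            labels.append(label)
            return len(parent) - 1

        root_new = new_node(-1, 0.0, self._labels[self._root])
        stack: list[tuple[int, int, float]] = [
            (c, root_new, float(self._blen[c]))
            for c in reversed(self._children[self._root]) if n_kept[c] > 0
        ]
        while stack:
            nd, pnew, acc = stack.pop()
            kept_children = [c for c in self._children[nd] if n_kept[c] > 0]
            if not self._children[nd]:
                new_node(pnew, acc, self._labels[nd])
            elif len(kept_children) == 1:
                c = kept_children[0]
                stack.append((c, pnew, acc + float(self._blen[c])))
            else:
                me = new_node(pnew, acc, self._labels[nd])
                for c in reversed(kept_children):
                    stack.append((c, me, float(self._blen[c])))
        return Phylogeny(parent, blen, labels)

    def resolve_polytomies(self, seed: int) -> "Phylogeny":
        """Strictly bifurcating copy; polytomies broken with zero-length branches.

        Children of each polytomy are joined pairwise in a seeded-random
        order, so the same seed always yields the same resolution. Tip
        depths, and hence the covariance matrix, are unchanged.
        """
        rng = np.random.default_rng(seed)
        parent = [int(p) for p in self._parent]
        blen = [float(b) for b in self._blen]
        labels = list(self._labels)
        children = [list(c) for c in self._children]
        for nd in list(range(len(children))):
            while len(children[nd]) > 2:
                i, j = sorted(rng.choice(len(children[nd]), size=2, replace=False))
                a, b = children[nd][i], children[nd][j]
                parent.append(nd)
                blen.append(0.0)
                labels.append(None)
                newid = len(parent) - 1
                children.append([a, b])
                parent[a] = newid
                parent[b] = newid
                children[nd] = [c for c in children[nd] if c not in (a, b)]
                children[nd].append(newid)
        return Phylogeny(parent, blen, labels)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_newick(self, include_internal_labels: bool = False) -> str:
        def fmt_label(lbl: str) -> str:
            if any(ch in lbl for ch in "()[]{}:;,' \t\n"):
                return "'" + lbl.replace("'", "''") + "'"
            return lbl

        parts: dict[int, str] = {}
        for nd in self._postorder:
            if not self._children[nd]:
                s = fmt_label(self._labels[nd])
            else:
                inner = ",".join(parts.pop(c) for c in self._children[nd])
                s = f"({inner})"
                if include_internal_labels and self._labels[nd]:
                    s += fmt_label(self._labels[nd])
            if nd != self._root:
                s += f":{self._blen[nd]:.12g}"
            parts[nd] = s
        return parts[self._root] + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, depth {self.depth:.4g}>"


def parse_newick(text: str, allow_missing_lengths: bool = False) -> Phylogeny:
    """Parse one Newick tree statement into a :class:`Phylogeny`.

    Quoted labels and ``[...]`` comments are tolerated and stripped. Missing
    branch lengths raise unless ``allow_missing_lengths`` is set (then 0).
    Malformed input (unbalanced parentheses, duplicate tip labels, empty
    tree) raises :class:`NewickParseError` naming the offending position or
    label.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(str(exc)) from exc
    return Phylogeny.from_dendropy(dtree, allow_missing_lengths=allow_missing_lengths)


def read_newick(path, allow_missing_lengths: bool = False) -> Phylogeny:
    """Read the first Newick tree from a file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read(), allow_missing_lengths=allow_missing_lengths)
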