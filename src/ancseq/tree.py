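"""Rooted phylogeny container with stable post-order node ids.

Nodes are stored in post-order, so node id ``k`` is simply position ``k``
(children always precede parents; the root is the last id).  Ids are
reassigned after any structural change, which keeps ancestor addressing
stable for a given tree object: equivalence of nodes across differently
built trees is established by comparing descendant leaf sets, never by id.

Newick reading goes through dendropy; writing emits post-order integer ids
as internal node labels so ancestors are addressable from the command line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "root_by_outgroup"]


class PhyloTree:
    """Rooted tree with branch lengths in substitutions/site.

    Attributes
    ----------
    parent : int array, parent id per node (-1 for the root)
    children : list of child-id lists per node
    lengths : float array, branch length above each node (0.0 at the root)
    labels : leaf name per node (None for internal nodes)
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        clamp_negative: bool = False,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if not (self.lengths.size == n and len(self.labels) == n):
            raise ValueError("parent/lengths/labels size mismatch")
        if np.sum(self.parent == -1) != 1 or self.parent[n - 1] != -1:
            raise ValueError("exactly one root required, stored last (post-order)")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise ValueError("nodes must be in post-order (parent id > child id)")
        neg = self.lengths < 0
        if np.any(neg):
            if clamp_negative:
                self.lengths = np.where(neg, 0.0, self.lengths)
            else:
                bad = int(np.argmax(neg))
                raise ValueError(
                    f"negative branch length {self.lengths[bad]} at node {bad}; "
                    "pass clamp_negative=True to zero it"
                )
        self.children: list[list[int]] = [[] for _ in range(n)]
        for k in range(n - 1):
            self.children[self.parent[k]].append(k)
        for k, (lab, ch) in enumerate(zip(self.labels, self.children)):
            if (lab is None) == (len(ch) == 0):
                raise ValueError(f"node {k}: leaves need labels, internals none")
        if len(set(self.leaf_labels)) != self.n_leaves:
            raise ValueError("duplicate leaf labels")

    # ------------------------------------------------------------ topology
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaf_ids(self) -> list[int]:
        return [k for k in range(self.n_nodes) if not self.children[k]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[k] for k in self.leaf_ids]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def internal_ids(self) -> list[int]:
        return [k for k in range(self.n_nodes) if self.children[k]]

    def leaf_set(self, node: int) -> frozenset[str]:
        """Descendant leaf-label set of *node* (the node-equivalence key)."""
        return self._leaf_sets()[node]

    def _leaf_sets(self) -> list[frozenset[str]]:
        if not hasattr(self, "_leaf_sets_cache"):
            sets: list[set[str]] = [set() for _ in range(self.n_nodes)]
            for k in range(self.n_nodes):  # post-order
                if self.is_leaf(k):
                    sets[k].add(self.labels[k])
                else:
                    for c in self.children[k]:
                        sets[k] |= sets[c]
            self._leaf_sets_cache = [frozenset(s) for s in sets]
        return self._leaf_sets_cache

    def mrca(self, leaf_labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of leaf labels."""
        want = set(leaf_labels)
        if not want:
            raise ValueError("empty leaf set")
        missing = want - set(self.leaf_labels)
        if missing:
            raise KeyError(f"leaf labels not in tree: {sorted(missing)}")
        for k, s in enumerate(self._leaf_sets()):  # post-order: minimal first
            if want <= s:
                return k
        raise AssertionError("unreachable: root contains all leaves")

    def depth(self, node: int) -> float:
        """Path length from the root to *node*."""
        d = 0.0
        while self.parent[node] != -1:
            d += self.lengths[node]
            node = int(self.parent[node])
        return d

    def scaled(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.parent, self.lengths * factor, self.labels)

    # ---------------------------------------------------------------- io
    @classmethod
    def from_newick(cls, source: str | Path, clamp_negative: bool = False) -> "PhyloTree":
        """Parse Newick text or a file path (branch lengths required)."""
        text = str(source)
        if "(" not in text and Path(text).exists():
            text = Path(text).read_text()
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"newick parse failed: {exc}") from exc
        return cls.from_dendropy(dtree, clamp_negative=clamp_negative)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree", clamp_negative: bool = False) -> "PhyloTree":
        order = list(dtree.postorder_node_iter())
        index = {id(nd): k for k, nd in enumerate(order)}
        parent, lengths, labels = [], [], []
        for nd in order:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(0.0 if nd.parent_node is None else float(nd.edge.length or 0.0))
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon else nd.label
                if name is None:
                    raise ValueError("unlabeled leaf in newick input")
                labels.append(str(name))
            else:
                labels.append(None)
        return cls(parent, lengths, labels, clamp_negative=clamp_negative)

    def to_dendropy(self) -> "dendropy.Tree":
        taxa = dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for k in range(self.n_nodes):
            if self.is_leaf(k):
                dnodes[k].taxon = taxa.new_taxon(self.labels[k])
            else:
                dnodes[k].label = str(k)
            if self.parent[k] != -1:
                dnodes[k].edge.length = float(self.lengths[k])
        for k in range(self.n_nodes):
            for c in self.children[k]:
                dnodes[k].add_child(dnodes[c])
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dtree.seed_node = dnodes[self.root]
        dtree.is_rooted = True
        return dtree

    def to_newick(self, path: str | Path | None = None, internal_ids: bool = True) -> str:
        dtree = self.to_dendropy()
        text = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=not internal_ids,
            unquoted_underscores=True,
        ).strip()
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree {self.n_leaves} leaves, {self.n_nodes} nodes>"

    # ------------------------------------------------------------ rooting
    def reroot_at_edge(self, child_id: int, fraction: float = 0.5) -> "PhyloTree":
        """Re-root on the edge above *child_id*, placing the new root at
        ``fraction`` of the edge length measured from the child.

        A former degree-2 root is suppressed (its two edges merge).  Node
        ids are reassigned post-order in the returned tree.
        """
        if child_id == self.root:
            raise ValueError("cannot reroot on the root's (absent) parent edge")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        # Undirected adjacency: node key -> list of (neighbor, length)
        adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(self.n_nodes)}
        for k in range(self.n_nodes - 1):
            p = int(self.parent[k])
            adj[k].append((p, float(self.lengths[k])))
            adj[p].append((k, float(self.lengths[k])))
        # Suppress an old degree-2 root (it is not a real vertex unrooted).
        old_root = self.root
        if len(adj[old_root]) == 2 and old_root not in (child_id, int(self.parent[child_id])):
            (a, la), (b, lb) = adj[old_root]
            adj[a] = [(n, l) for n, l in adj[a] if n != old_root] + [(b, la + lb)]
            adj[b] = [(n, l) for n, l in adj[b] if n != old_root] + [(a, la + lb)]
            del adj[old_root]
        p = int(self.parent[child_id])
        if p == old_root and old_root not in adj:
            raise AssertionError("edge endpoint suppressed; pick the sibling edge")
        edge_len = float(self.lengths[child_id])
        new_root_key = self.n_nodes  # fresh key
        adj[child_id] = [(n, l) for n, l in adj[child_id] if n != p] + [
            (new_root_key, edge_len * fraction)
        ]
        adj[p] = [(n, l) for n, l in adj[p] if n != child_id] + [
            (new_root_key, edge_len * (1.0 - fraction))
        ]
        adj[new_root_key] = [(child_id, edge_len * fraction), (p, edge_len * (1.0 - fraction))]
        # The old root may have been left degree-2 when the split edge was
        # incident to it; merge its two remaining edges as well.
        if old_root in adj and len(adj[old_root]) == 2 and old_root != new_root_key:
            (a, la), (b, lb) = adj[old_root]
            adj[a] = [(n, l) for n, l in adj[a] if n != old_root] + [(b, la + lb)]
            adj[b] = [(n, l) for n, l in adj[b] if n != old_root] + [(a, la + lb)]
            del adj[old_root]
        return _from_adjacency(adj, new_root_key, self.labels)


def root_by_outgroup(tree: PhyloTree, outgroup_ids: Iterable[str]) -> PhyloTree:
    """Root on the edge separating the outgroup from everything else.

    The input's own root placement is ignored (treated as unrooted); the new
    root bisects the separating edge.  Fails when no single edge separates
    the outgroup from the ingroup.
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("empty outgroup")
    all_leaves = frozenset(tree.leaf_labels)
    missing = outgroup - all_leaves
    if missing:
        raise KeyError(f"outgroup ids not in tree: {sorted(missing)}")
    if outgroup == all_leaves:
        raise ValueError("outgroup spans the whole taxon set; no separating edge")
    old_root_sets = tree._leaf_sets()
    # In the unrooted sense, the edge above node k separates leaf_set(k)
    # from its complement; a degree-2 root's two edges are one edge.
    for k in range(tree.n_nodes - 1):
        below = old_root_sets[k]
        if below == outgroup or (all_leaves - below) == outgroup:
            p = int(tree.parent[k])
            root_kids = tree.children[tree.root]
            if p == tree.root and len(root_kids) == 2:
                # The old degree-2 root sits on the separating edge: the
                # unrooted edge is the merge of both root edges, and the
                # midpoint is measured on the merged length.
                sib = root_kids[1 - root_kids.index(k)]
                lk, ls = float(tree.lengths[k]), float(tree.lengths[sib])
                total = lk + ls
                half = 0.5 * total
                if total == 0.0:
                    return tree.reroot_at_edge(k, fraction=0.5)
                if half <= lk:
                    return tree.reroot_at_edge(k, fraction=half / lk)
                return tree.reroot_at_edge(sib, fraction=(total - half) / ls)
            return tree.reroot_at_edge(k, fraction=0.5)
    raise ValueError(
        "outgroup is not separable by a single edge (not unrooted-monophyletic)"
    )


def _from_adjacency(
    adj: dict[int, list[tuple[int, float]]],
    root_key: int,
    old_labels: Sequence[str | None],
) -> PhyloTree:
    """Orient an undirected tree from *root_key* and renumber post-order."""
    post: list[tuple[int, int, float]] = []  # (key, parent_key, length)
    stack: list[tuple[int, int, float, bool]] = [(root_key, -1, 0.0, False)]
    while stack:
        key, par, length, expanded = stack.pop()
        if expanded:
            post.append((key, par, length))
            continue
        stack.append((key, par, length, True))
        for nbr, l in adj[key]:
            if nbr != par:
                stack.append((nbr, key, l, False))
    index = {key: k for k, (key, _, _) in enumerate(post)}
    parent = [index[par] if par != -1 else -1 for _, par, _ in post]
    lengths = [l for _, _, l in post]
    labels = [
        old_labels[key] if key < len(old_labels) and len(adj[key]) == 1 else None
        for key, _, _ in post
    ]
    return PhyloTree(parent, lengths, labels)
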