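"""Phylogenetic trees and the structural queries used by the dating analysis.

Trees are thin wrappers around :class:`dendropy.Tree`. Branch lengths are in
substitutions per site throughout; any per-1,000-sites or per-100,000-sites
scaling is a display concern and never stored.

The tree builder is plain neighbor-joining (Saitou & Nei 1987). It is a
desk-scale stand-in for a maximum-likelihood search: on additive distance
matrices it recovers the generating tree exactly, which is the property the
downstream path-length analyses rely on.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "build_nj_tree"]


class PhyloTree:
    """A rooted (or rootable) phylogeny with branch lengths in substitutions/site."""

    def __init__(self, tree: dendropy.Tree):
        self._t = tree

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "PhyloTree":
        # SB/Sb tip names differ only by case: labels must stay case-sensitive
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 case_sensitive_taxon_labels=True)
        tree.is_rooted = rooted
        return cls(tree)

    @classmethod
    def read_newick(cls, path, rooted: bool = True) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), rooted=rooted)

    def to_newick(self) -> str:
        return self._t.as_string(schema="newick", unquoted_underscores=True,
                                 suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ structure
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    def _leaf(self, label: str) -> dendropy.Node:
        for lf in self._t.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"unknown tip label: {label!r}")

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        """Lowest common ancestor of a set of tips (single tip -> the tip itself)."""
        labels = list(labels)
        if not labels:
            raise ValueError("empty tip set")
        known = set(self.tip_labels)
        missing = [x for x in labels if x not in known]
        if missing:
            raise KeyError(f"unknown tip labels: {missing}")
        if len(labels) == 1:
            return self._leaf(labels[0])
        # intersect root-paths
        paths = []
        for lab in labels:
            node = self._leaf(lab)
            anc = []
            while node is not None:
                anc.append(node)
                node = node.parent_node
            paths.append(anc)
        common = set(paths[0])
        for anc in paths[1:]:
            common &= set(anc)
        # deepest common ancestor = first on any root-path that is common
        for node in paths[0]:
            if node in common:
                return node
        raise RuntimeError("no common ancestor found")  # pragma: no cover

    def path_length(self, node: dendropy.Node, tip_label: str) -> float:
        """Summed branch lengths from ``node`` down to a descendant tip."""
        cur = self._leaf(tip_label)
        total = 0.0
        while cur is not node:
            if cur.parent_node is None:
                raise ValueError(
                    f"node is not an ancestor of tip {tip_label!r}")
            total += cur.edge.length or 0.0
            cur = cur.parent_node
        return total

    def path_lengths_from_node(self, node: dendropy.Node,
                               tip_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.path_length(node, t) for t in tip_labels])

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        """True iff the tips are exactly the leaf set of some subtree (rooted)."""
        want = set(labels)
        if len(want) == 1:
            return True
        node = self.mrca(want)
        have = {lf.taxon.label for lf in node.leaf_iter()}
        return have == want

    def tip_distance(self, a: str, b: str) -> float:
        """Patristic (path) distance between two tips."""
        node = self.mrca([a, b])
        return self.path_length(node, a) + self.path_length(node, b)

    def _node_to_leaf_distances(self, node: dendropy.Node) -> dict[str, float]:
        """Graph distances from an arbitrary node to every leaf (ignores rooting)."""
        dist = {node: 0.0}
        stack = [node]
        while stack:
            cur = stack.pop()
            nbrs = list(cur.child_nodes())
            if cur.parent_node is not None:
                nbrs.append(cur.parent_node)
            for nb in nbrs:
                if nb in dist:
                    continue
                edge = cur.edge if nb is cur.parent_node else nb.edge
                dist[nb] = dist[cur] + (edge.length or 0.0)
                stack.append(nb)
        return {n.taxon.label: d for n, d in dist.items() if n.is_leaf()}

    # -------------------------------------------------------------- rooting
    def root_with_outgroup(self, outgroup_labels: Iterable[str]) -> "PhyloTree":
        """Root on the branch separating the outgroup from the ingroup.

        The outgroup tips must form one side of a bipartition of the unrooted
        tree. The root is placed at the clock-balanced point of that branch:
        the position where the mean root-to-tip depth is the same on the
        outgroup and ingroup sides (clamped to the branch ends). Under a
        molecular clock this recovers the true divergence node, which is what
        the ratio-calibration uses as its reference depth. Tip-to-tip path
        lengths are unaffected by the placement.
        """
        og = set(outgroup_labels)
        all_tips = set(self.tip_labels)
        if not og or not og <= all_tips:
            raise KeyError(f"unknown outgroup tips: {sorted(og - all_tips)}")
        if og == all_tips:
            raise ValueError("outgroup cannot contain every tip")

        tree = self._t.clone(depth=1)
        tree.is_rooted = False
        target = None
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if below == og or (all_tips - below) == og:
                target = node
                break
        if target is None:
            raise ValueError("outgroup tips do not form a clade in the tree")

        edge = target.edge
        L = edge.length or 0.0
        head = target
        head_leaves = {lf.taxon.label for lf in head.leaf_iter()}
        tail_leaves = all_tips - head_leaves
        d_head = PhyloTree(tree)._node_to_leaf_distances(head)
        # Root at distance y from the head node. Head-side depth is
        # y + mean_H(d_head); tail-side depth is (L - y) + (mean_T(d_head) - L)
        # (tail-side distances measured from head include the full edge).
        # Balancing the two sides gives y = (mean_T - mean_H) / 2.
        m_head = float(np.mean([d_head[t] for t in head_leaves]))
        m_tail = float(np.mean([d_head[t] for t in tail_leaves]))
        y = 0.5 * (m_tail - m_head)
        y = min(max(y, 0.0), L)
        # length2 is assigned to the head-side edge, length1 to the tail side
        tree.reroot_at_edge(edge, length1=L - y, length2=y)
        tree.is_rooted = True
        return PhyloTree(tree)


def build_nj_tree(matrix) -> PhyloTree:
    """Neighbor-joining tree from a :class:`~supergene.distances.DistanceMatrix`.

    Returns an unrooted tree (trifurcating seed node). Negative branch length
    estimates are clamped to zero and the deficit is moved onto the sibling
    branch of the join, so that the joined pair's mutual distance is preserved.
    On an additive matrix the output reproduces every pairwise distance to
    machine precision.
    """
    ids = list(matrix.ids)
    D = np.asarray(matrix.d, dtype=float).copy()
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 samples")
    if not np.all(np.isfinite(D[~np.eye(n, dtype=bool)])):
        raise ValueError("distance matrix contains undefined entries")

    ns = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = []
    for lab in ids:
        nd = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(nd)

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        # clamp negatives; deficit moves to the sibling so li + lj is conserved
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        return parent

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = join(i, j, li, lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        # replace i with the new node, drop j
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        nodes[i] = parent
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        del nodes[j]

    # resolve the last three nodes around a central (unrooted) vertex
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    center = dendropy.Node()
    for nd, ln in zip(nodes, (l0, l1, l2)):
        center.add_child(nd)
        nd.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)
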