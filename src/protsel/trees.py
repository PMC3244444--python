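"""Rooted phylogenies with branch partitions.

Thin wrapper around :mod:`dendropy` providing the array views the
likelihood core needs (postorder edge lists, tip indexing), clade-based
branch partitions (foreground vs background), root-to-tip paths and
patristic distances.  Branch identity follows the child node: a branch is
named by its child's taxon label for terminal branches and by a stable
``node<k>`` label (postorder rank) for internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, indexed for pruning.

    Nodes are numbered in postorder; tips occupy no special range but
    ``tip_index`` maps taxon label -> node id.  ``parent[i]`` is -1 for the
    root.  Edge ``i`` is the branch above node ``i`` (undefined for the
    root; ``lengths[root]`` is 0).
    """

    newick: str
    tree: dendropy.Tree = field(repr=False)
    labels: list[str]              # per node; taxon label or "node<k>"
    parent: np.ndarray             # (n_nodes,) int, -1 at root
    lengths: np.ndarray            # (n_nodes,) float, branch above node
    children: list[list[int]]      # per node
    postorder: np.ndarray          # node ids, postorder (root last)
    tip_index: dict[str, int]

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a rooted Newick string (or path to one)."""
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                source = fh.read()
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        labels = [""] * n
        tip_index: dict[str, int] = {}
        k_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels[i] = nd.taxon.label
                if labels[i] in tip_index:
                    raise ValueError(f"duplicate tip label {labels[i]!r}")
                tip_index[labels[i]] = i
            else:
                labels[i] = f"node{k_internal}"
                k_internal += 1
        return cls(
            newick=source.strip(),
            tree=tree,
            labels=labels,
            parent=parent,
            lengths=lengths,
            children=children,
            postorder=np.arange(n),
            tip_index=tip_index,
        )

    # -- basic views ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    def branch_ids(self) -> list[int]:
        """All non-root node ids, i.e. one per branch."""
        r = self.root
        return [i for i in range(self.n_nodes) if i != r]

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        """Copy of this phylogeny with replaced branch lengths (per node)."""
        out = Phylogeny(
            newick=self.newick, tree=self.tree, labels=self.labels,
            parent=self.parent, lengths=np.asarray(lengths, dtype=float).copy(),
            children=self.children, postorder=self.postorder,
            tip_index=self.tip_index,
        )
        return out

    # -- clades and paths ---------------------------------------------

    def mrca(self, taxa: list[str]) -> int:
        ids = [self.tip_index[t] for t in taxa]
        paths = []
        for i in ids:
            path = set()
            while i != -1:
                path.add(i)
                i = self.parent[i]
            paths.append(path)
        common = set.intersection(*paths)
        # deepest common ancestor = the one whose subtree excludes others
        node = ids[0]
        while node not in common or not all(node in p for p in paths):
            node = self.parent[node]
        return node

    def subtree_nodes(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def clade_branches(self, taxa: list[str], include_stem: bool = True) -> set[int]:
        """Branch ids of the clade spanned by ``taxa``.

        Raises if ``taxa`` are not exactly the tips of a connected clade.
        ``include_stem`` adds the branch above the clade's MRCA.
        """
        node = self.mrca(taxa)
        sub = self.subtree_nodes(node)
        sub_tips = {self.labels[i] for i in sub if not self.children[i]}
        if sub_tips != set(taxa):
            raise ValueError(
                "taxa do not form a connected clade "
                f"(clade tips {sorted(sub_tips)})"
            )
        branches = {i for i in sub if i != node}
        if include_stem and node != self.root:
            branches.add(node)
        return branches

    def root_to_tip_path(self, species: str) -> list[int]:
        """Branch ids (child-node ids) from the root down to ``species``."""
        if species not in self.tip_index:
            raise KeyError(f"{species!r} is not a tip of the tree")
        path = []
        i = self.tip_index[species]
        while self.parent[i] != -1:
            path.append(i)
            i = self.parent[i]
        return path[::-1]

    def patristic_distances(self, taxa: list[str] | None = None) -> np.ndarray:
        """Matrix of path-length distances between tips (in ``taxa`` order)."""
        taxa = taxa if taxa is not None else self.tip_labels
        # node depth from root, then d(a,b) = depth(a)+depth(b)-2*depth(mrca)
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            p = self.parent[i]
            if p != -1:
                depth[i] = depth[p] + self.lengths[i]
        n = len(taxa)
        D = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                m = self.mrca([taxa[a], taxa[b]])
                d = depth[self.tip_index[taxa[a]]] + depth[self.tip_index[taxa[b]]] - 2 * depth[m]
                D[a, b] = D[b, a] = d
        return D

    def retain_taxa(self, taxa: list[str]) -> "Phylogeny":
        """Pruned copy keeping only ``taxa``; unifurcations collapsed."""
        keep = [t for t in self.tip_labels if t in set(taxa)]
        if len(keep) < 2:
            raise ValueError("need at least 2 taxa to retain")
        t = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        t.retain_taxa_with_labels(keep)
        t.suppress_unifurcations()
        newick = t.as_string(schema="newick", suppress_rooting=True)
        return Phylogeny.from_newick(newick)

    # -- output --------------------------------------------------------

    def to_newick(self, lengths: np.ndarray | None = None) -> str:
        lengths = self.lengths if lengths is None else lengths

        def fmt(i: int) -> str:
            if not self.children[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if self.parent[i] != -1:
                s += f":{lengths[i]:.10g}"
            return s

        return fmt(self.root) + ";"
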