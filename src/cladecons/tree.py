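"""Rooted phylogenetic trees with branch lengths and optional node ages.

The tree is stored as flat arrays (parent pointers, branch lengths) so the
likelihood code can traverse it cheaply; newick text is parsed and written
through dendropy, with the package's own invariant checks layered on top.
Branch lengths are in expected substitutions per site; ages, when present,
are in millions of years before present and must decrease from root to tip.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "NewickError", "parse_newick"]


class NewickError(ValueError):
    """Raised when newick text is malformed or violates tree invariants."""


class PhyloTree:
    """Rooted tree over ``n`` nodes indexed ``0..n-1`` in postorder.

    Attributes
    ----------
    parent : int array, ``-1`` for the root (always the last node).
    lengths : float array, branch length from each node to its parent
        (0 for the root).
    names : list of node labels; every leaf has a unique non-empty name.
    ages : optional float array of node ages (Myr before present).
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        names: Sequence[str | None],
        ages: Sequence[float] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.names = list(names)
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        self._validate()
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n - 1):
            self.children[self.parent[i]].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0 or self.parent[-1] != -1 or np.sum(self.parent == -1) != 1:
            raise NewickError("tree must have exactly one root, stored last")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise NewickError("nodes must be in postorder (children first)")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            bad = np.flatnonzero(~np.isfinite(self.lengths) | (self.lengths < 0))[0]
            raise NewickError(
                f"negative or non-finite branch length {self.lengths[bad]!r} "
                f"on node {self.names[bad] or bad}"
            )
        leaves = [i for i in range(n) if not np.any(self.parent == i)]
        labels = [self.names[i] for i in leaves]
        if any(not lb for lb in labels):
            raise NewickError("every leaf must carry a label")
        dup = {lb for lb in labels if labels.count(lb) > 1}
        if dup:
            raise NewickError(f"duplicate leaf label: {sorted(dup)[0]!r}")
        if self.ages is not None:
            for i in range(n - 1):
                if not self.ages[i] < self.ages[self.parent[i]]:
                    raise NewickError(
                        f"age of node {self.names[i] or i} must be below its parent"
                    )

    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices]

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def postorder(self) -> range:
        return range(self.n_nodes)

    def copy(self, lengths: Sequence[float] | None = None) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            self.lengths.copy() if lengths is None else np.asarray(lengths, float),
            list(self.names),
            None if self.ages is None else self.ages.copy(),
        )

    # ------------------------------------------------------------------ #
    def node_by_name(self, name: str) -> int:
        for i, nm in enumerate(self.names):
            if nm == name:
                return i
        raise KeyError(name)

    def mrca(self, names: Iterable[str]) -> int:
        """Most recent common ancestor of the named leaves."""
        idx = [self.node_by_name(n) for n in names]
        if not idx:
            raise ValueError("mrca of an empty set")
        paths = []
        for i in idx:
            path = [i]
            while self.parent[path[-1]] != -1:
                path.append(int(self.parent[path[-1]]))
            paths.append(set(path))
        common = set.intersection(*paths)
        return min(common)  # postorder: lowest index = most recent

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes in the clade rooted at ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return sorted(out)

    def clade_edges(self, names: Iterable[str], include_stem: bool = True) -> np.ndarray:
        """Edges (child-node ids) inside the clade spanned by ``names``.

        The stem edge is the branch above the clade's MRCA.
        """
        m = self.mrca(names)
        nodes = self.subtree_nodes(m)
        if not include_stem:
            nodes = [v for v in nodes if v != m]
        return np.array([v for v in nodes if self.parent[v] != -1], dtype=np.int64)

    def durations(self) -> np.ndarray:
        """Per-edge time spans (parent age - node age), requires ages."""
        if self.ages is None:
            raise ValueError("tree has no node ages")
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 1):
            d[i] = self.ages[self.parent[i]] - self.ages[i]
        return d

    # ------------------------------------------------------------------ #
    def induced_subtree(self, names: Iterable[str]) -> "PhyloTree":
        """Restriction of the tree to the named leaves.

        Unary internal nodes created by the restriction are suppressed and
        their branch lengths summed, so path lengths between retained leaves
        are preserved.
        """
        keep = set(names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        dtree = self._to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        # retain_taxa suppresses unifurcations internally but may leave a
        # unary root; collapse it into its single child.
        root = dtree.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            dtree.seed_node = child
            child.parent_node = None
            root = child
        return _from_dendropy(dtree, ages=self._age_map())

    def _age_map(self) -> dict[str, float] | None:
        if self.ages is None:
            return None
        return {
            self.names[i]: float(self.ages[i])
            for i in range(self.n_nodes)
            if self.names[i]
        }

    def with_ages(self, ages: dict[str, float], default_leaf_age: float = 0.0) -> "PhyloTree":
        """Attach node ages by node label; unlabeled leaves get ``default_leaf_age``."""
        arr = np.full(self.n_nodes, np.nan)
        for i in range(self.n_nodes):
            nm = self.names[i]
            if nm and nm in ages:
                arr[i] = ages[nm]
            elif self.is_leaf[i]:
                arr[i] = default_leaf_age
        if np.any(np.isnan(arr)):
            bad = [self.names[i] or i for i in np.flatnonzero(np.isnan(arr))]
            raise ValueError(f"no age for nodes: {bad}")
        return PhyloTree(self.parent, self.lengths, self.names, arr)

    # ------------------------------------------------------------------ #
    def _to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace()
        dnodes = []
        for i in range(self.n_nodes):
            nd = dendropy.Node()
            nd.edge.length = float(self.lengths[i]) if self.parent[i] != -1 else None
            if self.is_leaf[i]:
                nd.taxon = ns.require_taxon(label=self.names[i])
            elif self.names[i]:
                nd.label = self.names[i]
            dnodes.append(nd)
        for i in range(self.n_nodes - 1):
            dnodes[self.parent[i]].add_child(dnodes[i])
        return dendropy.Tree(taxon_namespace=ns, seed_node=dnodes[self.root])

    def to_newick(self) -> str:
        t = self._to_dendropy()
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()
        return s

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.leaf_names)} leaves, length={self.total_length:.4g})"


def _from_dendropy(dtree: dendropy.Tree, ages: dict[str, float] | None = None) -> PhyloTree:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    parent, lengths, names = [], [], []
    for nd in order:
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            el = nd.edge.length
            if el is None:
                el = 0.0
            lengths.append(float(el))
        if nd.taxon is not None:
            names.append(nd.taxon.label)
        else:
            names.append(nd.label)
    tree = PhyloTree(parent, lengths, names)
    if ages:
        have = {tree.names[i] for i in range(tree.n_nodes) if tree.names[i]}
        if all(
            tree.names[i] in ages for i in range(tree.n_nodes) if tree.names[i]
        ) and have:
            try:
                tree = tree.with_ages({k: v for k, v in ages.items() if k in have})
            except ValueError:
                pass
    return tree


def parse_newick(text: str) -> PhyloTree:
    """Parse newick text into a :class:`PhyloTree`.

    Raises :class:`NewickError` for malformed text, duplicate leaf labels or
    negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())
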