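"""Phylogeny handling: parsing, pruning, and phylogenetic covariance.

Trees are parsed with dendropy and wrapped in a light array-backed
:class:`Phylogeny` that exposes exactly what the samplers need: tip depths,
root-to-tip path segments, and the Brownian-motion variance-covariance
matrix ``C`` with entries ``C[i, j]`` equal to the shared path length from
the root to the most recent common ancestor of tips *i* and *j*.

Pagel's lambda is applied to the covariance matrix (off-diagonal scaling),
not to the branch lengths themselves: lambda = 0 yields a diagonal matrix,
i.e. a star phylogeny / non-phylogenetic analysis, and lambda = 1 leaves
``C`` untouched.  Tip labels are normalized by replacing whitespace with
underscores; matching is exact-string after that normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSet",
    "PhyloCovariance",
    "read_trees",
    "prune_to_taxa",
    "vcv_matrix",
    "lambda_scale",
]

_WS = re.compile(r"\s+")


def _norm_label(label: str) -> str:
    return _WS.sub("_", label.strip())


class Phylogeny:
    """A rooted tree with branch lengths, backed by flat node arrays.

    Nodes are indexed in preorder (root first).  ``parent[i]`` is the index
    of node *i*'s parent (-1 for the root) and ``length[i]`` its subtending
    branch length (0 for the root).  Tips carry unique labels.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.length = np.zeros(n, dtype=float)
        self.is_tip = np.zeros(n, dtype=bool)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(f"missing branch length on node {i}")
                bl = float(nd.edge.length)
                if not np.isfinite(bl) or bl < 0:
                    raise ValueError(f"invalid branch length {bl!r} on node {i}")
                self.length[i] = bl
            if nd.is_leaf():
                self.is_tip[i] = True
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("unlabeled tip")
                nd.taxon.label = _norm_label(nd.taxon.label)
                labels[i] = nd.taxon.label
        self.tip_indices = np.flatnonzero(self.is_tip)
        self.tip_labels: tuple[str, ...] = tuple(labels[i] for i in self.tip_indices)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dups = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        # depth of every node from the root
        self.depth = np.zeros(n, dtype=float)
        for i in range(1, n):
            self.depth[i] = self.depth[self.parent[i]] + self.length[i]
        self._tip_of = {lab: int(node) for lab, node in zip(self.tip_labels, self.tip_indices)}

    # -- basic properties --------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.depth[self.tip_indices].max())

    def tip_node(self, label: str) -> int:
        try:
            return self._tip_of[_norm_label(label)]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip distance for every tip, in tip_labels order."""
        return self.depth[self.tip_indices].copy()

    def path_to_root(self, node: int) -> list[int]:
        """Node indices from (and including) ``node`` up to, excluding, the root."""
        out = []
        while self.parent[node] >= 0:
            out.append(node)
            node = self.parent[node]
        return out

    def branches(self) -> np.ndarray:
        """Indices of all non-root nodes (each identifies its subtending branch)."""
        return np.arange(1, self.n_nodes)

    def terminal_branch_length(self, label: str) -> float:
        return float(self.length[self.tip_node(label)])

    def _clade_tips(self) -> list[tuple[str, ...]]:
        """Sorted tip-label tuple under every node."""
        sets: list[list[str] | None] = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            if sets[i] is None:
                sets[i] = []
            if self.is_tip[i]:
                sets[i] = [self.tip_labels[list(self.tip_indices).index(i)]]
            p = self.parent[i]
            if p >= 0:
                if sets[p] is None:
                    sets[p] = []
                sets[p].extend(sets[i])  # type: ignore[union-attr]
        return [tuple(sorted(s)) for s in sets]  # type: ignore[arg-type]

    def branch_ids(self) -> dict[int, str]:
        """Stable branch identifiers: the sorted tip set below the branch, '|'-joined.

        Stable across node re-orderings, so shift summaries from different
        runs (or tools) can be aligned.
        """
        clades = self._clade_tips()
        return {int(i): "|".join(clades[i]) for i in self.branches()}

    def branch_index(self) -> dict[str, int]:
        return {bid: i for i, bid in self.branch_ids().items()}

    # -- construction / export --------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        dt = dendropy.Tree.get(data=text, schema="newick")
        return cls(dt)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def prune(self, taxa: Iterable[str]) -> "Phylogeny":
        return prune_to_taxa(self, taxa)

    def vcv(self) -> "PhyloCovariance":
        return vcv_matrix(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_tips} tips, height {self.height:.3g})"


@dataclass
class TreeSet:
    """An ordered collection of phylogenies over a common taxon superset."""

    trees: list[Phylogeny]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet must contain at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    def prune(self, taxa: Iterable[str]) -> "TreeSet":
        taxa = list(taxa)
        return TreeSet([t.prune(taxa) for t in self.trees], provenance=self.provenance)


@dataclass
class PhyloCovariance:
    """Tip-indexed Brownian covariance matrix implied by a tree."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        self.matrix = m

    def reorder(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(tuple(labels), self.matrix[np.ix_(idx, idx)])


def read_trees(path: str, format: str = "newick") -> TreeSet:
    """Read all trees from a Newick or NEXUS file, in file order.

    Branch lengths are preserved exactly as written; trees lacking branch
    lengths, or containing duplicate tip labels, are rejected.  Parse errors
    on Newick input name the offending tree index.
    """
    format = format.lower()
    if format not in {"newick", "nexus"}:
        raise ValueError(f"unsupported tree format: {format!r}")
    with open(path) as fh:
        text = fh.read()
    trees: list[Phylogeny] = []
    if format == "newick":
        statements = [s.strip() for s in text.split(";") if s.strip()]
        for i, stmt in enumerate(statements):
            try:
                dt = dendropy.Tree.get(data=stmt + ";", schema="newick")
                trees.append(Phylogeny(dt))
            except Exception as exc:
                raise ValueError(f"failed to parse tree {i} in {path}: {exc}") from exc
    else:
        try:
            tl = dendropy.TreeList.get(data=text, schema="nexus")
        except Exception as exc:
            raise ValueError(f"failed to parse NEXUS file {path}: {exc}") from exc
        for i, dt in enumerate(tl):
            try:
                trees.append(Phylogeny(dt))
            except Exception as exc:
                raise ValueError(f"invalid tree {i} in {path}: {exc}") from exc
    return TreeSet(trees, provenance=path)


def prune_to_taxa(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Restrict a tree to ``taxa``, conserving all pairwise tip path lengths.

    Unbranched internal nodes left by the pruning are suppressed with their
    branch lengths summed.
    """
    wanted = [_norm_label(t) for t in taxa]
    missing = sorted(set(wanted) - set(tree.tip_labels))
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(set(wanted)) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    dt = tree._dtree.extract_tree_with_taxa_labels(labels=set(wanted))
    return Phylogeny(dt)


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Brownian variance-covariance matrix of a tree.

    ``C[i, j]`` is the depth of MRCA(i, j); ``C[i, i]`` the root-to-tip
    distance of tip *i*.
    """
    n = tree.n_tips
    C = np.zeros((n, n))
    tip_pos = {int(node): k for k, node in enumerate(tree.tip_indices)}
    # tips below each node, accumulated leaf-to-root
    below: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i in range(1, tree.n_nodes):
        children[tree.parent[i]].append(i)
    for i in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip[i]:
            below[i] = [tip_pos[i]]
        else:
            for c in children[i]:
                below[i].extend(below[c])
        # pairs of tips whose MRCA is exactly node i: across distinct children
        if not tree.is_tip[i]:
            d = tree.depth[i]
            kids = children[i]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ta in below[kids[a]]:
                        for tb in below[kids[b]]:
                            C[ta, tb] = C[tb, ta] = d
    diag = tree.tip_depths()
    np.fill_diagonal(C, diag)
    return PhyloCovariance(tree.tip_labels, C)


def lambda_scale(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonal covariances by lambda.

    lambda = 0 gives a star phylogeny (non-phylogenetic analysis); lambda = 1
    returns the covariance unchanged.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    m = C.matrix
    out = lam * m + (1.0 - lam) * np.diag(np.diag(m))
    return PhyloCovariance(C.labels, out)
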