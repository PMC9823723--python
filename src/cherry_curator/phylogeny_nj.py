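"""Unweighted neighbor joining on SSR dissimilarities, with locus-resampling
bootstrap supports.

The dissimilarity between two fingerprints is 1 minus their simple-matching
similarity (fraction of matched alleles at mutually typed loci).  Trees are
built with the classic Saitou-Nei agglomeration; ties in the Q criterion
are broken deterministically toward the lexicographically lowest pair of
cluster labels, and negative branch lengths are clamped to zero with the
deficit logged.  Bootstrap supports resample loci (columns) with
replacement and report the percentage of replicate trees containing each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core import SSRGenotype
from .identity_dedup import DEFAULT_MIN_SHARED, similarity_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)


@dataclass
class TreeNode:
    """A node of an (unrooted, stored rooted-at-trifurcation) NJ tree."""

    label: str = ""  # taxon label at leaves
    length: float = 0.0  # branch length to parent
    support: Optional[float] = None  # bootstrap % on the edge to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(l.label for l in self.leaves())


@dataclass
class SupportTree:
    """An unrooted tree with leaf labels, branch lengths and optional
    bootstrap supports on internal edges."""

    root: TreeNode

    def leaf_labels(self) -> tuple[str, ...]:
        return self.root.leaf_labels()

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each canonically represented by the
        side not containing the lexicographically smallest leaf."""
        all_leaves = set(self.leaf_labels())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def internal_edges(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(node, canonical bipartition) for every internal non-root edge."""
        all_leaves = set(self.leaf_labels())
        anchor = min(all_leaves)
        out: list[tuple[TreeNode, frozenset[str]]] = []

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.append((node, frozenset(side)))
            return below

        walk(self.root)
        return out

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: TreeNode, parent: dendropy.Node) -> None:
            for child in node.children:
                dnode = dendropy.Node()
                dnode.edge.length = child.length
                if child.is_leaf:
                    dnode.taxon = taxa.require_taxon(label=child.label)
                elif child.support is not None:
                    dnode.label = str(int(round(child.support)))
                parent.add_child(dnode)
                build(child, dnode)

        tree.seed_node.edge.length = None
        build(self.root, tree.seed_node)
        tree.is_rooted = False
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()


def dissimilarity_matrix(
    genotypes: Sequence[SSRGenotype],
    labels: Optional[Sequence[str]] = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> DissimilarityMatrix:
    """Pairwise 1 - similarity; pairs sharing too few typed loci are an
    error (the matrix must be complete for tree building)."""
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(genotypes))]
    sim, _ = similarity_matrix(genotypes, min_shared=min_shared)
    nan_pairs = [
        (labels[i], labels[j])
        for i, j in zip(*np.where(np.isnan(sim)))
        if i < j
    ]
    if nan_pairs:
        raise ValueError(f"pairs not comparable (too few shared loci): {nan_pairs}")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(labels), d)


def neighbor_joining(matrix: DissimilarityMatrix) -> SupportTree:
    """Classic Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken toward the lexicographically lowest
    (cluster label, cluster label) pair, where a cluster's label is its
    smallest leaf label; negative branch lengths are clamped to 0 and the
    deficit logged.  Returns an unrooted tree (trifurcating root).
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in matrix.labels]
    tags: list[str] = list(matrix.labels)  # smallest leaf label per cluster

    def clamp(length: float, context: str) -> float:
        if length < 0:
            log.info("negative branch length %.6f at %s clamped to 0", length, context)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((tags[i], tags[j]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li, f"join({tags[i]},{tags[j]})")
        nodes[j].length = clamp(lj, f"join({tags[i]},{tags[j]})")
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        tags = [tags[k] for k in keep] + [min(tags[i], tags[j])]

    # final trifurcation: three clusters joined at one internal node
    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = clamp(lk, "final trifurcation")
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportTree(root)


def bootstrap_support(
    genotypes: Sequence[SSRGenotype],
    labels: Optional[Sequence[str]] = None,
    B: int = 1000,
    seed: int = 0,
    min_shared: int = 1,
) -> SupportTree:
    """NJ tree with bootstrap supports from locus resampling.

    Loci (columns) are resampled with replacement B times; the support of
    an internal edge is the percentage of replicate trees containing the
    same leaf bipartition.  A single integer seed drives all replicates
    through per-replicate substreams, so runs are reproducible.
    """
    if B < 1:
        raise ValueError("bootstrap replicate count B must be >= 1")
    if len(genotypes) < 4:
        raise ValueError("bootstrap supports need at least 4 genotypes")
    loci = list(genotypes[0].alleles)
    if len(loci) < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(genotypes))]

    full = neighbor_joining(dissimilarity_matrix(genotypes, labels, min_shared))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in full.bipartitions()}

    streams = np.random.SeedSequence(seed).spawn(B)
    for rep in range(B):
        rng = np.random.default_rng(streams[rep])
        chosen = rng.integers(0, len(loci), size=len(loci))
        resampled = [
            SSRGenotype(
                {f"L{k}": g.alleles[loci[c]] for k, c in enumerate(chosen)}
            )
            if any(g.alleles[loci[c]] is not None for c in chosen)
            else None
            for g in genotypes
        ]
        if any(r is None for r in resampled):
            continue  # replicate dropped: some genotype lost all loci
        tree = neighbor_joining(
            dissimilarity_matrix(resampled, labels, min_shared=min_shared)
        )
        for bp in tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    for node, bp in full.internal_edges():
        node.support = 100.0 * counts[bp] / B
    return full
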