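"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own computational paths:
identity probabilities by Monte-Carlo genotype-pair simulation, allelic
richness by exhaustive subsample enumeration, and additive distance
matrices built from randomly grown trees whose topology is known by
construction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mc_pi(p: np.ndarray, n_pairs: int, rng) -> tuple[float, float]:
    """Monte-Carlo estimate (and SE) of P(two random HWE genotypes match)."""
    k = len(p)
    g = rng.choice(k, size=(n_pairs, 4), p=p)
    a = np.sort(g[:, :2], axis=1)
    b = np.sort(g[:, 2:], axis=1)
    same = np.all(a == b, axis=1)
    est = same.mean()
    se = math.sqrt(est * (1 - est) / n_pairs)
    return float(est), se


def mc_pi_sib(p: np.ndarray, n_pairs: int, rng) -> tuple[float, float]:
    """Monte-Carlo estimate of P(two full sibs share a genotype)."""
    k = len(p)
    mother = rng.choice(k, size=(n_pairs, 2), p=p)
    father = rng.choice(k, size=(n_pairs, 2), p=p)
    picks = rng.integers(2, size=(n_pairs, 4))
    c1 = np.stack(
        [mother[np.arange(n_pairs), picks[:, 0]], father[np.arange(n_pairs), picks[:, 1]]],
        axis=1,
    )
    c2 = np.stack(
        [mother[np.arange(n_pairs), picks[:, 2]], father[np.arange(n_pairs), picks[:, 3]]],
        axis=1,
    )
    same = np.all(np.sort(c1, axis=1) == np.sort(c2, axis=1), axis=1)
    est = same.mean()
    se = math.sqrt(est * (1 - est) / n_pairs)
    return float(est), se


def enumerate_allelic_richness(counts: dict[int, int], g: int) -> float:
    """Exact Ar(g) by enumerating every g-subset of the gene copies."""
    copies = [a for allele, c in counts.items() for a in [allele] * c]
    total = 0
    n_sub = 0
    for sub in itertools.combinations(range(len(copies)), g):
        total += len({copies[i] for i in sub})
        n_sub += 1
    return total / n_sub


def random_additive_tree(rng, n_leaves: int):
    """Random binary unrooted tree; returns (labels, distance matrix,
    internal bipartitions canonicalized by the side excluding the first
    label alphabetically).

    Grown by sequential leaf attachment, so the topology and the additive
    leaf-to-leaf distances are known independently of any NJ code.
    """
    labels = [f"T{i + 1:02d}" for i in range(n_leaves)]
    # adjacency of a tree over node ids; leaves 0..n-1
    next_id = n_leaves
    edges: dict[tuple[int, int], float] = {}

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    def edge_list():
        return [(u, v) for (u, v) in edges if u < v]

    # start with a 3-star
    center = next_id
    next_id += 1
    for leaf in range(3):
        add_edge(center, leaf, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n_leaves):
        u, v = edge_list()[rng.integers(len(edge_list()))]
        w = edges[(u, v)]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = next_id
        next_id += 1
        del edges[(u, v)], edges[(v, u)]
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(mid, leaf, float(rng.uniform(0.1, 1.0)))

    # distances by BFS over the tree
    import collections

    adj: dict[int, list[tuple[int, float]]] = collections.defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            node = queue.popleft()
            for nxt, w in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    queue.append(nxt)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]

    # bipartitions: drop each internal edge, collect leaf side
    anchor = labels[0]
    bips = set()
    internal = [(u, v) for (u, v) in edges if u < v and u >= n_leaves and v >= n_leaves]
    for u, v in internal:
        seen = {u}
        queue = collections.deque([u])
        while queue:
            node = queue.popleft()
            for nxt, w in adj[node]:
                if nxt == v and node == u:
                    continue
                if nxt not in seen and not (node == u and nxt == v):
                    seen.add(nxt)
                    queue.append(nxt)
        side = {labels[i] for i in seen if i < n_leaves}
        if 1 < len(side) < n_leaves - 1:
            side = side if anchor not in side else set(labels) - side
            bips.add(frozenset(side))
    return labels, D, bips


def support_tree_distances(tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths of a phylogeny-module tree, computed by
    an independent traversal (depth accumulation + lowest common ancestor
    via root paths)."""
    root = tree.root
    paths: dict[str, list] = {}

    def walk(node, path):
        path = path + [node]
        if node.is_leaf:
            paths[node.label] = path
        for c in node.children:
            walk(c, path)

    walk(root, [])
    labels = sorted(paths)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            shared = 0
            for a, b in zip(pi, pj):
                if a is b:
                    shared += 1
                else:
                    break
            d = sum(nd.length for nd in pi[shared:]) + sum(nd.length for nd in pj[shared:])
            D[i, j] = D[j, i] = d
    return labels, D
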