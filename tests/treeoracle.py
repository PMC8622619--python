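"""Shared test oracle: random additive trees and split/length maps.

Independent of the package's own tree machinery except for reading the
public clade structure of a built Tree.
"""

import numpy as np


def random_unrooted_tree(rng, n_taxa):
    """Adjacency map of a random unrooted binary tree with positive
    branch lengths."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    adj = {t: {} for t in taxa}

    def add(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop(u, v):
        del adj[u][v]
        del adj[v][u]

    add("I0", taxa[0], rng.uniform(0.1, 1.0))
    add("I0", taxa[1], rng.uniform(0.1, 1.0))
    add("I0", taxa[2], rng.uniform(0.1, 1.0))
    nxt = 1
    for t in taxa[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        f = rng.uniform(0.3, 0.7)
        new = f"I{nxt}"
        nxt += 1
        drop(u, v)
        add(u, new, w * f)
        add(new, v, w * (1 - f))
        add(new, t, rng.uniform(0.1, 1.0))
    return taxa, adj


def path_distances(taxa, adj):
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, t in enumerate(taxa):
            d[i, j] = dist[t]
    return (d + d.T) / 2       # exact symmetry despite float summation order


def oracle_splits_and_lengths(taxa, adj):
    """Canonical split -> length for internal edges; leaf -> pendant."""
    leafset = frozenset(taxa)
    ref = min(taxa)
    splits, pendant = {}, {}
    for u in adj:
        for v, w in adj[u].items():
            if u > v:
                continue
            # leaves on v's side when the edge is removed
            side = set()
            stack, seen = [v], {u, v}
            while stack:
                x = stack.pop()
                if x in leafset:
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if v in leafset:
                side = {v}
            if u in leafset and not side:
                side = leafset - {u}
            if len(side) == 1:
                pendant[next(iter(side))] = w
            elif len(side) == len(taxa) - 1:
                pendant[next(iter(leafset - side))] = w
            else:
                canon = frozenset(side) if ref not in side \
                    else leafset - frozenset(side)
                splits[canon] = w
    return splits, pendant


def tree_splits_and_lengths(tree):
    leafset = frozenset(tree.leaf_names())
    ref = min(leafset)
    splits, pendant = {}, {}
    for node, below in tree.clades():
        if node is tree.root:
            continue
        side = below if ref not in below else leafset - below
        if 1 < len(side) < len(leafset) - 1:
            splits[side] = node.length
    for leaf in tree.leaves():
        pendant[leaf.name] = leaf.length
    return splits, pendant


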