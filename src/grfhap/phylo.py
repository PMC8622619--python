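"""SNP-only phylogenies: distance matrices, neighbor joining, bootstrap.

The haplotype tree is built from substitution columns only: positions
covered by indels in any taxon are eliminated (the "positions containing
gaps removed" convention), as are masked microsatellite tracts, so
haplotypes that differ only by indels or repeat length collapse together.
Trees are produced by canonical neighbor joining over p- or Jukes-Cantor
distances, rooted on an outgroup pendant edge, with bootstrap support from
site resampling.  Protein trees reuse the same machinery with gap-aware
identity distances (a gap is a 21st state).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .gene_model import GeneModel
from .variants import Variant, HaplotypeRecord


class PhyloError(ValueError):
    pass


class DegenerateMatrixError(PhyloError):
    pass


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    taxa: list[str]
    sites: list[int]                 # genomic positions
    states: np.ndarray               # taxa x sites, dtype '<U1'

    def resample(self, rng) -> "SnpMatrix":
        idx = rng.integers(0, len(self.sites), size=len(self.sites))
        return SnpMatrix(self.taxa, [self.sites[i] for i in idx],
                         self.states[:, idx])


def build_snp_matrix(haplotypes, model: GeneModel,
                     mask: list[tuple[int, int]] | None = None) -> SnpMatrix:
    """Substitution-only character matrix across haplotypes.

    ``haplotypes`` is a list of :class:`HaplotypeRecord` or a mapping of
    taxon name to variant list.  Deletion/length-changing columns are
    eliminated; equal-length multi-base substitutions are decomposed into
    per-position columns.
    """
    if isinstance(haplotypes, dict):
        items = list(haplotypes.items())
    else:
        items = [(h.haplotype_id, h.variant_set) for h in haplotypes]
    taxa = [name for name, _ in items]

    subs: dict[int, dict[str, str]] = {}
    eliminated: set[int] = set()
    for name, variants in items:
        for v in variants:
            if v.vclass == "SNV":
                subs.setdefault(v.gstart, {})[name] = v.alt_allele
            elif v.vclass == "delins" and \
                    len(v.ref_allele) == len(v.alt_allele):
                for k in range(len(v.ref_allele)):
                    subs.setdefault(v.gstart + k, {})[name] = v.alt_allele[k]
            elif v.vclass in ("del", "delins"):
                eliminated.update(range(v.gstart, v.gend + 1))
            # insertions add no reference positions: ignored

    if mask:
        for a, b in mask:
            eliminated.update(range(a, b + 1))
    sites = sorted(p for p in subs if p not in eliminated)
    if not sites:
        raise DegenerateMatrixError("no polymorphic substitution columns")
    states = np.empty((len(taxa), len(sites)), dtype="<U1")
    for j, p in enumerate(sites):
        ref = model.base_at(p)
        col = subs[p]
        for i, t in enumerate(taxa):
            states[i, j] = col.get(t, ref)
    return SnpMatrix(taxa, sites, states)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(m: SnpMatrix, correction: str = "p") -> np.ndarray:
    """Pairwise distances: normalized mismatch fraction, optionally
    Jukes-Cantor corrected."""
    n, L = m.states.shape
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = float(np.mean(m.states[i] != m.states[j]))
        if correction == "JC69":
            if p >= 0.75:
                raise PhyloError(
                    f"JC69 undefined for pair ({m.taxa[i]}, {m.taxa[j]}): "
                    f"p = {p:.3f} >= 0.75")
            p = -0.75 * np.log(1 - 4 * p / 3)
        elif correction != "p":
            raise PhyloError(f"unknown correction {correction!r}")
        d[i, j] = d[j, i] = p
    return d


def identity_distance(seqs: dict[str, str], **align_params) -> tuple[list[str], np.ndarray]:
    """Alignment-based mismatch fraction between protein sequences.

    All alignment columns count; a gap aligned to a residue is a
    difference (gap = extra state).
    """
    from Bio import Align
    names = list(seqs)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = align_params.get("match", 1.0)
    aligner.mismatch_score = align_params.get("mismatch", -1.0)
    aligner.open_gap_score = align_params.get("gap_open", -3.0)
    aligner.extend_gap_score = align_params.get("gap_extend", -1.0)
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = aligner.align(seqs[names[i]], seqs[names[j]])[0]
        a, b = str(aln[0]), str(aln[1])
        diff = sum(1 for x, y in zip(a, b) if x != y)
        d[i, j] = d[j, i] = diff / len(a)
    return names, d


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name=None, length=0.0, children=None, support=None):
        self.name = name
        self.length = length
        self.children = children or []
        self.support = support

    def is_leaf(self):
        return not self.children


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[Node]:
        out = []

        def walk(n):
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)
        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def total_length(self) -> float:
        tot = 0.0

        def walk(n):
            nonlocal tot
            tot += n.length
            for c in n.children:
                walk(c)
        walk(self.root)
        return tot - self.root.length

    def clades(self):
        """(node, frozenset of leaf names below it) for internal nodes."""
        out = []

        def walk(n) -> frozenset:
            if n.is_leaf():
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            out.append((n, below))
            return below
        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side not
        containing the first taxon (unrooted comparison)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits = set()
        for node, below in self.clades():
            side = below if ref not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def newick(self, support: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if support and n.support is not None:
                label = f"{n.support:.0f}"
            return f"({inner}){label}:{n.length:.6g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    # -- rerooting -------------------------------------------------------

    def _adjacency(self):
        """Undirected edge list with lengths; nodes identified by object."""
        adj: dict[int, list] = {}
        nodes: dict[int, Node] = {}

        def walk(n):
            nodes[id(n)] = n
            for c in n.children:
                adj.setdefault(id(n), []).append((id(c), c.length))
                adj.setdefault(id(c), []).append((id(n), c.length))
                walk(c)
        walk(self.root)
        return adj, nodes


def neighbor_joining(d: np.ndarray, taxa: list[str]) -> Tree:
    """Canonical neighbor joining.

    Ties in the Q criterion are broken by the lowest (i, j) index pair in
    the current node ordering, making the algorithm deterministic.  On an
    additive distance matrix the true tree (topology and branch lengths)
    is recovered exactly.
    """
    n = len(taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    d = np.asarray(d, dtype=float).copy()
    if d.shape != (n, n) or not np.allclose(d, d.T) or (d < -1e-12).any():
        raise PhyloError("distance matrix must be symmetric non-negative")
    nodes = [Node(name=t) for t in taxa]
    active = list(range(n))
    D = d

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * D[ai, aj] - r[ai] - r[aj]
            if best is None or q < best[0] - 1e-12:
                best = (q, ai, aj)
        _, ai, aj = best
        dij = D[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        ni, nj = nodes[active[ai]], nodes[active[aj]]
        ni.length, nj.length = li, lj
        parent = Node(children=[ni, nj])
        nodes.append(parent)
        new_d = np.array([(D[ai, k] + D[aj, k] - dij) / 2
                          for k in range(m) if k not in (ai, aj)])
        keep = [k for k in range(m) if k not in (ai, aj)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        active = [active[k] for k in keep] + [len(nodes) - 1]

    # final three-way join
    (a, b, c) = active
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    na.length = max((dab + dac - dbc) / 2, 0.0)
    nb.length = max((dab + dbc - dac) / 2, 0.0)
    nc.length = max((dac + dbc - dab) / 2, 0.0)
    return Tree(Node(children=[na, nb, nc]))


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root the tree on the midpoint of the outgroup's pendant edge."""
    if outgroup not in tree.leaf_names():
        raise PhyloError(f"outgroup {outgroup!r} is not a leaf of the tree")
    adj, nodes = tree._adjacency()
    leaf_id = next(i for i, n in nodes.items()
                   if n.is_leaf() and n.name == outgroup)
    (nbr_id, length), = adj[leaf_id]

    new_nodes: dict[int, Node] = {}

    def build(nid: int, parent: int | None, edge_len: float) -> Node:
        old = nodes[nid]
        fresh = Node(name=old.name, length=edge_len, support=old.support)
        for oid, olen in adj[nid]:
            if oid != parent:
                fresh.children.append(build(oid, nid, olen))
        return fresh

    out_side = build(leaf_id, nbr_id, length / 2)
    in_side = build(nbr_id, leaf_id, length / 2)
    return Tree(Node(children=[out_side, in_side]))


def bootstrap_support(m: SnpMatrix, reps: int = 500, seed: int = 0,
                      correction: str = "p",
                      outgroup: str | None = None) -> Tree:
    """NJ tree from the full matrix, with bootstrap supports on internal
    edges (percent of column-resampled replicates containing each split)."""
    if reps < 1:
        raise PhyloError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(distance_matrix(m, correction), m.taxa)
    counts: dict[frozenset, int] = {}
    for _ in range(reps):
        rep = m.resample(rng)
        t = neighbor_joining(distance_matrix(rep, correction), rep.taxa)
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    if outgroup is not None:
        full = root_with_outgroup(full, outgroup)
    all_leaves = frozenset(full.leaf_names())
    ref = min(all_leaves)
    for node, below in full.clades():
        if node is full.root:
            continue
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * counts.get(side, 0) / reps
    return full


def write_distance_matrix(taxa: list[str], d: np.ndarray, path) -> None:
    """PHYLIP-style square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, t in enumerate(taxa):
            row = " ".join(f"{x:.6f}" for x in d[i])
            fh.write(f"{t:<12s} {row}\n")
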