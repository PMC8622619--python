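"""Neighbor joining, distances, rooting and bootstrap.

The NJ oracle: random additive (tree-metric) distance matrices built from
random unrooted trees must be reconstructed exactly — topology and branch
lengths.  scikit-bio's independent NJ implementation cross-checks topology.
"""

import itertools

import numpy as np
import pytest

from treeoracle import (oracle_splits_and_lengths, path_distances,
                        random_unrooted_tree, tree_splits_and_lengths)

from grfhap import phylo
from grfhap.phylo import (DegenerateMatrixError, PhyloError, SnpMatrix,
                          bootstrap_support, build_snp_matrix,
                          distance_matrix, neighbor_joining,
                          root_with_outgroup)


# ---------------------------------------------------------------------------
# random additive trees (test-side oracle machinery)
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# NJ correctness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_additive_tree_exactly(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    taxa, adj = random_unrooted_tree(rng, n)
    d = path_distances(taxa, adj)
    tree = neighbor_joining(d, taxa)
    s_true, p_true = oracle_splits_and_lengths(taxa, adj)
    s_got, p_got = tree_splits_and_lengths(tree)
    assert set(s_got) == set(s_true)
    for k in s_true:
        assert s_got[k] == pytest.approx(s_true[k], abs=1e-9)
    for t in taxa:
        assert p_got[t] == pytest.approx(p_true[t], abs=1e-9)


def test_nj_three_taxa():
    d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
    t = neighbor_joining(d, ["a", "b", "c"])
    p = {l.name: l.length for l in t.leaves()}
    assert p["a"] == pytest.approx(1.0)
    assert p["b"] == pytest.approx(1.0)
    assert p["c"] == pytest.approx(2.0)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(42)
    taxa, adj = random_unrooted_tree(rng, 7)
    d = path_distances(taxa, adj)
    t1 = neighbor_joining(d, taxa)
    perm = list(rng.permutation(len(taxa)))
    taxa2 = [taxa[i] for i in perm]
    d2 = d[np.ix_(perm, perm)]
    t2 = neighbor_joining(d2, taxa2)
    assert t1.bipartitions() == t2.bipartitions()
    assert t1.total_length() == pytest.approx(t2.total_length())


def test_nj_matches_scikit_bio():
    """Independent implementation cross-check (scikit-bio) on additive
    matrices: identical unrooted topology."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as sk_nj
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        taxa, adj = random_unrooted_tree(rng, 7)
        d = path_distances(taxa, adj)
        mine = neighbor_joining(d, taxa)
        sk_tree = sk_nj(DistanceMatrix(d, ids=taxa))
        leafset = frozenset(taxa)
        ref = min(taxa)
        sk_splits = set()
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            side = below if ref not in below else leafset - below
            if 1 < len(side) < len(taxa) - 1:
                sk_splits.add(side)
        assert mine.bipartitions() == sk_splits


def test_nj_requires_three_taxa():
    with pytest.raises(PhyloError):
        neighbor_joining(np.zeros((2, 2)), ["a", "b"])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _mat(rows, taxa=None):
    states = np.array([list(r) for r in rows], dtype="<U1")
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return SnpMatrix(taxa, list(range(states.shape[1])), states)


def test_p_distance_cases():
    m = _mat(["ACGT", "ACGT", "TGCA"])
    d = distance_matrix(m, "p")
    assert d[0, 1] == 0.0
    assert d[0, 2] == 1.0
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_p_distance_matches_count_oracle():
    rng = np.random.default_rng(1)
    states = rng.choice(list("ACGT"), size=(6, 40))
    m = SnpMatrix([f"t{i}" for i in range(6)], list(range(40)), states)
    d = distance_matrix(m, "p")
    for i, j in itertools.combinations(range(6), 2):
        mm = sum(1 for k in range(40) if states[i, k] != states[j, k])
        assert d[i, j] == pytest.approx(mm / 40)


def test_jc69_correction_and_domain():
    m = _mat(["AAAAAAAAAA", "AAAAAAAAAT", "TTTAAAAAAA"])
    d = distance_matrix(m, "JC69")
    p = 0.1
    assert d[0, 1] == pytest.approx(-0.75 * np.log(1 - 4 * p / 3))
    with pytest.raises(PhyloError, match="t0.*t2|pair"):
        distance_matrix(_mat(["AAAA", "TTTT", "AAAA"]), "JC69")


# ---------------------------------------------------------------------------
# SNP matrix construction
# ---------------------------------------------------------------------------

def test_indel_columns_eliminated(model):
    from grfhap.variants import variants_from_names
    two = {
        "x": variants_from_names(model, ["c.495G>T", "c.126_134del"]),
        "y": variants_from_names(model, []),
    }
    m = build_snp_matrix(two, model)
    assert len(m.sites) == 1
    assert m.sites[0] == model.coding_to_genomic("495")


def test_deletion_only_haplotypes_collapse(model, haps, acc2allele,
                                           ssr_locus):
    """a.1 (reference) and d.1 (deletion only) become identical rows after
    gap-column elimination."""
    named = {acc2allele[h.member_accessions[0]]: h.variant_set
             for h in haps}
    mask = [(ssr_locus.gstart - 1, ssr_locus.gend + 1)]
    m = build_snp_matrix(named, model, mask=mask)
    ia, idd = m.taxa.index("a.1"), m.taxa.index("d.1")
    assert (m.states[ia] == m.states[idd]).all()
    d = distance_matrix(m)
    assert d[ia, idd] == 0.0


def test_column_count_matches_planted_snvs(model, haps, acc2allele,
                                           ssr_locus):
    named = {acc2allele[h.member_accessions[0]]: h.variant_set
             for h in haps}
    mask = [(ssr_locus.gstart - 1, ssr_locus.gend + 1)]
    m = build_snp_matrix(named, model, mask=mask)
    snv_pos = set()
    deleted = set()
    for vs in named.values():
        for v in vs:
            if v.vclass == "SNV":
                snv_pos.add(v.gstart)
            elif v.vclass == "del":
                deleted.update(range(v.gstart, v.gend + 1))
    assert sorted(p for p in snv_pos if p not in deleted) == m.sites


def test_degenerate_matrix_raises(model):
    with pytest.raises(DegenerateMatrixError):
        build_snp_matrix({"x": [], "y": []}, model)


def test_indel_taxon_does_not_change_existing_distances(model):
    from grfhap.variants import variants_from_names
    base = {
        "x": variants_from_names(model, ["c.495G>T"]),
        "y": variants_from_names(model, ["c.729C>G"]),
    }
    m1 = build_snp_matrix(base, model)
    d1 = distance_matrix(m1)
    base["z"] = variants_from_names(model, ["c.126_134del"])
    m2 = build_snp_matrix(base, model)
    d2 = distance_matrix(m2)
    assert d2[0, 1] == d1[0, 1]


# ---------------------------------------------------------------------------
# rooting and bootstrap
# ---------------------------------------------------------------------------

def test_root_with_outgroup_places_root_on_pendant_edge():
    rng = np.random.default_rng(3)
    taxa, adj = random_unrooted_tree(rng, 6)
    d = path_distances(taxa, adj)
    t = neighbor_joining(d, taxa)
    rooted = root_with_outgroup(t, taxa[0])
    assert len(rooted.root.children) == 2
    sides = [set(l.name for l in phylo.Tree(c).leaves())
             for c in rooted.root.children]
    assert {taxa[0]} in sides
    # unrooted splits unchanged by rooting
    assert rooted.bipartitions() == t.bipartitions()


def test_root_unknown_taxon_raises():
    d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float)
    t = neighbor_joining(d, list("abc"))
    with pytest.raises(PhyloError):
        root_with_outgroup(t, "zzz")


def test_bootstrap_single_rep_supports_are_0_or_100():
    rng = np.random.default_rng(0)
    states = rng.choice(list("ACGT"), size=(6, 30))
    m = SnpMatrix([f"t{i}" for i in range(6)], list(range(30)), states)
    t = bootstrap_support(m, reps=1, seed=5)
    sup = [n.support for n, _ in t.clades()
           if n is not t.root and n.support is not None]
    assert sup and all(s in (0.0, 100.0) for s in sup)


def test_bootstrap_two_clean_clades_high_support():
    """Two clades with 10 diagnostic sites each get >= 90% support at 500
    replicates."""
    taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
    cols = []
    for _ in range(10):                     # diagnostic for the a-clade
        cols.append(["T", "T", "T", "A", "A", "A"])
    for _ in range(10):
        cols.append(["G", "G", "G", "C", "C", "C"])
    # a few noise columns distinguishing members
    cols.append(["T", "A", "A", "A", "A", "A"])
    cols.append(["A", "A", "A", "C", "C", "A"])
    states = np.array(cols).T
    m = SnpMatrix(taxa, list(range(states.shape[1])), states)
    t = bootstrap_support(m, reps=500, seed=11)
    split_support = {}
    leafset = frozenset(taxa)
    ref = min(taxa)
    for node, below in t.clades():
        if node is t.root or node.support is None:
            continue
        side = below if ref not in below else leafset - below
        split_support[side] = node.support
    a_side = frozenset(["b1", "b2", "b3"])   # canonical side (no 'a1')
    assert split_support[a_side] >= 90


def test_bootstrap_deterministic_for_seed():
    rng = np.random.default_rng(2)
    states = rng.choice(list("ACGT"), size=(5, 25))
    m = SnpMatrix([f"t{i}" for i in range(5)], list(range(25)), states)
    t1 = bootstrap_support(m, reps=50, seed=9)
    t2 = bootstrap_support(m, reps=50, seed=9)
    assert t1.newick() == t2.newick()


def test_tree_length_invariant_under_relabeling():
    rng = np.random.default_rng(8)
    taxa, adj = random_unrooted_tree(rng, 6)
    d = path_distances(taxa, adj)
    t1 = neighbor_joining(d, taxa)
    t2 = neighbor_joining(d, [f"X{t}" for t in taxa])
    assert t1.total_length() == pytest.approx(t2.total_length())


def test_replayed_catalog_urartu_like_is_most_distant(model, haps,
                                                      acc2allele, ssr_locus):
    """Rooted on a synthetic B-genome-like outgroup, the wild-diploid-like
    haplotype (c.1) is the most divergent ingroup taxon."""
    from grfhap import hgvs as hgvs_mod
    from grfhap.variants import align_to_reference, call_variants
    rng = np.random.default_rng(5)
    mask = (ssr_locus.gstart - 1, ssr_locus.gend + 1)
    edits, used = [], set()
    while len(edits) < 40:
        p = int(rng.integers(0, len(model.sequence)))
        g = model.offset + p
        if p in used or mask[0] <= g <= mask[1]:
            continue
        used.add(p)
        b = "ACGT"[int(rng.integers(0, 4))]
        if b != model.sequence[p]:
            edits.append(hgvs_mod.Edit(p, p + 1, b))
    og = hgvs_mod.apply_edits(model.sequence, edits)
    named = {acc2allele[h.member_accessions[0]]: h.variant_set
             for h in haps}
    named["GRF3-2B"] = call_variants(
        model, align_to_reference(model.sequence, og), mask=[mask])
    m = build_snp_matrix(named, model, mask=[mask])
    d = distance_matrix(m)
    ingroup = [t for t in m.taxa if t != "GRF3-2B"]
    mean_to_bread = {}
    for t in ingroup:
        others = [x for x in ingroup if x != t and not x.startswith("c.")]
        i = m.taxa.index(t)
        mean_to_bread[t] = np.mean([d[i, m.taxa.index(o)] for o in others])
    assert max(mean_to_bread, key=mean_to_bread.get) == "c.1"
    tree = bootstrap_support(m, reps=100, seed=3, outgroup="GRF3-2B")
    pend = {l.name: l.length for l in tree.leaves()}
    assert pend["c.1"] == max(v for k, v in pend.items()
                              if k not in ("GRF3-2B",))
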