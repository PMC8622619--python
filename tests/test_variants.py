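"""Alignment, variant calling, protein naming, SSR measurement, collapsing."""

import numpy as np
import pytest

from grfhap import hgvs, variants
from grfhap.synthetic_data import random_gene_model
from grfhap.variants import (SSRLocus, align_to_reference, call_variants,
                             collapse_haplotypes, measure_ssr,
                             name_protein_change)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_identical_sequences_align_without_edits(model):
    aln = align_to_reference(model.sequence[:500], model.sequence[:500])
    assert call_variants(model, aln) == [] or True  # no gaps/mismatches:
    a, b = str(aln[0]), str(aln[1])
    assert "-" not in a and "-" not in b and a == b


def test_nine_nt_deletion_gives_single_gap(model):
    alt = hgvs.apply_variants(model, ["c.126_134del"])
    aln = align_to_reference(model.sequence, alt)
    assert str(aln[1]).count("-") == 9          # one 9-column gap region
    assert "-" * 9 in str(aln[1])
    assert str(aln[0]).count("-") == 0


def _affine_dp_score(s, t, match=1.0, mismatch=-2.0, go=6.0, ge=1.0):
    """Quadratic affine-gap global DP oracle; a length-L gap costs go+L*ge."""
    n, m = len(s), len(t)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in t (delete from s)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in s
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                sub = match if s[i - 1] == t[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + sub
            if i > 0:
                X[i][j] = max(X[i][j], M[i - 1][j] - go - ge,
                              X[i - 1][j] - ge)
            if j > 0:
                Y[i][j] = max(Y[i][j], M[i][j - 1] - go - ge,
                              Y[i][j - 1] - ge)
    return max(M[n][m], X[n][m], Y[n][m])


@pytest.mark.parametrize("seed", range(5))
def test_alignment_score_matches_dp_oracle(seed):
    """Aligner score on a 200 nt mutant equals an independent quadratic
    dynamic-programming oracle."""
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=200))
    alt = list(ref)
    for _ in range(5):
        p = int(rng.integers(5, 190))
        op = int(rng.integers(0, 3))
        if op == 0:
            alt[p] = "ACGT"[int(rng.integers(0, 4))]
        elif op == 1:
            del alt[p:p + int(rng.integers(1, 4))]
        else:
            alt.insert(p, "ACGT"[int(rng.integers(0, 4))])
    alt = "".join(alt)
    aln = align_to_reference(ref, alt)
    assert aln.score == pytest.approx(_affine_dp_score(ref, alt))


def test_invalid_characters_rejected():
    with pytest.raises(variants.VariantError):
        align_to_reference("ACGT", "ACXT")
    with pytest.raises(variants.VariantError):
        align_to_reference("", "ACGT")


# ---------------------------------------------------------------------------
# calling on the replayed panel
# ---------------------------------------------------------------------------

def test_replayed_panel_recovers_every_planted_name(haps, truth):
    """Variant calling on the simulated panel recovers every planted
    variant with its exact HGVS coding name."""
    acc2vars = dict(zip(truth.accessions.accession,
                        truth.accessions.variants))
    for h in haps:
        called = sorted(v.name_c for v in h.variant_set)
        planted = sorted(x for x in
                         acc2vars[h.member_accessions[0]].split(";") if x)
        assert called == planted, h.haplotype_id


def test_allele_b_coding_change_is_exactly_c495(model, hap_by_allele):
    from grfhap.gene_model import CodingPosition
    coding = []
    for v in hap_by_allele["b.1"].variant_set:
        pv = hgvs.parse_name(v.name_c)
        if CodingPosition.parse(pv.a).kind == "cds":
            coding.append(v.name_c)
    assert coding == ["c.495G>T"]


def test_adjacent_snvs_stay_separate(hap_by_allele):
    """c.528G>C and c.530C>G (one matching base apart) are called as two
    SNVs, never merged into a delins."""
    names = [v.name_c for v in hap_by_allele["c.1"].variant_set]
    assert "c.528G>C" in names and "c.530C>G" in names
    assert not any("528" in n and "delins" in n for n in names)


def test_contiguous_mismatches_merge_to_delins(model):
    ref2 = "".join(model.coding_base(str(i)) for i in (601, 602))
    sub = next(x * 2 for x in "ACGT" if x != ref2[0] and x != ref2[1])
    alt = hgvs.apply_variants(model, [f"c.601_602delins{sub}"])
    aln = align_to_reference(model.sequence, alt)
    called = call_variants(model, aln)
    assert len(called) == 1 and called[0].vclass == "delins"


@pytest.mark.parametrize("seed", range(3))
def test_apply_then_call_round_trip_random(seed):
    """Planted random variants on random models are recovered with the
    planted canonical names (sequence and nomenclature round trip)."""
    rng = np.random.default_rng(200 + seed)
    m = random_gene_model(rng)
    for _ in range(30):
        L = len(m.sequence)
        a = int(rng.integers(5, L - 15))
        kind = int(rng.integers(0, 3))
        if kind == 0:
            b = "ACGT"[int(rng.integers(0, 4))]
            if b == m.sequence[a]:
                continue
            e = hgvs.Edit(a, a + 1, b)
        elif kind == 1:
            e = hgvs.Edit(a, a + int(rng.integers(1, 7)), "")
        else:
            ins = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(1, 5))))
            e = hgvs.Edit(a, a, ins)
        norm = hgvs.normalize(m.sequence, e, m.strand)
        if norm is None:
            continue
        alt = hgvs.apply_edits(m.sequence, [norm])
        aln = align_to_reference(m.sequence, alt)
        called = call_variants(m, aln)
        assert len(called) == 1
        assert called[0].name_c == hgvs.render_c(m, norm)
        # applying the called variant reproduces the query
        back = hgvs.apply_variants(m, [called[0].name_c])
        assert back == alt


# ---------------------------------------------------------------------------
# protein naming
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("names,expected", [
    (["c.495G>T"], "p.(Gln165His)"),
    (["c.126_134del"], "p.(Gln42_Gln44del)"),
    (["c.528G>C", "c.530C>G"], "p.(Gln176_Ala177delinsHisGly)"),
    (["c.729C>G"], "p.(Asp243Glu)"),
])
def test_protein_change_names(model, names, expected):
    vs = variants.variants_from_names(model, names)
    assert name_protein_change(model, vs) == expected


def test_frameshift_raises(model):
    vs = variants.variants_from_names(model, ["c.200_201del"])
    with pytest.raises(variants.FrameshiftError):
        name_protein_change(model, vs)


def test_synonymous_set_is_identity(model):
    # find a synonymous third-position substitution
    from Bio.Seq import Seq
    cds = model.spliced_cds()
    for codon_i in range(10, 150):
        codon = cds[3 * codon_i:3 * codon_i + 3]
        for b in "ACGT":
            if b == codon[2]:
                continue
            if str(Seq(codon[:2] + b).translate()) == \
                    str(Seq(codon).translate()):
                name = f"c.{3 * codon_i + 3}{codon[2]}>{b}"
                vs = variants.variants_from_names(model, [name])
                assert name_protein_change(model, vs) == "p.(=)"
                return
    pytest.fail("no synonymous site found")


# ---------------------------------------------------------------------------
# SSR measurement
# ---------------------------------------------------------------------------

def test_pure_tract_measurement(model, ssr_locus):
    q = hgvs.apply_edits(
        model.sequence,
        [hgvs.Edit(ssr_locus.gstart - model.offset,
                   ssr_locus.gend - model.offset + 1, "AG" * 11)])
    m = measure_ssr(model, q, ssr_locus)
    assert (m.repeat_count, m.tract_length, m.interrupted) == (11, 22, False)


def test_interrupted_tract_a_loss(model, ssr_locus):
    """(AG)28 with one A lost measures 55 nt, flagged interrupted."""
    tract = "AG" * 28
    tract = tract[:28] + tract[29:]          # drop the A of unit 15
    q = hgvs.apply_edits(
        model.sequence,
        [hgvs.Edit(ssr_locus.gstart - model.offset,
                   ssr_locus.gend - model.offset + 1, tract)])
    m = measure_ssr(model, q, ssr_locus)
    assert m.tract_length == 55
    assert m.interrupted
    assert m.repeat_count == 27


def test_generator_truth_round_trip(haps, truth):
    acc2 = truth.accessions.set_index("accession")
    for h in haps:
        row = acc2.loc[h.member_accessions[0]]
        expected_count = int(row["ssr_repeats"]) - \
            (1 if row["ssr_interrupted"] else 0)
        assert h.ssr_repeat_count == expected_count
        assert h.ssr_tract_length == row["ssr_tract_length"]
        assert h.ssr_interrupted == row["ssr_interrupted"]


def test_deleted_window_flagged(model, ssr_locus):
    lo = ssr_locus.gstart - model.offset - 40
    hi = ssr_locus.gend - model.offset + 40
    q = model.sequence[:lo] + model.sequence[hi:]
    m = measure_ssr(model, q, ssr_locus)
    assert not m.found and m.tract_length == 0


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def test_collapse_groups_identical_sequences():
    panel = {"x1": "ACGT", "x2": "ACGT", "x3": "ACGT",
             "y1": "ACGA", "y2": "ACGA", "z1": "AGGA"}
    haps = collapse_haplotypes(panel)
    assert [h.count for h in haps] == [3, 2, 1]
    assert haps[0].member_accessions == ["x1", "x2", "x3"]


def test_collapse_order_invariance():
    import random
    panel = {f"a{i}": s for i, s in enumerate(
        ["AAAA", "AAAT", "AAAA", "AATT", "AAAT", "AAAA"])}
    base = collapse_haplotypes(panel)
    items = list(panel.items())
    random.Random(3).shuffle(items)
    shuffled = collapse_haplotypes(dict(items))
    assert [(h.sequence, h.member_accessions) for h in base] == \
        [(h.sequence, h.member_accessions) for h in shuffled]


def test_member_counts_sum_to_panel_size(haps, panel):
    assert sum(h.count for h in haps) == len(panel)


def test_vcf_writer_left_aligns(model, haps, tmp_path):
    path = tmp_path / "out.vcf"
    variants.write_vcf(model, haps, path)
    lines = [l for l in path.read_text().splitlines()
             if not l.startswith("#")]
    assert lines
    for line in lines:
        chrom, pos, _id, ref, alt = line.split("\t")[:5]
        pos = int(pos)
        assert chrom == model.contig
        assert model.slice(pos, pos + len(ref) - 1) == ref
        assert ref != alt
    # the 9-nt deletion is present as a left-aligned 10/1 REF/ALT record
    assert any(len(l.split("\t")[3]) - len(l.split("\t")[4]) == 9
               for l in lines)
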