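"""Variant discovery and naming over a single-gene region.

Each accession sequence is globally aligned to the reference (affine gap
penalties), mismatching alignment runs are extracted as normalized variants
with HGVS g. and c. names, the 5'UTR microsatellite is measured separately,
and byte-identical sequences are collapsed into haplotypes.

Microsatellite tracts are excluded from SNV/indel calling (their length
variation is reported by :func:`measure_ssr` instead), mirroring how the
locus is treated as two separate axes of variation: point/indel variants on
the one hand, repeat length on the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from . import hgvs
from .gene_model import GeneModel, cds_to_protein_position, revcomp

_DNA_OK = set("ACGTN")


class VariantError(ValueError):
    pass


class FrameshiftError(VariantError):
    """Combined variant set is not in-frame (unsupported)."""


@dataclass(frozen=True)
class Variant:
    """A normalized difference against the reference.

    ``gstart``/``gend`` are 1-based inclusive genomic coordinates; for pure
    insertions they are the two flanking bases.  ``ref_allele`` and
    ``alt_allele`` are plus-strand sequences (one may be empty).  Indels are
    3'-shifted on the coding strand.
    """
    gstart: int
    gend: int
    ref_allele: str
    alt_allele: str
    vclass: str            # SNV | del | ins | delins
    name_g: str
    name_c: str
    contig: str

    @property
    def name_g_full(self) -> str:
        return f"{self.contig}:{self.name_g}"


@dataclass
class SSRLocus:
    """A microsatellite locus: repeat unit and reference tract interval."""
    unit: str
    gstart: int
    gend: int
    name: str = "SSR"


@dataclass
class SsrMeasurement:
    repeat_count: int
    tract_length: int
    interrupted: bool
    found: bool


@dataclass
class HaplotypeRecord:
    haplotype_id: str
    member_accessions: list[str]
    sequence: str = ""
    variant_set: list[Variant] = field(default_factory=list)
    ssr_repeat_count: int = 0
    ssr_tract_length: int = 0
    ssr_interrupted: bool = False

    @property
    def count(self) -> int:
        return len(self.member_accessions)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

#: default affine-gap scores: a gap of length L costs 6 + L.
DEFAULT_ALIGN_PARAMS = dict(match=1.0, mismatch=-2.0,
                            gap_open=-6.0, gap_extend=-1.0)


def make_aligner(match=1.0, mismatch=-2.0, gap_open=-6.0, gap_extend=-1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gap base and
    # extend_gap_score for each further one; fold the per-base cost in.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference(ref: str, query: str, **params):
    """Global pairwise alignment of query against the reference.

    Deterministic for fixed inputs: the first optimal alignment in
    Biopython's canonical enumeration order is returned.
    """
    for name, s in (("reference", ref), ("query", query)):
        if not s:
            raise VariantError(f"{name} sequence is empty")
        bad = set(s.upper()) - _DNA_OK
        if bad:
            raise VariantError(
                f"{name} contains invalid characters {sorted(bad)}")
    aligner = make_aligner(**{**DEFAULT_ALIGN_PARAMS, **params})
    return aligner.align(ref.upper(), query.upper())[0]


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _alignment_runs(aref: str, aqry: str):
    """Yield (ref_start, ref_end, alt) raw edits from gapped strings.

    Adjacent non-matching columns (mismatch or gap) form a single run, so
    truly contiguous events merge while events separated by at least one
    matching column stay apart.
    """
    rpos = 0                      # consumed reference bases
    run_start = None
    run_alt: list[str] = []
    for cr, cq in zip(aref, aqry):
        if cr != "-" and cq != "-" and cr == cq:
            if run_start is not None:
                yield run_start, rpos, "".join(run_alt)
                run_start, run_alt = None, []
            rpos += 1
            continue
        if run_start is None:
            run_start = rpos
            run_alt = []
        if cq != "-":
            run_alt.append(cq)
        if cr != "-":
            rpos += 1
    if run_start is not None:
        yield run_start, rpos, "".join(run_alt)


def call_variants(model: GeneModel, alignment,
                  mask: list[tuple[int, int]] | None = None) -> list[Variant]:
    """Extract normalized, named variants from a reference/query alignment.

    ``mask`` lists genomic intervals (1-based inclusive) whose variants are
    suppressed (e.g. a microsatellite tract).
    """
    aref, aqry = str(alignment[0]), str(alignment[1])
    seq = model.sequence
    out: list[Variant] = []
    for rs, re_, alt in _alignment_runs(aref, aqry):
        edit = hgvs.normalize(seq, hgvs.Edit(rs, re_, alt), model.strand)
        if edit is None:
            continue
        gs = model.offset + edit.start
        ge = model.offset + edit.end - 1
        if edit.start == edit.end:           # insertion: flanking pair
            gs, ge = gs - 1, gs
        if mask and any(gs <= m_end and m_start <= ge
                        for m_start, m_end in mask):
            continue
        out.append(Variant(
            gstart=gs, gend=ge,
            ref_allele=seq[edit.start:edit.end], alt_allele=edit.alt,
            vclass=hgvs.classify(seq, edit),
            name_g=hgvs.render_g(model, edit),
            name_c=hgvs.render_c(model, edit),
            contig=model.contig))
    return out


def variants_from_names(model: GeneModel, names: list[str]) -> list[Variant]:
    """Build Variant records directly from HGVS names (no alignment)."""
    out = []
    for n in names:
        edit = hgvs.normalize(model.sequence, hgvs.resolve(model, n),
                              model.strand)
        if edit is None:
            raise VariantError(f"{n} is an identity on this model")
        gs = model.offset + edit.start
        ge = model.offset + edit.end - 1
        if edit.start == edit.end:
            gs, ge = gs - 1, gs
        out.append(Variant(
            gstart=gs, gend=ge,
            ref_allele=model.sequence[edit.start:edit.end],
            alt_allele=edit.alt, vclass=hgvs.classify(model.sequence, edit),
            name_g=hgvs.render_g(model, edit),
            name_c=hgvs.render_c(model, edit), contig=model.contig))
    return out


# ---------------------------------------------------------------------------
# protein-level naming
# ---------------------------------------------------------------------------

def _apply_to_cds(model: GeneModel, variant_set: list[Variant]) -> str:
    """Alternate spliced CDS after applying the CDS-region variants."""
    cds = model.spliced_cds()
    L = len(cds)
    edits = []
    for v in variant_set:
        pv = hgvs.parse_name(v.name_c)
        try:
            a1 = _cds_index(pv.a)
            a2 = _cds_index(pv.b) if pv.b else a1
        except _NotCds:
            continue                      # UTR/intron variant: CDS unchanged
        if pv.vtype == "ins":
            ins = pv.alt
            edits.append((a2 - 1, a2 - 1, ins))
        else:
            alt = pv.alt
            edits.append((a1 - 1, a2, alt))
    edits.sort()
    out = cds
    for s, e, alt in reversed(edits):
        if not (0 <= s <= e <= L):
            raise VariantError("variant extends beyond the CDS")
        out = out[:s] + alt + out[e:]
    return out


class _NotCds(Exception):
    pass


def _cds_index(addr: str) -> int:
    from .gene_model import CodingPosition
    cp = CodingPosition.parse(addr)
    if cp.kind != "cds":
        raise _NotCds
    return cp.base


def name_protein_change(model: GeneModel,
                        variant_set: list[Variant]) -> str:
    """HGVS p. description of the combined effect of a variant set.

    Deletions inside repeat runs take the most C-terminal placement;
    substitutions of consecutive residues collapse into a delins.
    Synonymous sets yield ``p.(=)``.
    """
    alt_cds = _apply_to_cds(model, variant_set)
    if len(alt_cds) % 3:
        raise FrameshiftError(
            "variant set changes CDS length by a non-multiple of 3; "
            "frameshift naming is not supported")
    ref_p = str(Seq(model.spliced_cds()).translate()).rstrip("*")
    alt_p = str(Seq(alt_cds).translate())
    if "*" in alt_p[:-1]:
        alt_p = alt_p[:alt_p.index("*")]
    else:
        alt_p = alt_p.rstrip("*")

    # maximal common prefix then suffix => most C-terminal placement
    i = 0
    while i < len(ref_p) and i < len(alt_p) and ref_p[i] == alt_p[i]:
        i += 1
    j = 0
    while (j < len(ref_p) - i and j < len(alt_p) - i
           and ref_p[-1 - j] == alt_p[-1 - j]):
        j += 1
    ref_mid = ref_p[i:len(ref_p) - j]
    alt_mid = alt_p[i:len(alt_p) - j]

    if not ref_mid and not alt_mid:
        return "p.(=)"
    if len(ref_mid) == 1 and len(alt_mid) == 1:
        return f"p.({seq3(ref_mid)}{i + 1}{seq3(alt_mid)})"
    if not alt_mid:
        first = f"{seq3(ref_mid[0])}{i + 1}"
        if len(ref_mid) == 1:
            return f"p.({first}del)"
        last = f"{seq3(ref_mid[-1])}{i + len(ref_mid)}"
        return f"p.({first}_{last}del)"
    if not ref_mid:
        left = f"{seq3(ref_p[i - 1])}{i}"
        right = f"{seq3(ref_p[i])}{i + 1}"
        return f"p.({left}_{right}ins{''.join(seq3(a) for a in alt_mid)})"
    first = f"{seq3(ref_mid[0])}{i + 1}"
    last = f"{seq3(ref_mid[-1])}{i + len(ref_mid)}"
    ins = "".join(seq3(a) for a in alt_mid)
    return f"p.({first}_{last}delins{ins})"


# ---------------------------------------------------------------------------
# microsatellite measurement
# ---------------------------------------------------------------------------

def _merged_runs(text: str, unit: str):
    """Maximal unit runs, merging runs separated by <unit-length gaps that
    are a prefix or suffix of the unit (interrupted repeats)."""
    runs = []
    k = len(unit)
    p = 0
    while p + k <= len(text):
        if text[p:p + k] == unit:
            q = p
            while q + k <= len(text) and text[q:q + k] == unit:
                q += k
            runs.append((p, q))
            p = q
        else:
            p += 1
    merged = []
    for s, e in runs:
        if merged:
            ps, pe = merged[-1]
            gap = text[pe:s]
            if 0 < len(gap) < k and (unit.startswith(gap)
                                     or unit.endswith(gap)):
                merged[-1] = (ps, e)
                continue
            if len(gap) == 0:
                merged[-1] = (ps, e)
                continue
        merged.append((s, e))
    return merged


def measure_ssr(model: GeneModel, query: str, locus: SSRLocus,
                anchor_len: int = 20) -> SsrMeasurement:
    """Measure the microsatellite tract of ``locus`` in ``query``.

    The tract is located by exact search for the reference sequence
    flanking the tract (downstream anchor first, then upstream).  The
    longest merged repeat run adjacent to the anchor is reported;
    single-base losses inside the tract count toward ``tract_length`` and
    set ``interrupted``.
    """
    query = query.upper()
    unit = locus.unit
    right_anchor = model.slice(locus.gend + 1, locus.gend + anchor_len)
    left_anchor = model.slice(locus.gstart - anchor_len, locus.gstart - 1)

    window = None
    rpos = query.find(right_anchor)
    if right_anchor and rpos != -1 and query.find(right_anchor, rpos + 1) == -1:
        lo = max(0, rpos - 2 * (locus.gend - locus.gstart + 1) - 20)
        window = (lo, rpos)
    else:
        lpos = query.find(left_anchor)
        if left_anchor and lpos != -1 \
                and query.find(left_anchor, lpos + 1) == -1:
            start = lpos + len(left_anchor)
            hi = min(len(query),
                     start + 2 * (locus.gend - locus.gstart + 1) + 20)
            window = (start, hi)
    if window is None:
        return SsrMeasurement(0, 0, False, False)

    text = query[window[0]:window[1]]
    runs = _merged_runs(text, unit)
    if not runs:
        return SsrMeasurement(0, 0, False, True)
    s, e = max(runs, key=lambda r: r[1] - r[0])
    span = text[s:e]
    tract_length = len(span)
    # count non-overlapping full units
    repeat_count = 0
    p = 0
    while p + len(unit) <= len(span):
        if span[p:p + len(unit)] == unit:
            repeat_count += 1
            p += len(unit)
        else:
            p += 1
    interrupted = tract_length != repeat_count * len(unit)
    return SsrMeasurement(repeat_count, tract_length, interrupted, True)


# ---------------------------------------------------------------------------
# haplotype collapsing and the panel pipeline
# ---------------------------------------------------------------------------

def collapse_haplotypes(panel: dict[str, str]) -> list[HaplotypeRecord]:
    """Group byte-identical sequences; order by size, then first member."""
    groups: dict[str, list[str]] = {}
    for acc in sorted(panel):
        groups.setdefault(panel[acc].upper(), []).append(acc)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-len(kv[1]), kv[1][0]))
    width = max(2, len(str(len(ordered))))
    return [
        HaplotypeRecord(haplotype_id=f"H{i + 1:0{width}d}",
                        member_accessions=members, sequence=seq)
        for i, (seq, members) in enumerate(ordered)
    ]


def analyze_panel(model: GeneModel, panel: dict[str, str],
                  ssr_locus: SSRLocus | None = None,
                  **align_params) -> list[HaplotypeRecord]:
    """Full pipeline: collapse, align each haplotype, call and name variants,
    measure the microsatellite."""
    haps = collapse_haplotypes(panel)
    mask = None
    if ssr_locus is not None:
        mask = [(ssr_locus.gstart - 1, ssr_locus.gend + 1)]
    for h in haps:
        if h.sequence == model.sequence:
            h.variant_set = []
        else:
            aln = align_to_reference(model.sequence, h.sequence,
                                     **align_params)
            h.variant_set = call_variants(model, aln, mask=mask)
        if ssr_locus is not None:
            m = measure_ssr(model, h.sequence, ssr_locus)
            h.ssr_repeat_count = m.repeat_count
            h.ssr_tract_length = m.tract_length
            h.ssr_interrupted = m.interrupted
    return haps


def read_panel_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_panel_fasta(panel: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in panel.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_variant_table(haps: list[HaplotypeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\taccessions\tname_g\tname_c\tvclass\n")
        for h in haps:
            members = ",".join(h.member_accessions)
            if not h.variant_set:
                fh.write(f"{h.haplotype_id}\t{members}\t.\t.\t.\n")
            for v in h.variant_set:
                fh.write(f"{h.haplotype_id}\t{members}\t{v.name_g_full}\t"
                         f"{v.name_c}\t{v.vclass}\n")


# ---------------------------------------------------------------------------
# minimal VCF 4.2 writer
# ---------------------------------------------------------------------------

def _left_align(seq: str, edit: hgvs.Edit) -> tuple[int, str, str]:
    """VCF-style left-aligned POS/REF/ALT (1-based local POS; anchor base
    prepended for indels, per VCF convention)."""
    start, end, alt = edit.start, edit.end, edit.alt
    ref = seq[start:end]
    if len(ref) == 1 and len(alt) == 1:
        return start + 1, ref, alt
    # shift pure indels left on the plus strand
    if not ref or not alt:
        while start > 0:
            if not alt and seq[start - 1] == seq[end - 1]:   # deletion
                start, end = start - 1, end - 1
                continue
            if not ref and alt and seq[start - 1] == alt[-1]:  # insertion
                alt = alt[-1] + alt[:-1]
                start, end = start - 1, end - 1
                continue
            break
        ref = seq[start:end]
    if start == 0:
        # region starts inside the event: anchor on the right instead
        return 1, ref + seq[end], alt + seq[end]
    return start, seq[start - 1] + ref, seq[start - 1] + alt


def write_vcf(model: GeneModel, haps: list[HaplotypeRecord], path) -> None:
    """Sites-only VCF 4.2 with left-anchored REF/ALT.

    Note this representation differs from the HGVS names, which are
    3'-shifted on the coding strand; both describe the same edits.
    """
    site_map: dict[tuple[int, str, str], set[str]] = {}
    for h in haps:
        for v in h.variant_set:
            edit = hgvs.Edit(v.gstart - model.offset,
                             v.gend - model.offset + 1, v.alt_allele)
            if v.vclass == "ins":
                edit = hgvs.Edit(v.gend - model.offset,
                                 v.gend - model.offset, v.alt_allele)
            pos0, ref, alt = _left_align(model.sequence, edit)
            site_map.setdefault((model.offset + pos0 - 1, ref, alt),
                                set()).add(h.haplotype_id)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={model.contig}>\n")
        fh.write("##INFO=<ID=HAPS,Number=.,Type=String,"
                 "Description=\"Haplotypes carrying the allele\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (pos, ref, alt), hap_ids in sorted(site_map.items()):
            info = "HAPS=" + ",".join(sorted(hap_ids))
            fh.write(f"{model.contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")
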