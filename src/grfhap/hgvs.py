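"""HGVS-style variant names: parsing, normalization, rendering, application.

Variants are held internally as *edits*: a replacement of the half-open,
0-based local interval ``[start, end)`` of the stored plus-strand sequence
by ``alt`` (empty ``alt`` for deletions, ``start == end`` for pure
insertions).  Normalization trims shared prefix/suffix bases and 3'-shifts
pure indels along the *coding* strand, the most-3' representation.

Accepted textual forms (optionally prefixed ``contig:``)::

    c.495G>T            g.687050412G>T
    c.126_134del        g.687052487_687052488del
    c.-102_-91del       c.*8C>T
    c.325+32_325+33insTCC   (abbreviated alias c.325+32_+33insTCC)
    c.528_530delinsCTG

Deletion names may carry the deleted bases (``delAG``); they are checked
against the reference when present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .gene_model import CodingPosition, GeneModel, GeneModelError, revcomp


class HgvsError(ValueError):
    pass


_CADDR = r"\*?-?\d+(?:[+-]\d+)?"
_NAME_RE = re.compile(
    r"^(?:(?P<contig>[\w.]+):)?(?P<scope>[cg])\.(?P<rest>.+)$")
_SUB_RE = re.compile(
    r"^(?P<p>%s)(?P<ref>[ACGT])>(?P<alt>[ACGT])$" % _CADDR)
_DELINS_RE = re.compile(
    r"^(?P<a>%s)(?:_(?P<b>%s|\+\d+))?delins(?P<seq>[ACGT]+)$"
    % (_CADDR, _CADDR))
_DEL_RE = re.compile(
    r"^(?P<a>%s)(?:_(?P<b>%s|\+\d+))?del(?P<seq>[ACGT]*)$"
    % (_CADDR, _CADDR))
_INS_RE = re.compile(
    r"^(?P<a>%s)_(?P<b>%s|\+\d+)ins(?P<seq>[ACGT]+)$" % (_CADDR, _CADDR))


@dataclass(frozen=True)
class Edit:
    """Replacement of local plus-strand interval [start, end) by ``alt``."""
    start: int
    end: int
    alt: str

    def __post_init__(self):
        if self.start > self.end or self.start < 0:
            raise HgvsError(f"bad edit interval {self.start}:{self.end}")


@dataclass(frozen=True)
class ParsedVariant:
    scope: str            # 'c' or 'g'
    vtype: str            # 'sub' | 'del' | 'ins' | 'delins'
    a: str                # first address (text)
    b: str | None         # second address, if a range
    ref: str              # stated reference allele ('' if none)
    alt: str              # substituted/inserted sequence ('' for del)
    contig: str | None = None


def _expand_abbrev(a: str, b: str) -> str:
    """Expand the abbreviated intron alias: 325+32_+33 -> 325+33.

    Only plus offsets can be abbreviated; a bare ``-N`` is always read as
    a 5'UTR address (the two are otherwise ambiguous).
    """
    if re.match(r"^\+\d+$", b):
        m = re.match(r"^(\*?-?\d+)[+-]\d+$", a)
        if not m:
            raise HgvsError(f"abbreviated offset {b!r} without intron anchor")
        return m.group(1) + b
    return b


def parse_name(text: str) -> ParsedVariant:
    m = _NAME_RE.match(text.strip())
    if not m:
        raise HgvsError(f"cannot parse variant name {text!r}")
    scope, rest, contig = m.group("scope"), m.group("rest"), m.group("contig")
    s = _SUB_RE.match(rest)
    if s:
        return ParsedVariant(scope, "sub", s.group("p"), None,
                             s.group("ref"), s.group("alt"), contig)
    d = _DELINS_RE.match(rest)
    if d:
        b = _expand_abbrev(d.group("a"), d.group("b")) if d.group("b") else None
        return ParsedVariant(scope, "delins", d.group("a"), b, "",
                             d.group("seq"), contig)
    d = _DEL_RE.match(rest)
    if d:
        b = _expand_abbrev(d.group("a"), d.group("b")) if d.group("b") else None
        return ParsedVariant(scope, "del", d.group("a"), b,
                             d.group("seq"), "", contig)
    i = _INS_RE.match(rest)
    if i:
        return ParsedVariant(scope, "ins", i.group("a"),
                             _expand_abbrev(i.group("a"), i.group("b")),
                             "", i.group("seq"), contig)
    raise HgvsError(f"cannot parse variant description {rest!r}")


# -- resolution to edits -----------------------------------------------------

def _addr_to_genomic(model: GeneModel, scope: str, addr: str) -> int:
    if scope == "g":
        return int(addr)
    return model.coding_to_genomic(CodingPosition.parse(addr))


def resolve(model: GeneModel, name: str | ParsedVariant) -> Edit:
    """Turn an HGVS c./g. name into a plus-strand local edit."""
    pv = parse_name(name) if isinstance(name, str) else name
    minus = model.strand == "-" and pv.scope == "c"
    ga = _addr_to_genomic(model, pv.scope, pv.a)
    gb = _addr_to_genomic(model, pv.scope, pv.b) if pv.b else ga
    g1, g2 = min(ga, gb), max(ga, gb)

    if pv.vtype == "sub":
        ref = model.slice(g1, g2)
        stated = revcomp(pv.ref) if minus else pv.ref
        if ref != stated:
            raise HgvsError(
                f"{pv.a}: stated ref {pv.ref!r} != model ref at that site")
        alt = revcomp(pv.alt) if minus else pv.alt
        return Edit(model.local(g1), model.local(g2) + 1, alt)

    if pv.vtype == "del":
        ref = model.slice(g1, g2)
        stated = revcomp(pv.ref) if minus else pv.ref
        if pv.ref and ref != stated:
            raise HgvsError(f"{pv.a}: stated deleted bases do not match model")
        return Edit(model.local(g1), model.local(g2) + 1, "")

    if pv.vtype == "delins":
        alt = revcomp(pv.alt) if minus else pv.alt
        return Edit(model.local(g1), model.local(g2) + 1, alt)

    # insertion between two flanking bases
    if g2 != g1 + 1:
        raise HgvsError(
            f"insertion flanks {pv.a}_{pv.b} are not adjacent bases")
    alt = revcomp(pv.alt) if minus else pv.alt
    p = model.local(g2)
    return Edit(p, p, alt)


# -- normalization -----------------------------------------------------------

def normalize(seq: str, edit: Edit, strand: str = "+") -> Edit | None:
    """Trim, then 3'-shift pure indels on the coding strand.

    Returns None when the edit is an identity. Normalizing twice equals
    normalizing once.
    """
    start, end, alt = edit.start, edit.end, edit.alt
    ref = seq[start:end]
    while ref and alt and ref[0] == alt[0]:
        ref, alt, start = ref[1:], alt[1:], start + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt, end = ref[:-1], alt[:-1], end - 1
    if not ref and not alt:
        return None
    if ref and alt:
        return Edit(start, end, alt)
    if alt == "":                      # pure deletion
        if strand == "+":
            while end < len(seq) and seq[start] == seq[end]:
                start, end = start + 1, end + 1
        else:
            while start > 0 and seq[start - 1] == seq[end - 1]:
                start, end = start - 1, end - 1
        return Edit(start, end, "")
    # pure insertion
    p, s = start, alt
    if strand == "+":
        while p < len(seq) and seq[p] == s[0]:
            s = s[1:] + s[0]
            p += 1
    else:
        while p > 0 and seq[p - 1] == s[-1]:
            s = s[-1] + s[:-1]
            p -= 1
    return Edit(p, p, s)


def classify(seq: str, edit: Edit) -> str:
    ref = seq[edit.start:edit.end]
    if len(ref) == 1 and len(edit.alt) == 1:
        return "SNV"
    if edit.alt == "":
        return "del"
    if ref == "":
        return "ins"
    return "delins"


# -- rendering ---------------------------------------------------------------

def render_g(model: GeneModel, edit: Edit, contig: bool = False) -> str:
    pre = f"{model.contig}:" if contig else ""
    ref = model.sequence[edit.start:edit.end]
    gs = model.offset + edit.start
    ge = model.offset + edit.end - 1
    if len(ref) == 1 and len(edit.alt) == 1:
        return f"{pre}g.{gs}{ref}>{edit.alt}"
    if edit.alt == "":
        return (f"{pre}g.{gs}del" if gs == ge else f"{pre}g.{gs}_{ge}del")
    if ref == "":
        return f"{pre}g.{gs - 1}_{gs}ins{edit.alt}"
    rng = f"{gs}" if gs == ge else f"{gs}_{ge}"
    return f"{pre}g.{rng}delins{edit.alt}"


def render_c(model: GeneModel, edit: Edit) -> str:
    minus = model.strand == "-"
    ref = model.sequence[edit.start:edit.end]
    gs = model.offset + edit.start
    ge = model.offset + edit.end - 1

    def addr(g: int) -> str:
        return str(model.genomic_to_coding(g))

    if len(ref) == 1 and len(edit.alt) == 1:
        r, a = (revcomp(ref), revcomp(edit.alt)) if minus else (ref, edit.alt)
        return f"c.{addr(gs)}{r}>{a}"
    if edit.alt == "":
        a1, a2 = (addr(ge), addr(gs)) if minus else (addr(gs), addr(ge))
        return f"c.{a1}del" if gs == ge else f"c.{a1}_{a2}del"
    if ref == "":
        left_g, right_g = gs - 1, gs
        if minus:
            left_g, right_g = gs, gs - 1
        ins = revcomp(edit.alt) if minus else edit.alt
        return f"c.{addr(left_g)}_{addr(right_g)}ins{ins}"
    a1, a2 = (addr(ge), addr(gs)) if minus else (addr(gs), addr(ge))
    alt = revcomp(edit.alt) if minus else edit.alt
    rng = a1 if gs == ge else f"{a1}_{a2}"
    return f"c.{rng}delins{alt}"


def canonical_c(model: GeneModel, name: str) -> str:
    """Parse a c./g. name, normalize it, and render the canonical c. form."""
    e = normalize(model.sequence, resolve(model, name), model.strand)
    if e is None:
        raise HgvsError(f"{name} is an identity on this model")
    return render_c(model, e)


# -- application -------------------------------------------------------------

def apply_edits(seq: str, edits: list[Edit]) -> str:
    """Apply non-overlapping edits to a sequence."""
    ordered = sorted(edits, key=lambda e: (e.start, e.end))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise HgvsError(
                f"overlapping edits at {prev.start}:{prev.end} "
                f"and {nxt.start}:{nxt.end}")
    out = seq
    for e in reversed(ordered):
        out = out[:e.start] + e.alt + out[e.end:]
    return out


def apply_variants(model: GeneModel, names: list[str]) -> str:
    """Apply HGVS c./g. variant names to the reference sequence."""
    edits = [resolve(model, n) for n in names]
    return apply_edits(model.sequence, edits)
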