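"""Reference gene-region model and coordinate conversions.

A :class:`GeneModel` holds a single contiguous genomic slice (gene body plus
flanks) together with its exon structure, CDS span, strand and promoter
window.  It converts between genomic positions and HGVS-style coding
addresses (``c.N`` for CDS bases, ``c.-N`` for positions 5' of the start
codon, ``c.*N`` for positions 3' of the stop codon, ``c.N+M``/``c.N-M`` for
intronic positions anchored to the nearest exon edge).

Coordinates are 1-based inclusive throughout, matching HGVS conventions.
For minus-strand genes the stored sequence is the genomic plus strand and
all coding-space logic operates on the reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}
_DNA = set("ACGT")

_ADDR_RE = re.compile(r"^(?P<anchor>\*\d+|-\d+|\d+)(?P<off>[+-]\d+)?$")


class GeneModelError(ValueError):
    """Invalid gene model or coordinate request."""


class OutOfRangeError(GeneModelError):
    """Position outside the modeled region."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CodingPosition:
    """HGVS coding-style address of a single base.

    ``kind`` is one of ``cds``, ``utr5``, ``utr3`` or ``intron``.  For CDS
    bases ``base`` holds the 1..L position on the spliced coding sequence.
    UTR bases carry ``utr_offset`` (negative for ``c.-N``, positive for
    ``c.*N``); positions upstream of the transcript or downstream of it
    continue the UTR numbering.  Intronic bases carry the address of the
    anchoring exon-edge base plus a signed ``intron_offset``.
    """

    kind: str
    base: int = 0
    utr_offset: int = 0
    intron_offset: int = 0

    def __post_init__(self):
        if self.kind not in ("cds", "utr5", "utr3", "intron"):
            raise GeneModelError(f"unknown kind {self.kind!r}")

    def _anchor_text(self) -> str:
        if self.base:
            return str(self.base)
        if self.utr_offset < 0:
            return str(self.utr_offset)
        if self.utr_offset > 0:
            return f"*{self.utr_offset}"
        raise GeneModelError("intron address lacks an anchor")

    def __str__(self) -> str:
        if self.kind == "cds":
            return str(self.base)
        if self.kind == "utr5":
            return str(self.utr_offset)
        if self.kind == "utr3":
            return f"*{self.utr_offset}"
        return f"{self._anchor_text()}{self.intron_offset:+d}"

    @classmethod
    def parse(cls, text: str) -> "CodingPosition":
        m = _ADDR_RE.match(text.strip())
        if not m:
            raise GeneModelError(f"cannot parse coding address {text!r}")
        anchor, off = m.group("anchor"), m.group("off")
        base = utr = 0
        if anchor.startswith("*"):
            utr = int(anchor[1:])
            kind = "utr3"
        elif anchor.startswith("-"):
            utr = int(anchor)
            kind = "utr5"
        else:
            base = int(anchor)
            kind = "cds"
        if off is not None:
            return cls(kind="intron", base=base, utr_offset=utr,
                       intron_offset=int(off))
        return cls(kind=kind, base=base, utr_offset=utr)


@dataclass
class GeneModel:
    """A reference gene region with exon/CDS/promoter annotation."""

    contig: str
    offset: int                      # genomic coordinate of sequence[0]
    sequence: str
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # genomic, 1-based inclusive, sorted
    cds_start: int                   # first base of start codon (coding 5')
    cds_end: int                     # last base of stop codon (coding 3')
    promoter: tuple[int, int] | None = None
    _addr: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.exons = [tuple(e) for e in self.exons]
        self.validate()
        self._build_map()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError("strand must be '+' or '-'")
        if set(self.sequence) - _DNA:
            raise GeneModelError("sequence contains non-ACGT characters")
        last = None
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"exon {s}-{e} reversed")
            if not (self.offset <= s and e <= self.gend):
                raise GeneModelError(f"exon {s}-{e} outside region")
            if last is not None and s <= last:
                raise GeneModelError("exons overlap or are unsorted")
            last = e
        for g in (self.cds_start, self.cds_end):
            if not any(s <= g <= e for s, e in self.exons):
                raise GeneModelError(f"CDS endpoint {g} not inside an exon")
        cds = self.spliced_cds()
        if len(cds) % 3:
            raise GeneModelError("spliced CDS length not a multiple of 3")
        if not cds.startswith("ATG"):
            raise GeneModelError("CDS does not begin with ATG")
        if cds[-3:] not in _STOPS:
            raise GeneModelError("CDS does not end with a stop codon")
        if self.promoter is not None:
            ps, pe = self.promoter
            for s, e in self.exons:
                if ps <= e and s <= pe:
                    raise GeneModelError("promoter window overlaps an exon")

    # -- basic geometry -----------------------------------------------------

    @property
    def gend(self) -> int:
        """Genomic coordinate of the last stored base."""
        return self.offset + len(self.sequence) - 1

    def local(self, gpos: int) -> int:
        """0-based index into ``sequence`` for genomic position ``gpos``."""
        if not (self.offset <= gpos <= self.gend):
            raise OutOfRangeError(
                f"g.{gpos} outside region {self.offset}-{self.gend}")
        return gpos - self.offset

    def base_at(self, gpos: int) -> str:
        return self.sequence[self.local(gpos)]

    def slice(self, gstart: int, gend: int) -> str:
        """Reference bases on the plus strand, 1-based inclusive."""
        if gstart > gend:
            return ""
        return self.sequence[self.local(gstart):self.local(gend) + 1]

    def _tx_positions(self) -> list[int]:
        """Genomic positions of transcribed bases, in coding order."""
        pos: list[int] = []
        for s, e in self.exons:
            pos.extend(range(s, e + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def spliced_cds(self) -> str:
        """CDS on the coding strand (spliced)."""
        tx = self._tx_positions()
        i0, i1 = tx.index(self.cds_start), tx.index(self.cds_end)
        bases = "".join(self.sequence[g - self.offset] for g in tx[i0:i1 + 1])
        if self.strand == "-":
            # tx is already in coding (descending genomic) order; each base
            # just needs complementing.
            bases = bases.translate(str.maketrans("ACGT", "TGCA"))
        return bases

    def protein(self) -> str:
        """Translation of the spliced CDS, without the terminal stop."""
        return str(Seq(self.spliced_cds()).translate()).rstrip("*")

    # -- coordinate map -----------------------------------------------------

    def _build_map(self) -> None:
        tx = self._tx_positions()
        txset = {g: i for i, g in enumerate(tx)}
        i0, i1 = txset[self.cds_start], txset[self.cds_end]

        addr: dict[int, CodingPosition] = {}
        for g, i in txset.items():
            if i < i0:
                addr[g] = CodingPosition("utr5", utr_offset=i - i0)
            elif i <= i1:
                addr[g] = CodingPosition("cds", base=i - i0 + 1)
            else:
                addr[g] = CodingPosition("utr3", utr_offset=i - i1)

        sign = 1 if self.strand == "+" else -1
        first_tx, last_tx = tx[0], tx[-1]
        for g in range(self.offset, self.gend + 1):
            if g in addr:
                continue
            if sign * (g - first_tx) < 0:          # upstream flank
                k = abs(g - first_tx)
                addr[g] = CodingPosition("utr5", utr_offset=-(i0 + k))
            elif sign * (g - last_tx) > 0:          # downstream flank
                k = abs(g - last_tx)
                addr[g] = CodingPosition(
                    "utr3", utr_offset=(len(tx) - 1 - i1) + k)
            else:                                   # intronic
                prev_edge = max((e for s, e in self.exons if e < g),
                                default=None)
                next_edge = min((s for s, e in self.exons if s > g),
                                default=None)
                # edges in coding orientation
                if self.strand == "+":
                    e5, e3 = prev_edge, next_edge
                    d5, d3 = g - e5, e3 - g
                else:
                    e5, e3 = next_edge, prev_edge
                    d5, d3 = e5 - g, g - e3
                if d5 <= d3:
                    a = addr[e5]
                    addr[g] = CodingPosition(
                        "intron", base=a.base, utr_offset=a.utr_offset,
                        intron_offset=d5)
                else:
                    a = addr[e3]
                    addr[g] = CodingPosition(
                        "intron", base=a.base, utr_offset=a.utr_offset,
                        intron_offset=-d3)
        self._addr = addr
        self._tx = tx
        self._i0, self._i1 = i0, i1

    # -- public conversions -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return self._i1 - self._i0 + 1

    def genomic_to_coding(self, gpos: int) -> CodingPosition:
        if not (self.offset <= gpos <= self.gend):
            raise OutOfRangeError(
                f"g.{gpos} outside region {self.offset}-{self.gend}")
        return self._addr[gpos]

    def coding_to_genomic(self, cpos: CodingPosition | str) -> int:
        if isinstance(cpos, str):
            cpos = CodingPosition.parse(cpos)
        sign = 1 if self.strand == "+" else -1
        tx, i0, i1 = self._tx, self._i0, self._i1
        if cpos.kind == "cds":
            if not 1 <= cpos.base <= self.cds_length:
                raise OutOfRangeError(f"c.{cpos.base} beyond CDS")
            return tx[i0 + cpos.base - 1]
        if cpos.kind == "utr5":
            n = -cpos.utr_offset
            if n <= 0:
                raise OutOfRangeError("c.-N requires N >= 1")
            if n <= i0:
                return tx[i0 - n]
            g = tx[0] - sign * (n - i0)
            if not (self.offset <= g <= self.gend):
                raise OutOfRangeError(f"c.{cpos} beyond stored 5' flank")
            return g
        if cpos.kind == "utr3":
            n = cpos.utr_offset
            if n <= 0:
                raise OutOfRangeError("c.*N requires N >= 1")
            tail = len(tx) - 1 - i1
            if n <= tail:
                return tx[i1 + n]
            g = tx[-1] + sign * (n - tail)
            if not (self.offset <= g <= self.gend):
                raise OutOfRangeError(f"c.{cpos} beyond stored 3' flank")
            return g
        # intron
        anchor = CodingPosition(
            "cds", base=cpos.base) if cpos.base else CodingPosition(
            "utr5" if cpos.utr_offset < 0 else "utr3",
            utr_offset=cpos.utr_offset)
        ag = self.coding_to_genomic(anchor)
        g = ag + sign * cpos.intron_offset
        if not (self.offset <= g <= self.gend):
            raise OutOfRangeError(f"c.{cpos} outside region")
        return g

    def coding_base(self, cpos: CodingPosition | str) -> str:
        """Reference base on the *coding strand* at a coding address."""
        b = self.base_at(self.coding_to_genomic(cpos))
        return b if self.strand == "+" else revcomp(b)


def cds_to_protein_position(cpos: int) -> int:
    """Codon index of a CDS base: floor((cpos-1)/3) + 1."""
    if cpos <= 0:
        raise GeneModelError(f"CDS position must be positive, got {cpos}")
    return (cpos - 1) // 3 + 1


# -- persistence ------------------------------------------------------------

def write_fasta(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{model.contig}:{model.offset}-{model.gend}\n")
        for i in range(0, len(model.sequence), 70):
            fh.write(model.sequence[i:i + 70] + "\n")


def write_annotation(model: GeneModel, path) -> None:
    """TSV sidecar with the model's structural metadata."""
    exon_txt = ",".join(f"{s}-{e}" for s, e in model.exons)
    prom = (f"{model.promoter[0]}-{model.promoter[1]}"
            if model.promoter else ".")
    with open(path, "w") as fh:
        fh.write("contig\toffset\tstrand\texons\tcds_start\tcds_end\tpromoter\n")
        fh.write(f"{model.contig}\t{model.offset}\t{model.strand}\t"
                 f"{exon_txt}\t{model.cds_start}\t{model.cds_end}\t{prom}\n")


def read_gene_model(fasta_path, annotation_path) -> GeneModel:
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    with open(annotation_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        row = dict(zip(header, fh.readline().rstrip("\n").split("\t")))
    exons = [tuple(int(x) for x in part.split("-"))
             for part in row["exons"].split(",")]
    promoter = None
    if row.get("promoter", ".") != ".":
        a, b = row["promoter"].split("-")
        promoter = (int(a), int(b))
    return GeneModel(
        contig=row["contig"], offset=int(row["offset"]),
        sequence=str(record.seq), strand=row["strand"], exons=exons,
        cds_start=int(row["cds_start"]), cds_end=int(row["cds_end"]),
        promoter=promoter)


def read_gff3_gene_model(fasta_path, gff3_path,
                         promoter: tuple[int, int] | None = None) -> GeneModel:
    """Import a model from a GFF3 file.

    Only ``gene``, ``exon`` and ``CDS`` feature types are honored
    (1-based inclusive coordinates, per the GFF3 spec).  The promoter
    window, absent from GFF3, may be supplied separately.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    contig = strand = None
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    offset = None
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                continue
            seqid, _, ftype, start, end, _, fstrand = f[:7]
            if ftype == "gene":
                contig, strand = seqid, fstrand
            elif ftype == "exon":
                exons.append((int(start), int(end)))
            elif ftype == "CDS":
                cds.append((int(start), int(end)))
    if not exons or not cds or contig is None:
        raise GeneModelError("GFF3 must provide gene, exon and CDS features")
    exons.sort()
    cds.sort()
    m = re.match(r"^(\S+?):(\d+)-(\d+)$", record.id)
    offset = int(m.group(2)) if m else 1
    cds_start, cds_end = cds[0][0], cds[-1][1]
    if strand == "-":
        cds_start, cds_end = cds_end, cds_start
    return GeneModel(contig=contig, offset=offset, sequence=str(record.seq),
                     strand=strand, exons=exons,
                     cds_start=cds_start, cds_end=cds_end, promoter=promoter)
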