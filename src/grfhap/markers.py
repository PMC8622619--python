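"""In-silico molecular markers: PCR, CAPS digestion, SSR genotyping.

``insilico_pcr`` finds exact primer placements and reports product
coordinates and lengths (both primer footprints included).  ``caps_digest``
cuts an amplicon with a (possibly type IIS, staggered) restriction enzyme
and reports fragment lengths following the top-strand cut positions (the
bottom-strand convention is also available; for SfaN I's 5/9 stagger the
two differ by 4 nt).  ``ssr_genotype`` assigns fragment sizes to disjoint
per-locus bins, the standard trick for co-amplified homoeologs whose
product ranges do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

try:
    import tomllib
except ModuleNotFoundError:                      # pragma: no cover
    tomllib = None

from .gene_model import revcomp


class MarkerError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int = 5000

    def __post_init__(self):
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise MarkerError(f"{self.name}: primers must be >= 15 nt")
        if self.max_product <= len(self.forward) + len(self.reverse):
            raise MarkerError(f"{self.name}: max_product too small")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition site with downstream cut offsets.

    ``cut_top``/``cut_bottom`` count bases between the 3' end of the
    recognition site and the cut, on the respective strand.  SfaN I is
    GCATC(5/9): cut_top=5, cut_bottom=9.
    """
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        if self.cut_top < 0 or self.cut_bottom < 0:
            raise MarkerError("cut offsets must be >= 0")


SFANI = RestrictionEnzyme("SfaNI", "GCATC", 5, 9)


@dataclass
class SSRLocusBins:
    """Disjoint [min, max] product-size intervals per locus label."""
    bins: dict[str, tuple[int, int]]

    def __post_init__(self):
        items = sorted(self.bins.items(), key=lambda kv: kv[1])
        for (n1, (a1, b1)), (n2, (a2, b2)) in zip(items, items[1:]):
            if a2 <= b1:
                raise MarkerError(
                    f"bins {n1} and {n2} overlap ({a1}-{b1} vs {a2}-{b2})")


@dataclass(frozen=True)
class PcrProduct:
    start: int          # 0-based on the given template strand
    end: int            # exclusive
    length: int
    sequence: str


def insilico_pcr(template: str, primers: PrimerPair,
                 search_both_strands: bool = True) -> list[PcrProduct]:
    """All exact-match amplification products within ``max_product``.

    The forward primer is matched on the template as given and the reverse
    primer as its reverse complement downstream; with
    ``search_both_strands`` the same search also runs on the reverse
    complement of the template (products are reported in the coordinates of
    the strand they were found on).
    """
    template = template.upper()
    if len(template) < len(primers.forward) + len(primers.reverse):
        return []
    products = []
    seen = set()
    strands = [template]
    if search_both_strands:
        strands.append(revcomp(template))
    for strand_seq in strands:
        for p in _find_all(strand_seq, primers.forward.upper()):
            tail = revcomp(primers.reverse.upper())
            stop = min(len(strand_seq), p + primers.max_product)
            for q in _find_all(strand_seq[p:stop], tail):
                end = p + q + len(tail)
                seq = strand_seq[p:end]
                key = min(seq, revcomp(seq))
                if key in seen:        # same molecule found from both strands
                    continue
                seen.add(key)
                products.append(
                    PcrProduct(start=p, end=end, length=end - p,
                               sequence=seq))
    products.sort(key=lambda pr: (pr.length, pr.sequence))
    return products


def _find_all(text: str, pat: str):
    p = text.find(pat)
    while p != -1:
        yield p
        p = text.find(pat, p + 1)


def caps_digest(amplicon: str, enzyme: RestrictionEnzyme,
                strand: str = "top") -> list[int]:
    """Fragment lengths after complete digestion, sorted ascending.

    Recognition sites are found on both strands; each yields one
    double-strand break.  Reported lengths follow the cut positions on the
    requested strand (``top`` by default).  Sites whose cut would fall
    beyond the amplicon are ignored with a warning (the enzyme cannot
    cleave a truncated site).  Fragment lengths always sum to the amplicon
    length.
    """
    if not amplicon:
        raise MarkerError("empty amplicon")
    amplicon = amplicon.upper()
    rec = enzyme.recognition.upper()
    L = len(amplicon)
    off = enzyme.cut_top if strand == "top" else enzyme.cut_bottom
    off_rc = enzyme.cut_bottom if strand == "top" else enzyme.cut_top
    cuts = set()
    for p in _find_all(amplicon, rec):                 # site on top strand
        c = p + len(rec) + off
        if 0 < c < L:
            cuts.add(c)
        elif c >= L:
            warnings.warn(f"{enzyme.name} site at {p}: cut beyond amplicon "
                          "end; site ignored")
    for p in _find_all(amplicon, revcomp(rec)):        # site on bottom strand
        c = p - off_rc
        if 0 < c < L:
            cuts.add(c)
        elif c <= 0:
            warnings.warn(f"{enzyme.name} bottom-strand site at {p}: cut "
                          "beyond amplicon start; site ignored")
    bounds = [0] + sorted(cuts) + [L]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def ssr_genotype(products: list[int], bins: SSRLocusBins
                 ) -> tuple[dict[str, list[int]], list[int]]:
    """Assign product sizes to loci; returns (per-locus sizes, unassigned)."""
    assigned: dict[str, list[int]] = {name: [] for name in bins.bins}
    unassigned: list[int] = []
    for size in products:
        for name, (lo, hi) in bins.bins.items():
            if lo <= size <= hi:
                assigned[name].append(size)
                break
        else:
            unassigned.append(size)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def load_marker_config(path):
    """Read primer/enzyme/bin definitions from a TOML file."""
    if tomllib is None:
        raise MarkerError("tomllib unavailable")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    primers = {name: PrimerPair(name=name, **spec)
               for name, spec in data.get("primers", {}).items()}
    enzymes = {name: RestrictionEnzyme(name=name, **spec)
               for name, spec in data.get("enzymes", {}).items()}
    bins = None
    if "ssr_bins" in data:
        bins = SSRLocusBins({k: tuple(v)
                             for k, v in data["ssr_bins"].items()})
    return primers, enzymes, bins


def write_marker_config(primers: dict[str, PrimerPair],
                        enzymes: dict[str, RestrictionEnzyme],
                        bins: SSRLocusBins | None, path) -> None:
    lines = []
    for name, p in primers.items():
        lines += [f'[primers."{name}"]',
                  f'forward = "{p.forward}"',
                  f'reverse = "{p.reverse}"',
                  f"max_product = {p.max_product}", ""]
    for name, e in enzymes.items():
        lines += [f'[enzymes."{name}"]',
                  f'recognition = "{e.recognition}"',
                  f"cut_top = {e.cut_top}",
                  f"cut_bottom = {e.cut_bottom}", ""]
    if bins is not None:
        lines.append("[ssr_bins]")
        for name, (lo, hi) in bins.bins.items():
            lines.append(f'"{name}" = [{lo}, {hi}]')
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
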