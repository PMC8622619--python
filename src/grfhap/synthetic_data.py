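"""Synthetic study data: reference gene, haplotype panel, phenotypes.

The generator emits a surrogate wheat *GRF3-2A*-like gene region that honors
every structural constraint of the studied locus: 1,075 nt stored before the
start codon and 1,389 nt after the stop codon; four exons with introns 2 and
3 carrying the catalogued intronic variants; an (AG)n microsatellite in the
5'UTR; a polyglutamine tract of 7 consecutive CAG codons starting at residue
38; and a coding sequence in which every catalogued coding variant
(c.126_134del, c.495G>T, c.528G>C, c.530C>G, c.729C>G) has its printed name
as the canonical 3'-shifted representation.  The coordinate system is
anchored so that c.495 sits at chr2A:g.687050412, which also places the
printed promoter variants (g.687048137/328/382/627) and the post-transcript
variants at g.687052487 into the structurally correct compartments.

The default allele catalog replays the published variant sets; the haplotype
panel is drawn with deterministic largest-remainder counts so that 77 of 199
accessions (38.7%) carry the c.495G>T allele.  Phenotypes are simulated as
trait = baseline + year effect + allele effect (carriers) + Gaussian noise,
with score traits drawn binomially.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hgvs
from .gene_model import GeneModel, revcomp

CONTIG = "chr2A"
ANCHOR_C495_G = 687050412          # genomic position of c.495
PROMOTER_WINDOW = (687047878, 687048697)
EXON_CDS_BOUNDS = ((1, 100), (101, 325), (326, 689), (690, 768))
INTRON_LENGTHS = (450, 520, 1470)
CDS_CODONS = 256                   # 255 residues + stop
UTR5_LEN = 200
UTR3_LEN = 331
SSR_UNIT = "AG"
SSR_START_C = -85                  # 5'UTR start of the (AG)n tract

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS)


class ConfigError(ValueError):
    pass


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleDef:
    """A named haplotype: its variant set, SSR length and frequency."""
    name: str
    isoform: str
    variants: tuple[str, ...]
    ssr_repeats: int
    freq: float
    ssr_a_loss: bool = False


#: Replay of the published variant catalog.  Only the ~39% carrier
#: frequency of the c.495G>T allele is anchored by the study; the remaining
#: frequencies and SSR lengths are invented defaults (see docs/methods.md).
DEFAULT_CATALOG: tuple[AlleleDef, ...] = (
    AlleleDef("b.1", "B", ("chr2A:g.687048627G>C", "c.495G>T"), 16, 0.30),
    AlleleDef("b.2", "B", ("chr2A:g.687048627G>C", "c.495G>T"), 13, 0.09),
    AlleleDef("a.1", "A", (), 28, 0.28),
    AlleleDef("a.2", "A", ("chr2A:g.687048627G>C",), 22, 0.11),
    AlleleDef("a.3", "A", ("chr2A:g.687048627G>C",), 28, 0.08,
              ssr_a_loss=True),
    AlleleDef("a.4", "A",
              ("chr2A:g.687048627G>C", "chr2A:g.687048382C>T"), 24, 0.04),
    AlleleDef("a.6", "A",
              ("chr2A:g.687048627G>C", "chr2A:g.687048137G>T"), 20, 0.03),
    AlleleDef("a.10", "A", ("chr2A:g.687048627G>C", "c.*8C>T"), 26, 0.03),
    AlleleDef("c.1", "C",
              ("chr2A:g.687048627G>C", "chr2A:g.687048328A>G",
               "c.325+32_325+33insTCC", "c.325+169G>C", "c.326-39A>G",
               "c.326-174A>G", "c.528G>C", "c.530C>G", "c.689+136A>G",
               "c.689+241T>C", "c.729C>G", "c.*285A>G", "c.*312A>T",
               "chr2A:g.687052487C>T"), 11, 0.02),
    AlleleDef("d.1", "D", ("c.126_134del",), 28, 0.01),
    # keeps the reference repeat count: the c.-102_-91del sits a few bases
    # from the tract, and a simultaneous tract-length change there has no
    # unambiguous alignment (the published repeat length is not printed)
    AlleleDef("a.16", "A",
              ("chr2A:g.687048627G>C", "chr2A:g.687048328A>G", "c.-140A>G",
               "c.-102_-91del", "chr2A:g.687052487_687052488del"), 28, 0.01),
)

#: trait -> (baseline, noise sd).  Units: heading days after sowing;
#: 1000-kernel weight g; test weight g/L; protein %; yield t/ha.
DEFAULT_TRAITS: dict[str, tuple[float, float]] = {
    "heading_date": (205.0, 2.0),
    "kernel_weight_1000": (40.0, 3.0),
    "test_weight": (780.0, 15.0),
    "grain_protein": (14.0, 0.8),
    "grain_yield": (7.0, 0.8),
}

#: additive shift for carriers of the effect variant
DEFAULT_EFFECTS: dict[str, float] = {
    "heading_date": -2.0,
    "kernel_weight_1000": 1.5,
    "test_weight": 10.0,
    "grain_protein": 0.3,
    "grain_yield": -0.2,
}

DEFAULT_YEAR_EFFECTS: dict[int, dict[str, float]] = {
    2018: {"heading_date": 0.0, "kernel_weight_1000": -2.0,
           "test_weight": -5.0, "grain_protein": 0.5, "grain_yield": -0.8},
    2019: {"heading_date": 3.0, "kernel_weight_1000": 1.0,
           "test_weight": 4.0, "grain_protein": -0.2, "grain_yield": 0.5},
    2020: {"heading_date": -2.0, "kernel_weight_1000": 0.5,
           "test_weight": 2.0, "grain_protein": -0.1, "grain_yield": 0.2},
}

#: score trait -> (levels, base success prob, carrier prob shift)
DEFAULT_SCORE_TRAITS: dict[str, tuple[int, float, float]] = {
    "winter_hardiness": (9, 0.70, 0.0),
    "lodging_score": (9, 0.75, -0.05),
}


@dataclass
class SimConfig:
    seed: int = 0
    n_accessions: int = 199
    flank5: int = 1075
    flank3: int = 1389
    exon_count: int = 4
    ssr_repeat_range: tuple[int, int] = (11, 37)
    ssr_ref_repeats: int = 28
    polyq_start: int = 38
    polyq_length: int = 7
    strand: str = "+"
    allele_catalog: tuple[AlleleDef, ...] = DEFAULT_CATALOG
    random_snp_rate: float = 0.0        # per-base rate of private noncoding SNPs
    effect_variant: str = "c.495G>T"
    traits: dict = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    year_effects: dict = field(
        default_factory=lambda: {y: dict(v)
                                 for y, v in DEFAULT_YEAR_EFFECTS.items()})
    noise_sd: dict | None = None
    years: tuple[int, ...] = (2018, 2019, 2020)
    score_traits: dict = field(
        default_factory=lambda: dict(DEFAULT_SCORE_TRAITS))

    def __post_init__(self):
        if self.exon_count != 4:
            raise ConfigError(
                "the replayed catalog layout requires exactly 4 exons")
        if self.flank5 < UTR5_LEN + 830 or self.flank3 < UTR3_LEN:
            raise ConfigError("flanks too short to host the variant catalog")
        lo, hi = self.ssr_repeat_range
        if not (1 <= lo <= self.ssr_ref_repeats <= hi):
            raise ConfigError("ssr_ref_repeats outside ssr_repeat_range")
        if any(a.ssr_repeats < lo or a.ssr_repeats > hi
               for a in self.allele_catalog):
            raise ConfigError("allele SSR repeat count outside range")
        total = sum(a.freq for a in self.allele_catalog)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"allele frequencies sum to {total}, not 1")
        if any("c.126_134del" in a.variants for a in self.allele_catalog):
            if (self.polyq_start, self.polyq_length) != (38, 7):
                raise ConfigError(
                    "c.126_134del requires the polyQ tract at residues 38-44")
        if self.polyq_start + self.polyq_length > 160:
            raise ConfigError("polyQ tract collides with fixed codons")


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated panel."""
    accessions: pd.DataFrame     # accession, allele, isoform, variants, ...
    effect_variant: str
    effect_sizes: dict
    year_effects: dict


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _loc_c(n: int) -> int:
    """0-based local index of CDS base n (default layout, sense strand)."""
    loc = UTR5_LEN + 875 + (n - 1)
    for (s, e), ilen in zip(EXON_CDS_BOUNDS, INTRON_LENGTHS):
        if n > e:
            loc += ilen
    return loc


def _loc_u5(n: int) -> int:
    """0-based local index of c.-n (UTR5 numbering extends into promoter)."""
    return 1075 - n


def _loc_u3(n: int) -> int:
    return _loc_c(EXON_CDS_BOUNDS[-1][1]) + n


def _rand_dna(rng, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _scan_motifs(seq: list[str], lo: int, hi: int,
                 motifs: tuple[str, ...]) -> list[tuple[int, str]]:
    text = "".join(seq[lo:hi])
    hits = []
    for m in motifs:
        p = text.find(m)
        while p != -1:
            hits.append((lo + p, m))
            p = text.find(m, p + 1)
    return hits


def _sanitize_window(seq: list[str], protected: set[int], lo: int, hi: int,
                     motifs: tuple[str, ...], cds_locs: dict[int, int]) -> None:
    """Mutate unprotected bases so no motif occurs in seq[lo:hi]."""
    for _ in range(200):
        hits = _scan_motifs(seq, lo, hi, motifs)
        if not hits:
            return
        pos, motif = hits[0]
        fixed = False
        order = sorted(range(pos, pos + len(motif)),
                       key=lambda j: abs(j - (pos + len(motif) // 2)))
        for j in order:
            if j in protected:
                continue
            for b in "ACGT":
                if b == seq[j]:
                    continue
                old = seq[j]
                seq[j] = b
                if j in cds_locs:
                    cpos = cds_locs[j]
                    c0 = (cpos - 1) // 3 * 3 + 1
                    codon = "".join(seq[cds_locs_inv] for cds_locs_inv in
                                    (_loc_c(c0), _loc_c(c0 + 1),
                                     _loc_c(c0 + 2)))
                    if codon in _STOPS:
                        seq[j] = old
                        continue
                if _scan_motifs(seq, max(lo, j - 6),
                                min(hi, j + 7), motifs):
                    seq[j] = old
                    continue
                protected.add(j)
                fixed = True
                break
            if fixed:
                break
        if not fixed:
            raise ConfigError(
                f"cannot sanitize motif {motif} at local {pos}")
    raise ConfigError("motif sanitation did not converge")


def _build_sense(cfg: SimConfig):
    """Build the plus-strand reference and layout bookkeeping."""
    rng = np.random.default_rng([cfg.seed, 17])
    prom_len = cfg.flank5 - UTR5_LEN
    if prom_len != 875:
        raise ConfigError(
            "default layout requires flank5 = 1075 (875 nt promoter stored)")
    tail_len = cfg.flank3 - UTR3_LEN

    # coding sequence, codon by codon
    codons = list(rng.choice(_NONSTOP_CODONS, size=CDS_CODONS - 1))
    codons.append("TGA")
    fixed_codons = {1: "ATG", cfg.polyq_start - 1: "CTG",
                    cfg.polyq_start + cfg.polyq_length: "CAC",
                    164: "GCG", 165: "CAG", 166: "CTC",
                    176: "CAG", 177: "GCC", 243: "GAC"}
    for k in range(cfg.polyq_start, cfg.polyq_start + cfg.polyq_length):
        fixed_codons[k] = "CAG"
    for k, cdn in fixed_codons.items():
        codons[k - 1] = cdn
    cds = "".join(codons)

    tract = SSR_UNIT * cfg.ssr_ref_repeats
    tract_start = _loc_u5(-SSR_START_C)                  # local of c.-85
    tract_end = tract_start + len(tract) - 1

    total = cfg.flank5 + 768 + sum(INTRON_LENGTHS) + cfg.flank3
    seq = _rand_dna(rng, total)
    protected: set[int] = set()

    def put(loc: int, bases: str):
        for k, b in enumerate(bases):
            seq[loc + k] = b
            protected.add(loc + k)

    # CDS segments (overwrite the random filler)
    for n in range(1, 769):
        seq[_loc_c(n)] = cds[n - 1]
    cds_locs = {_loc_c(n): n for n in range(1, 769)}
    for k in fixed_codons:
        for n in range(3 * k - 2, 3 * k + 1):
            protected.add(_loc_c(n))

    offset = ANCHOR_C495_G - _loc_c(495)

    # promoter anchors (reference bases of the catalogued promoter SNVs)
    for g, b in ((687048137, "G"), (687048328, "A"),
                 (687048382, "C"), (687048627, "G")):
        put(g - offset, b)
    # 5'UTR anchors
    put(_loc_u5(140), "A")
    put(_loc_u5(102), "T")                # c.-102; != c.-90 for 3'-shift stop
    put(_loc_u5(90), "C")
    put(tract_start - 1, "C")             # break the repeat on the left
    put(tract_start, tract)
    put(tract_end + 1, "T")               # break the repeat on the right
    # intron 2 anchors
    put(_loc_c(325) + 33, "G")            # c.325+33 != T keeps insTCC put
    put(_loc_c(325) + 169, "G")
    put(_loc_c(326) - 39, "A")
    put(_loc_c(326) - 174, "A")
    # intron 3 anchors
    put(_loc_c(689) + 136, "A")
    put(_loc_c(689) + 241, "T")
    # 3'UTR anchors
    put(_loc_u3(8), "C")
    put(_loc_u3(285), "A")
    put(_loc_u3(312), "A")
    # immediately after the transcription stop site
    put(_loc_u3(UTR3_LEN) + 1, "C")
    put(_loc_u3(UTR3_LEN) + 2, "A")
    put(_loc_u3(UTR3_LEN) + 3, "G")       # != C keeps the 2-nt del 3'-shifted

    # marker footprints (0-based local, half-open)
    sites = {
        "q42_f": (_loc_c(126) - 171, _loc_c(126) - 148),
        "q42_r": (_loc_c(126) - 171 + 321, _loc_c(126) - 171 + 344),
        "q165_f": (_loc_c(492) - 191, _loc_c(492) - 168),
        "q165_r": (_loc_c(492) - 191 + 431, _loc_c(492) - 191 + 454),
        "ssr_f": (_loc_u5(185), _loc_u5(185) + 20),
        "ssr_r": (_loc_c(79) - 19, _loc_c(79) + 1),
    }

    # keep the CAPS amplicon free of stray SfaN I sites (either strand)
    _sanitize_window(seq, protected, sites["q165_f"][0], sites["q165_r"][1],
                     ("GCATC", "GATGC"), cds_locs)
    # keep the SSR amplicon free of competing AG runs
    for _ in range(50):
        hits = _scan_motifs(seq, sites["ssr_f"][0], sites["ssr_r"][1],
                            (SSR_UNIT * 4,))
        hits = [h for h in hits
                if not (tract_start - 8 <= h[0] <= tract_end)]
        if not hits:
            break
        pos, _m = hits[0]
        for j in range(pos, pos + 8):
            if j not in protected:
                seq[j] = "C"
                protected.add(j)
                break
        else:
            raise ConfigError("cannot break stray SSR run")

    sense = "".join(seq)

    exons = []
    cds_bounds_loc = [( _loc_c(s), _loc_c(e)) for s, e in EXON_CDS_BOUNDS]
    exons.append((offset + _loc_u5(UTR5_LEN), offset + cds_bounds_loc[0][1]))
    exons.append((offset + cds_bounds_loc[1][0], offset + cds_bounds_loc[1][1]))
    exons.append((offset + cds_bounds_loc[2][0], offset + cds_bounds_loc[2][1]))
    exons.append((offset + cds_bounds_loc[3][0], offset + _loc_u3(UTR3_LEN)))

    model = GeneModel(
        contig=CONTIG, offset=offset, sequence=sense, strand="+",
        exons=exons, cds_start=offset + _loc_c(1),
        cds_end=offset + _loc_c(768), promoter=PROMOTER_WINDOW)

    layout = {
        "sites": sites,
        "tract_start": tract_start,
        "tract_end": tract_end,
        "protected": protected,
    }
    return model, layout


def _mirror_model(model: GeneModel) -> GeneModel:
    """Reverse-complement a model in place-coordinates (minus-strand twin)."""
    L = len(model.sequence)
    o = model.offset

    def mg(g: int) -> int:
        return o + (L - 1 - (g - o))

    exons = sorted(tuple(sorted((mg(s), mg(e)))) for s, e in model.exons)
    prom = None
    if model.promoter:
        prom = tuple(sorted((mg(model.promoter[0]), mg(model.promoter[1]))))
    return GeneModel(
        contig=model.contig, offset=o, sequence=revcomp(model.sequence),
        strand="-" if model.strand == "+" else "+", exons=exons,
        cds_start=mg(model.cds_start), cds_end=mg(model.cds_end),
        promoter=prom)


def _mirror_edit(e: hgvs.Edit, L: int) -> hgvs.Edit:
    return hgvs.Edit(L - e.end, L - e.start, revcomp(e.alt))


def simulate_reference(cfg: SimConfig) -> GeneModel:
    """Generate the reference gene model (deterministic for a given seed)."""
    model, _layout = _build_sense(cfg)
    if cfg.strand == "-":
        model = _mirror_model(model)
    return model


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _largest_remainder(freqs: list[float], n: int) -> list[int]:
    exact = [f * n for f in freqs]
    counts = [int(x) for x in exact]
    order = sorted(range(len(freqs)),
                   key=lambda i: (exact[i] - counts[i], -i), reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _ssr_edits(model: GeneModel, layout, allele: AlleleDef,
               ref_repeats: int) -> list[hgvs.Edit]:
    """Edits turning the reference tract into the allele's tract."""
    ts, te = layout["tract_start"], layout["tract_end"]
    alt = SSR_UNIT * allele.ssr_repeats
    if allele.ssr_a_loss:
        # drop the A of the middle repeat unit (an interrupted tract)
        m = allele.ssr_repeats // 2
        alt = alt[: 2 * m] + alt[2 * m + 1:]
    raw = hgvs.Edit(ts, te + 1, alt)
    norm = hgvs.normalize(model.sequence, raw, model.strand)
    return [] if norm is None else [norm]


def simulate_panel(model: GeneModel, cfg: SimConfig):
    """Apply the allele catalog (plus optional private noncoding SNPs).

    Returns ``(panel, truth)`` where ``panel`` is an ordered mapping of
    accession name to gene-region sequence and ``truth`` a :class:`SimTruth`.
    The supplied ``model`` must come from :func:`simulate_reference` with the
    same config.
    """
    sense_model, layout = _build_sense(cfg)
    minus = cfg.strand == "-"
    final_model = _mirror_model(sense_model) if minus else sense_model
    if final_model.sequence != model.sequence:
        raise ConfigError("model does not match the config it was built from")
    L = len(sense_model.sequence)
    rng = np.random.default_rng([cfg.seed, 29])

    allele_edits: dict[str, list[hgvs.Edit]] = {}
    allele_ssr_edit: dict[str, list[hgvs.Edit]] = {}
    for allele in cfg.allele_catalog:
        try:
            edits = [hgvs.resolve(sense_model, v) for v in allele.variants]
        except Exception as exc:
            raise CatalogError(
                f"allele {allele.name}: cannot place variants: {exc}") from exc
        spans = sorted((e.start, e.end) for e in edits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise CatalogError(
                    f"allele {allele.name} has overlapping variants")
        allele_edits[allele.name] = edits
        allele_ssr_edit[allele.name] = _ssr_edits(
            sense_model, layout, allele, cfg.ssr_ref_repeats)

    counts = _largest_remainder(
        [a.freq for a in cfg.allele_catalog], cfg.n_accessions)
    assignment = [a for a, k in zip(cfg.allele_catalog, counts)
                  for _ in range(k)]
    perm = rng.permutation(len(assignment))
    width = max(3, len(str(cfg.n_accessions)))

    # pool of positions allowed to carry private noncoding SNPs
    if cfg.random_snp_rate > 0:
        blocked = set(layout["protected"])
        for s, e in layout["sites"].values():
            blocked.update(range(s, e))
        blocked.update(range(layout["tract_start"] - 2,
                             layout["tract_end"] + 3))
        coding = set()
        for (cs, ce) in EXON_CDS_BOUNDS:
            coding.update(range(_loc_c(cs), _loc_c(ce) + 1))
        pool = np.array(sorted(set(range(L)) - blocked - coding))

    panel: dict[str, str] = {}
    rows = []
    for idx in range(cfg.n_accessions):
        allele = assignment[perm[idx]]
        acc = f"ACC{idx + 1:0{width}d}"
        edits = list(allele_edits[allele.name])
        ssr_edits = list(allele_ssr_edit[allele.name])
        if cfg.random_snp_rate > 0:
            k = rng.poisson(cfg.random_snp_rate * L)
            occupied = [(e.start, e.end) for e in edits + ssr_edits]
            for p in rng.choice(pool, size=k, replace=False):
                p = int(p)
                if any(s - 1 <= p < e + 1 for s, e in occupied):
                    continue
                ref_b = sense_model.sequence[p]
                alt_b = "ACGT"[(("ACGT".index(ref_b)) +
                                int(rng.integers(1, 4))) % 4]
                edits.append(hgvs.Edit(p, p + 1, alt_b))
                occupied.append((p, p + 1))
        all_edits = edits + ssr_edits
        if minus:
            final_edits = [_mirror_edit(e, L) for e in all_edits]
            var_edits = [_mirror_edit(e, L) for e in edits]
            s_edits = [_mirror_edit(e, L) for e in ssr_edits]
        else:
            final_edits, var_edits, s_edits = all_edits, edits, ssr_edits
        panel[acc] = hgvs.apply_edits(final_model.sequence, final_edits)

        def canon(e):
            return hgvs.normalize(final_model.sequence, e, final_model.strand)

        names_c = [hgvs.render_c(final_model, canon(e)) for e in var_edits]
        names_g = [hgvs.render_g(final_model, canon(e), contig=True)
                   for e in var_edits]
        ssr_names = [hgvs.render_c(final_model, canon(e)) for e in s_edits]
        tract_len = 2 * allele.ssr_repeats - (1 if allele.ssr_a_loss else 0)
        rows.append({
            "accession": acc,
            "allele": allele.name,
            "isoform": allele.isoform,
            "variants": ";".join(names_c),
            "variants_g": ";".join(names_g),
            "ssr_variant": ";".join(ssr_names),
            "ssr_repeats": allele.ssr_repeats,
            "ssr_tract_length": tract_len,
            "ssr_interrupted": allele.ssr_a_loss,
            "carrier": cfg.effect_variant in names_c or
                       cfg.effect_variant in allele.variants,
        })
    truth = SimTruth(
        accessions=pd.DataFrame(rows),
        effect_variant=cfg.effect_variant,
        effect_sizes=dict(cfg.effect_sizes),
        year_effects={y: dict(v) for y, v in cfg.year_effects.items()},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# marker definitions matching the generated reference
# ---------------------------------------------------------------------------

def default_marker_defs(cfg: SimConfig):
    """Primer pairs, enzyme and SSR bins for the generated reference.

    Primers are exact slices of the reference placed so that the deletion
    marker amplifies 344 nt (335 nt on the c.126_134del haplotype), the
    CAPS marker amplifies 454 nt with the c.495G>T-created SfaN I site
    cutting 201 nt from the 5' end, and the SSR marker product is
    208 + 2n nt for n repeats (230-282 nt over the 11-37 repeat range).
    """
    from .markers import PrimerPair, SSRLocusBins, SFANI

    sense_model, layout = _build_sense(cfg)
    s = sense_model.sequence
    sites = layout["sites"]

    def sl(key):
        a, b = sites[key]
        return s[a:b]

    primers = {
        "GRF3A-Q42": PrimerPair("GRF3A-Q42", sl("q42_f"),
                                revcomp(sl("q42_r")), 600),
        "GRF3A-Q165": PrimerPair("GRF3A-Q165", sl("q165_f"),
                                 revcomp(sl("q165_r")), 700),
        "GRF3-2AD-SSR": PrimerPair("GRF3-2AD-SSR", sl("ssr_f"),
                                   revcomp(sl("ssr_r")), 400),
    }
    enzymes = {"SfaNI": SFANI}
    bins = SSRLocusBins({"TaGRF3-2A": (230, 282), "TaGRF3-2D": (211, 223)})
    return primers, enzymes, bins


def default_ssr_locus(cfg: SimConfig):
    """The 5'UTR (AG)n tract of the generated reference, as an SSR locus."""
    from .variants import SSRLocus

    sense_model, layout = _build_sense(cfg)
    ts, te = layout["tract_start"], layout["tract_end"]
    o = sense_model.offset
    if cfg.strand == "-":
        L = len(sense_model.sequence)
        gs, ge = o + (L - 1 - te), o + (L - 1 - ts)
        return SSRLocus(unit=revcomp(SSR_UNIT), gstart=gs, gend=ge,
                        name="GRF3-2A 5'UTR (AG)n")
    return SSRLocus(unit=SSR_UNIT, gstart=o + ts, gend=o + te,
                    name="GRF3-2A 5'UTR (AG)n")


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(truth: SimTruth, cfg: SimConfig,
                        seed: int | None = None):
    """Simulate an accession x year x trait phenotype panel.

    trait value = baseline + year effect + allele effect (carriers) + noise;
    score traits are 1 + Binomial(levels-1, p) with a carrier-shifted p.
    Returns a :class:`grfhap.assoc.PhenotypePanel`.
    """
    from .assoc import PhenotypePanel

    rng = np.random.default_rng(
        [cfg.seed if seed is None else seed, 43])
    acc = truth.accessions["accession"].to_numpy()
    carrier = truth.accessions["carrier"].to_numpy()
    n = len(acc)
    records = []
    for year in cfg.years:
        yeff = cfg.year_effects.get(year, {})
        for trait, (base, sd) in cfg.traits.items():
            if cfg.noise_sd and trait in cfg.noise_sd:
                sd = cfg.noise_sd[trait]
            shift = cfg.effect_sizes.get(trait, 0.0)
            vals = (base + yeff.get(trait, 0.0)
                    + shift * carrier
                    + rng.normal(0.0, sd, size=n))
            records.append(pd.DataFrame({
                "accession": acc, "year": year, "trait": trait,
                "value": vals}))
        for trait, (levels, p, pshift) in cfg.score_traits.items():
            pvec = np.clip(p + pshift * carrier, 0.01, 0.99)
            vals = 1 + rng.binomial(levels - 1, pvec)
            records.append(pd.DataFrame({
                "accession": acc, "year": year, "trait": trait,
                "value": vals.astype(float)}))
    phen = pd.concat(records, ignore_index=True)

    pv = hgvs.parse_name(cfg.effect_variant)
    ref_allele = pv.ref or "ref"
    alt_allele = pv.alt or "alt"
    geno = pd.DataFrame({
        "accession": acc,
        "marker": cfg.effect_variant,
        "allele": np.where(carrier, alt_allele, ref_allele),
    })
    return PhenotypePanel(phenotypes=phen, genotypes=geno)


# ---------------------------------------------------------------------------
# random small models for property testing
# ---------------------------------------------------------------------------

def random_gene_model(rng, n_exons: int = 4, strand: str | None = None,
                      contig: str = "chrS", offset: int = 1001) -> GeneModel:
    """A small random—but valid—gene model, for exercising coordinate logic.

    UTRs are confined to the terminal exons; introns and flanks are short.
    """
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    exon_lens = [int(rng.integers(50, 90)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(25, 70)) for _ in range(n_exons - 1)]
    utr5 = int(rng.integers(5, 25))
    utr3 = int(rng.integers(5, 25))
    cds_len = sum(exon_lens) - utr5 - utr3
    cds_len -= cds_len % 3
    utr3 = sum(exon_lens) - utr5 - cds_len
    flank5 = int(rng.integers(10, 40))
    flank3 = int(rng.integers(10, 40))

    middle = list(rng.choice(_NONSTOP_CODONS, size=cds_len // 3 - 2))
    cds = "ATG" + "".join(middle) + "TGA"
    # assemble transcript then split into exons
    dna = "ACGT"
    tx = ("".join(rng.choice(list(dna), size=utr5)) + cds +
          "".join(rng.choice(list(dna), size=utr3)))
    pieces, at = [], 0
    for ln in exon_lens:
        pieces.append(tx[at:at + ln])
        at += ln
    sense = "".join(rng.choice(list(dna), size=flank5))
    exon_spans_local = []
    for i, ex in enumerate(pieces):
        exon_spans_local.append((len(sense), len(sense) + len(ex) - 1))
        sense += ex
        if i < n_exons - 1:
            sense += "".join(rng.choice(list(dna), size=intron_lens[i]))
    sense += "".join(rng.choice(list(dna), size=flank3))

    cds_start_local = flank5 + utr5
    # cds start is inside exon 1 only if utr5 < exon_lens[0]; guaranteed above
    tx_locals = [g for s, e in exon_spans_local for g in range(s, e + 1)]
    cds_end_local = tx_locals[utr5 + cds_len - 1]

    exons = [(offset + s, offset + e) for s, e in exon_spans_local]
    model = GeneModel(contig=contig, offset=offset, sequence=sense,
                      strand="+", exons=exons,
                      cds_start=offset + cds_start_local,
                      cds_end=offset + cds_end_local, promoter=None)
    if strand == "-":
        model = _mirror_model(model)
    return model
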