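"""Protein isoform grouping and frequency-ranked allele designation.

Haplotypes translating to the same protein form an isoform group.  Groups
are lettered A, B, C, ... in decreasing order of total accession frequency;
within each group haplotypes are ranked 1, 2, ... by their own frequency,
yielding allele names like ``b.1`` (lowercase letter = encoded isoform,
number = haplotype frequency rank within the group).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .gene_model import CodingPosition, GeneModel, cds_to_protein_position
from .variants import HaplotypeRecord, name_protein_change, _apply_to_cds


@dataclass
class IsoformGroup:
    letter: str
    protein_sequence: str
    member_haplotypes: list[HaplotypeRecord]
    frequency: int                 # total member accessions
    protein_change: str = ""       # HGVS p. vs the reference protein


@dataclass(frozen=True)
class AlleleName:
    isoform_letter: str            # lowercase
    rank: int

    @property
    def rendered(self) -> str:
        return f"{self.isoform_letter}.{self.rank}"

    def __str__(self) -> str:
        return self.rendered


def translate_haplotype(model: GeneModel, hap: HaplotypeRecord) -> str | None:
    """Protein encoded by a haplotype, or None if the CDS gained an
    internal stop (flagged with a warning)."""
    alt_cds = _apply_to_cds(model, hap.variant_set)
    prot = str(Seq(alt_cds).translate())
    body = prot[:-1] if prot.endswith("*") else prot
    if "*" in body:
        warnings.warn(
            f"haplotype {hap.haplotype_id} has an internal stop; excluded")
        return None
    return body


def _codon_range(v) -> tuple[int, int] | None:
    """Codon span of a variant's coding addresses, or None outside the CDS."""
    import re as _re
    from . import hgvs as _hgvs
    pv = _hgvs.parse_name(v.name_c)
    codons = []
    for addr in (pv.a, pv.b):
        if addr is None:
            continue
        cp = CodingPosition.parse(addr)
        if cp.kind != "cds":
            return None
        codons.append(cds_to_protein_position(cp.base))
    return min(codons), max(codons)


def protein_changes(model: GeneModel,
                    variant_set: list[HaplotypeRecord]) -> list[str]:
    """HGVS p. descriptions, one per cluster of codon-adjacent variants.

    DNA variants hitting the same or consecutive codons are named jointly
    (two nearby substitutions altering consecutive residues collapse into
    one delins); distant variants are named separately.
    """
    cds_vars = []
    for v in variant_set:
        rng = _codon_range(v)
        if rng is not None:
            cds_vars.append((rng, v))
    cds_vars.sort(key=lambda t: t[0])
    clusters: list[list] = []
    last_end = -10
    for (a, b), v in cds_vars:
        if clusters and a <= last_end + 1:
            clusters[-1].append(v)
            last_end = max(last_end, b)
        else:
            clusters.append([v])
            last_end = b
    out = []
    for cl in clusters:
        name = name_protein_change(model, cl)
        if name != "p.(=)":
            out.append(name)
    return out


def group_isoforms(haplotypes: list[HaplotypeRecord],
                   model: GeneModel) -> list[IsoformGroup]:
    """Partition haplotypes by translated protein; letter by frequency.

    Frequencies count accessions.  Ties are broken lexicographically by
    protein sequence, making the lettering invariant to input order.
    """
    by_protein: dict[str, list[HaplotypeRecord]] = {}
    for h in haplotypes:
        prot = translate_haplotype(model, h)
        if prot is None:
            continue
        by_protein.setdefault(prot, []).append(h)
    ordered = sorted(
        by_protein.items(),
        key=lambda kv: (-sum(h.count for h in kv[1]), kv[0]))
    groups = []
    for letter, (prot, members) in zip(_letters(), ordered):
        members = sorted(members, key=lambda h: (-h.count,
                                                 h.member_accessions[0]))
        changes = protein_changes(model, members[0].variant_set)
        groups.append(IsoformGroup(
            letter=letter, protein_sequence=prot,
            member_haplotypes=members,
            frequency=sum(h.count for h in members),
            protein_change="; ".join(changes) if changes else "-"))
    return groups


def _letters():
    for ch in string.ascii_uppercase:
        yield ch
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            yield a + b


def designate_alleles(groups: list[IsoformGroup]
                      ) -> dict[str, AlleleName]:
    """Assign letter.rank names to haplotypes.

    Rank 1 is the most frequent haplotype of the group; frequency ties are
    broken by the earliest-sorting member accession name, then by fewer
    variants (a deterministic, input-order-invariant rule).
    """
    out: dict[str, AlleleName] = {}
    for g in groups:
        ranked = sorted(
            g.member_haplotypes,
            key=lambda h: (-h.count, h.member_accessions[0],
                           len(h.variant_set)))
        for rank, h in enumerate(ranked, start=1):
            out[h.haplotype_id] = AlleleName(g.letter.lower(), rank)
    return out


def write_designation_table(groups: list[IsoformGroup],
                            names: dict[str, AlleleName],
                            model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tallele\tisoform\tprotein_change\t"
                 "n_accessions\taccessions\n")
        for g in groups:
            for h in g.member_haplotypes:
                p = name_protein_change(model, h.variant_set)
                fh.write(f"{h.haplotype_id}\t{names[h.haplotype_id]}\t"
                         f"{g.letter}\t{p}\t{h.count}\t"
                         f"{','.join(h.member_accessions)}\n")
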