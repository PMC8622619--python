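# grfhap

Single-gene haplotype diversity analysis for plant molecular breeding:
variant discovery with HGVS naming over a gene region, protein-isoform
grouping with frequency-ranked allele designation, in-silico molecular
markers (PCR, CAPS, SSR), SNP-only phylogenies, and marker–trait
association statistics.

## The problem

Breeding programs routinely resequence a candidate gene — here modeled on
the wheat growth-regulating factor gene *TaGRF3-2A*
(TraesCS2A02G435100) — across a panel of accessions, and then need to:

1. name every difference against the reference in HGVS notation
   (`g.687050412G>T`, `c.495G>T`, `p.(Gln165His)`, `c.126_134del`,
   `c.325+32_325+33insTCC`, …), including the length of a 5'UTR
   microsatellite such as the (AG)n tract whose repeat number runs from
   11 to 37;
2. collapse identical sequences into haplotypes, partition haplotypes by
   the protein they encode, and designate alleles *letter.rank* — a
   lowercase letter for the encoded isoform (A, B, C, … by accession
   frequency) and a number for the haplotype's frequency rank within the
   isoform group (so the most common haplotype of the most common isoform
   is `a.1`);
3. predict what cheap gel-based markers will show: a subgenome-specific
   primer pair spanning an indel (344 bp vs 335 bp products for a 9-nt
   deletion), a CAPS assay in which a SNP creates an *Sfa*N I site
   — GCATC(5/9), a type IIS enzyme cutting 5 nt (top strand) / 9 nt
   (bottom strand) downstream — so the 454 bp amplicon is cleaved into
   201 + 253 bp for one allele and stays intact for the other, and a
   fluorescent SSR assay whose product-size bins (230–282 bp for the 2A
   homoeolog, 211–223 bp for 2D) do not overlap;
4. place haplotypes on a neighbor-joining tree built from substitution
   columns only (indel and microsatellite columns removed), rooted on a
   homoeologous outgroup, with bootstrap support; and
5. test marker–trait associations: per-year one-way ANOVA F-tests with
   95% confidence intervals, three-year least-squares means from an
   additive genotype+year model, Fisher's exact test for score traits,
   and allele-frequency tabulation.

Because the real resequencing data live in external archives, the package
ships a first-class synthetic-data generator that builds a surrogate gene
honoring every published structural constraint (flank lengths, exon
layout, polyglutamine tract at residues 38–44, 5'UTR (AG)n tract, and the
full variant catalog with its printed HGVS names as the canonical
3'-shifted representations) plus phenotypes with planted allele and year
effects, so the entire pipeline is testable end to end with no downloads.

## Worked example

```python
from grfhap import SimConfig, simulate_reference, simulate_panel
from grfhap.synthetic_data import default_marker_defs, default_ssr_locus
from grfhap import variants, proteins, markers

cfg = SimConfig(seed=1)
model = simulate_reference(cfg)
panel, truth = simulate_panel(model, cfg)

haps = variants.analyze_panel(model, panel,
                              ssr_locus=default_ssr_locus(cfg))
groups = proteins.group_isoforms(haps, model)
names = proteins.designate_alleles(groups)

print(f"{len(panel)} accessions -> {len(haps)} haplotypes, "
      f"{len(groups)} protein isoforms")
for g in groups:
    print(f"  isoform {g.letter}: {g.frequency:3d} accessions   "
          f"{g.protein_change}")

primers, enzymes, bins = default_marker_defs(cfg)
b1 = next(h for h in haps if str(names[h.haplotype_id]) == "b.1")
d1 = next(h for h in haps if str(names[h.haplotype_id]) == "d.1")
q42, q165 = primers["GRF3A-Q42"], primers["GRF3A-Q165"]
print("Q42 product (wild type):",
      [p.length for p in markers.insilico_pcr(model.sequence, q42)])
print("Q42 product (d.1):      ",
      [p.length for p in markers.insilico_pcr(d1.sequence, q42)])
amp = markers.insilico_pcr(b1.sequence, q165)[0]
print(f"Q165 amplicon {amp.length} bp -> SfaNI fragments",
      markers.caps_digest(amp.sequence, enzymes["SfaNI"]))
carriers = int(truth.accessions.carrier.sum())
print(f"c.495G>T carriers: {carriers}/{len(panel)} "
      f"({100*carriers/len(panel):.1f}%)")
```

prints

```
199 accessions -> 11 haplotypes, 4 protein isoforms
  isoform A: 116 accessions   -
  isoform B:  77 accessions   p.(Gln165His)
  isoform C:   4 accessions   p.(Gln176_Ala177delinsHisGly); p.(Asp243Glu)
  isoform D:   2 accessions   p.(Gln42_Gln44del)
Q42 product (wild type): [344]
Q42 product (d.1):       [335]
Q165 amplicon 454 bp -> SfaNI fragments [201, 253]
c.495G>T carriers: 77/199 (38.7%)
```

Reading the output: the simulated 199-accession panel collapses to 11
haplotypes encoding 4 protein isoforms; the most frequent isoform (A) is
the reference protein, B carries the Gln165His substitution, C the two
wild-diploid changes, D the three-glutamine deletion.  The deletion
marker shifts from 344 to 335 bp on the deletion haplotype; the CAPS
marker's 454 bp amplicon is cut into 201 + 253 bp when the SNP creates
the *Sfa*N I site; and 38.7% of accessions carry the `c.495G>T` variant.

The same pipeline is scriptable from the shell:

```bash
grfhap simulate --seed 1 --out sim/
grfhap call --ref sim/reference.fa --ann sim/reference.ann.tsv \
            --panel sim/panel.fa --ssr-locus sim/ssr_locus.json --out call/
grfhap designate --ref sim/reference.fa --ann sim/reference.ann.tsv \
            --panel sim/panel.fa --out designate/
grfhap markers --panel sim/panel.fa --markers sim/markers.toml --out markers.tsv
grfhap phylo --ref sim/reference.fa --ann sim/reference.ann.tsv \
            --panel sim/panel.fa --reps 500 --seed 7 --out tree.nwk
grfhap assoc --phen sim/phenotypes.tsv --geno sim/genotypes.tsv --out assoc/
```

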