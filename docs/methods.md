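# Methods

## Gene model and coordinates

A `GeneModel` stores one contiguous genomic slice (plus strand), its exon
intervals, CDS span, strand and promoter window, all 1-based inclusive.
Coding-style addresses follow HGVS: CDS bases are numbered 1..L along the
spliced coding strand; bases 5' of the A of ATG are `c.-N` (numbering
continues through the promoter/flank, since the stored region is small);
bases 3' of the stop codon are `c.*N`; intronic bases are anchored to the
nearest exon edge as `c.N+M` / `c.N-M`, with midpoint ties assigned to the
5' edge.  Minus-strand genes are fully supported: the stored sequence stays
in genomic orientation and all coding-space logic operates on the reverse
complement.  Annotation travels in a one-row TSV sidecar; a GFF3 import
helper honors `gene`/`exon`/`CDS` features only.

Variant names (`c.`/`g.`; SNV, del, ins, delins) are parsed and rendered by
a dedicated module.  Indels are normalized to the most-3' representation on
the coding strand (trim shared prefix/suffix bases, then shift while the
flanking base matches).  The abbreviated intron-insertion form
`c.325+32_+33insTCC` is accepted as an alias of the full
`c.325+32_325+33insTCC`; only `+` offsets may be abbreviated because a bare
`-N` is indistinguishable from a 5'UTR address.  Genomic (`g.`) names of
minus-strand indels show the same coding-strand-shifted interval rather
than a separate plus-strand normalization, so the two names always describe
one edit.

## Synthetic reference

The generator builds a surrogate gene, not the real chromosome-2A sequence
(which is not distributed here).  Every structural constraint the analysis
relies on is honored exactly:

- 1,075 nt stored before the start codon and 1,389 nt after the stop codon;
- four exons with CDS segments c.1–100 / c.101–325 / c.326–689 / c.690–768
  (255 residues + stop), so the catalogued variants fall in exon 2
  (c.126_134del), exon 3 (c.495, c.528, c.530), exon 4 (c.729), intron 2
  (c.325+…, c.326-…) and intron 3 (c.689+…);
- a polyglutamine tract of 7 CAG codons at residues 38–44 with codon 45 =
  CAC, which makes `c.126_134del` the canonical 3'-shifted name of the
  9-nt deletion and `p.(Gln42_Gln44del)` its protein effect;
- codons 164–166 = GCG·CAG·CTC, so the reference shows GCAGC across
  c.492–496 and the `c.495G>T` substitution creates the single *Sfa*N I
  site GCATC of the CAPS assay;
- a 5'UTR (AG)n tract starting at c.-85 (reference n = 28), with the 12-nt
  deletion site c.-102_-91 a few bases upstream;
- intron lengths 450 / 520 / 1,470 nt, 5'UTR 200 nt and 3'UTR 331 nt.
  These are solved, not measured: with the coordinate system anchored at
  c.495 = chr2A:g.687050412, they place all catalogued absolute
  coordinates (four promoter SNVs, the promoter analysis window
  g.687047878_687048697, and g.687052487 immediately after the transcript
  end) into the structurally correct compartments.  The real intron and
  UTR lengths of the locus are not published in the source material used
  here.

Random filler sequence is drawn from a seeded generator; two sanitation
passes then (a) remove any stray GCATC/GATGC from the CAPS amplicon window
and (b) break competing (AG)≥4 runs inside the SSR amplicon window, always
mutating unconstrained bases and never creating an internal stop codon.
Marker primers are exact 20–23-nt slices of the finished reference, placed
so the deletion marker yields 344 bp (335 bp on the deletion haplotype),
the CAPS amplicon is 454 bp with its top-strand cut 201 nt from the 5'
end, and the SSR product is 208 + 2n bp — mapping the 11–37 repeat range
onto the 230–282 bp homoeolog bin.

## Allele catalog and panel

The default catalog replays the published variant sets as eleven named
alleles across the A/B/C/D isoforms.  The only frequency the source
anchors numerically is the ~39% carrier rate of the `c.495G>T` allele
among 199 genotyped accessions; the generator uses deterministic
largest-remainder counts that give exactly 77/199 = 38.7% carriers.  All
other allele frequencies and SSR repeat counts are invented defaults,
chosen once to give a realistic frequency spectrum (two common alleles,
a tail of rare ones, singletons for the wild-species haplotypes).  The
emmer-like allele (a.16) keeps the reference repeat count: its 12-nt UTR
deletion lies a few bases from the tract, and a simultaneous tract-length
change there has no unambiguous pairwise alignment, so no caller could be
expected to factor the two events the same way the generator did.  An
optional per-accession rate of private non-coding SNPs (default 0) grows
the haplotype count beyond the catalog.

The tract length of an interrupted repeat counts all bases of the merged
run (an (AG)28 tract with one A lost measures 55 nt), and the repeat count
counts complete units (27); both conventions are reported because gel/
capillary figures are naturally read either way.

## Variant calling

Each unique panel sequence is globally aligned to the reference with
Biopython's `PairwiseAligner` (match +1, mismatch −2, gap open −6, gap
extend −1; a length-L gap costs 6 + L).  Runs of adjacent non-matching
columns become single events — so two substitutions separated by even one
matching base stay separate SNVs (e.g. c.528G>C and c.530C>G), while truly
contiguous mismatches merge into a delins.  Indels are 3'-shifted on the
coding strand before naming.  The microsatellite tract is masked during
calling and measured separately by anchored search (downstream flank
first, then upstream), merging runs interrupted by a partial unit.
Protein effects are named by translating reference and alternate CDS and
diffing with maximal common prefix then suffix, which yields the most
C-terminal placement for deletions in repeat runs; consecutive changed
residues render as a protein-level delins.  Frameshifts raise an explicit
error (none occur in the catalog).  A minimal sites-only VCF 4.2 writer
emits the same edits left-aligned with anchor bases — deliberately the
opposite shifting convention from HGVS, as VCF requires.

## Isoforms and allele designation

Haplotypes translating to identical proteins form isoform groups lettered
A, B, C, … by total accession frequency (ties broken lexicographically by
protein sequence).  Within a group, haplotypes are ranked by frequency;
ties break by earliest-sorting member accession name, then by fewer
variants.  Both orderings are invariant to input order.  Frequencies count
accessions, not haplotypes.  Haplotypes whose CDS gains an internal stop
are excluded with a warning.

## Phylogeny

The SNP matrix keeps substitution columns only: positions covered by a
deletion or length-changing delins in any taxon are eliminated (the
"positions containing gaps removed" convention), insertions contribute no
reference positions, the microsatellite window is masked, and equal-length
multi-base substitutions are decomposed into per-position columns.  A
consequence used as a test invariant: adding an indel-only haplotype never
changes existing pairwise distances, and a deletion-only haplotype
collapses onto the reference.  Distances are p-distances or Jukes–Cantor
(undefined at p ≥ 0.75, reported per pair).  Neighbor joining is the
canonical agglomeration with Q-criterion ties broken by the lowest index
pair and negative branch lengths clamped to zero; on additive matrices the
true topology and branch lengths are recovered exactly, which the test
suite verifies against an independent random-tree oracle and against
scikit-bio's implementation.  Maximum-likelihood inference is deliberately
out of scope: NJ over p/JC distances keeps the analysis deterministic at
desk scale, and the qualitative haplotype groupings are the comparison
surface.  Outgroup rooting bisects the outgroup's pendant edge.  Bootstrap
resamples columns with replacement, rebuilds NJ per replicate, and maps
bipartition frequencies onto the full-data tree; runs are seeded.
Protein trees reuse the machinery with alignment-based identity distances
in which a gap counts as a 21st state.

## Association statistics

"F-test" means the one-way ANOVA F between marker genotype groups within a
single year (the model formula is not otherwise specified in the source);
group means carry normal-theory (t-based) 95% confidence intervals.
Multi-year summaries are least-squares means from the additive
`value ~ genotype + year` OLS fit, averaging predictions over year levels
with equal weight — reducing to raw group means for balanced data;
rank-deficient designs (a genotype absent from the fit) are flagged
rather than silently dropped.  Fisher's exact test is the two-sided
hypergeometric rule (sum of tables no more probable than observed) via
scipy, validated in the suite against full integer enumeration for every
table with total ≤ 40.  Score traits enter Fisher's test as a 2×2 layout
of carrier status × above/below the panel median — one of several
defensible constructions, chosen and documented here.  Raw p-values are
reported; a Benjamini–Hochberg column is available but off by default.
Missing phenotype cells are dropped listwise per trait.

## Phenotype simulation

trait value = baseline + year effect + allele effect (carriers of the
designated variant, default `c.495G>T`) + Gaussian noise; score traits are
1 + Binomial(levels−1, p) with a carrier-shifted p.  Defaults: heading
date 205 days after sowing (sd 2, carrier effect −2), 1000-kernel weight
40 g (sd 3, +1.5), test weight 780 g/L (sd 15, +10), grain protein 14%
(sd 0.8, +0.3), grain yield 7 t/ha (sd 0.8, −0.2), three years with
small invented year shifts.  Effect directions follow the reported
associations (earlier heading, better grain filling, slightly lower
yield); magnitudes are invented but sized so a −2 day shift at sd 2 and
n≈200 gives essentially full power for the per-year F-test, while the
zero-effect configuration yields a type-I error statistically
indistinguishable from the nominal 5% (checked over 500 seeded
replicates).

## What the synthetic data do and do not show

The generator emulates assembled, homozygous, gap-free gene-region
sequences (wheat accessions are inbred lines), a deterministic allele
composition, and additive phenotype effects.  It does not emulate
sequencing error, heterozygosity, alignment-ambiguous tandem repeat
polymorphism beyond the single microsatellite, population structure, or
genotype×year interaction — so passing tests demonstrate correctness of
the computational pipeline under clean inputs, not robustness to raw-read
artifacts.  Real GenBank sequences can be swapped in for the panel at any
time; nothing in the pipeline depends on generator internals.

## Problem sizes and numerics

The default panel is 199 accessions (the genotyped panel size) collapsing
to 11 haplotypes; alignments are ~5.7 kb pairwise and take a few seconds
per unique haplotype.  Bootstrap defaults to 500 replicates.  Branch
lengths are clamped at ≥ 0; distances use exact column counts; Fisher and
F p-values come from scipy's exact/analytic distributions.  Determinism:
every stochastic step (reference filler, panel assignment, private SNPs,
phenotypes, bootstrap) derives from an explicit integer seed.
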