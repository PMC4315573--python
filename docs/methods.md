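# Methods

## Problem setting

A nuclear family segregates a phenotype in every sibling. Whole-genome
variant calls exist for the affected siblings (and possibly the parents);
the task is to reduce millions of called variants to the handful that could
explain the phenotype under a Mendelian model, and to say something about
their origin. `kindredvar` implements the post-calling portion of that
analysis; read alignment, variant calling and recalibration are upstream
and out of scope — the pipeline consumes VCF.

## Data model

Variants are normalised to biallelic records: multi-allelic sites are split
one record per ALT (other ALT alleles collapse to reference in the GT, the
`bcftools norm` convention), shared flanking bases are trimmed, and indels
are left-aligned against the reference when one is supplied. Coordinates
are 1-based inclusive at the interface (VCF convention) and 0-based
half-open internally. Genotypes are unordered diploid allele pairs over
{ref, alt, missing}; `./.` is *missing*, never hom-ref — with one deliberate
exception below. `FILTER` maps PASS → pass, `.` → unfiltered (kept by
default, dropped under `strict_pass`), anything else → fail.

**Merging per-member VCFs.** When each family member has a single-sample
VCF, a site absent from one member's file is assigned hom-ref for that
member: every member was assayed genome-wide, so a missing record is
evidence of absence, not absence of evidence. This mirrors the two-phase
design in which parental genotypes at candidate sites come from targeted
validation: "absent in both parents" is a genotype, and the
germline-mosaicism call depends on it. Explicit `./.` calls remain missing
and propagate to an *ambiguous* origin.

## Transcript model and impact classes

One canonical transcript is kept per gene — the longest CDS, ties broken by
lexicographically smallest transcript id. This trades multi-isoform realism
for a deterministic, testable effect model. Transcripts whose spliced CDS
length is not divisible by 3 are excluded from translation-based calls but
retained for splice classification.

Impact classes: `FRAMESHIFT`, `NONSENSE`, `MISSENSE`, `SPLICE_SITE`,
`INFRAME_INDEL`, `SYNONYMOUS`, `NONCODING`; *high impact* is exactly
{frameshift, nonsense, splice site}. Classification rules:

* CDS overlap takes precedence. Indels are classified purely by length
  arithmetic (change % 3); SNVs by translating the affected codon
  (strand-aware). An indel that also spans intronic bases is still
  classified by its total length change — a desk-scale simplification.
* A splice site is one of the 2 intronic bases immediately after an exon
  end or immediately before an exon start, at internal exon boundaries
  only. Terminal transcript edges are never splice sites, and no exonic
  base ever is. This strict 2+2 definition is narrower than annotation
  tools' "splice region" (which typically extends 3 bases into exons and
  8 into introns); it is the definition this pipeline is built around.
* For a transcript with an invalid CDS, coding variants get
  length-arithmetic-only calls flagged `low_confidence`; an SNV there maps
  to `INFRAME_INDEL` (an in-frame coding change of unknown effect), since
  no translation-based distinction is possible.

## The funnel

Stage order is fixed: quality → rarity → model grouping → panel. The rarity
filter discards a variant iff **any** configured source records a frequency
above the threshold (default 0.01); unrecorded variants survive, which is
what lets a novel causal variant reach the de novo model. The high-impact
de novo model then applies the stricter condition of *no record at all* (no
rsid, no frequency), so a 0.5% variant passes rarity but never that model.

Compound heterozygosity is approximated without phase: ≥ 2 distinct het
variants in one gene. No parental haplotypes are required. When
intersecting across siblings (`pair_identical=True`, the default), the
compound-het rule is re-derived on the intersection: a gene survives only
if the same ≥ 2 variants are het in every sibling, and a hom-alt candidate
only if hom-alt in every sibling. The variant-by-variant alternative is
available behind the flag.

The X-linked model imposes no zygosity constraint beyond carriage, because
with affected brothers either het-coded or hemizygous calls may appear
depending on the caller.

The funnel report counts, per sibling and for the shared intersection:
high-confidence variants, coding / splice / SNV / indel subsets, panel
overlap, rarity survivors, and for each model its variants, genes, and both
restricted to the panel. Counts are non-increasing along nested stages by
construction.

## HGVS consequences

For frameshift/nonsense/missense candidates the coding-DNA and protein
notations are derived by editing the CDS and diffing translations. Two
shifting conventions coexist deliberately: the VCF record stays
left-aligned, while the `c.` position is 3'-most shifted within the CDS as
HGVS requires (a deletion in a homopolymer is reported at the run's last
base). The protein description comes from the first codon at which the
mutant translation differs; for frameshifts, `fs*N` with N the 1-based
offset of the first stop in the shifted frame counting the first changed
residue as 1 — equivalently N−1 altered residues precede the stop
(`missense_run == stop_offset − 1` is asserted on every annotation). A
frameshift with no stop before the CDS end is written `fs*?`. A frameshift
whose first altered codon is itself a stop is written in nonsense style
(`p.Xxx<pos>*`, stop offset 1). The supported grammar is substitutions,
deletions and insertions with three-letter residue codes; duplications,
inversions, extensions and intronic `c.` offsets are out of scope.

## Origin classification

For a candidate carried by at least one affected sibling, with both
parental genotypes available: any carrier parent → *inherited*; both
parents hom-ref → *de novo*, and if ≥ 2 affected siblings carry the allele
→ *shared de novo, consistent with germline mosaicism* (independent
identical de novo events in multiple children are essentially impossible,
so a parental germ-cell lineage must carry the mutation). Any missing or
unavailable parental genotype → *ambiguous*. The carrier-parent check runs
first, so one carrier parent decides inheritance even if the other parent
is missing. Genotypes cannot distinguish germline from low-grade somatic
mosaicism, and the mutant germ-cell fraction is unknowable from this data,
so no recurrence risk is computed — the hedged wording is intentional.

The ranked report orders candidates (shared scope first, high impact first,
de novo/mosaic origin first, then position); it replaces a manual review
step with a deterministic, documented policy, not a claim about pathogenicity.

## Synthetic families

The generator builds everything the pipeline consumes. Reference: ~40 genes
of ~1.2 kb across four autosomes and an X contig, each with one 3-exon
transcript whose CDS starts ATG, ends TAA, has no internal stop and length
divisible by 3; ~30% of genes are minus-strand. The first 12 genes carry
real ASD-panel symbols (SHANK3 first, one on X) and form the written panel.

Background variation: position-unique SNVs (90%) and 1-bp deletions (10%),
each shared by all three siblings with probability 0.75 (matching the ~3/4
sharing seen in sibling genomes) or private to one sibling; every
background allele is carried het by at least one parent; 5% of records fail
the upstream quality filter. Frequencies are drawn uniform on
[0.001, 0.5] (4 decimals) for two sources with ±30% jitter, and by default
every background variant is recorded (rsid + frequencies) — background
stands for known population variation, while planted variants are novel.
Defaults: 2000 background variants per sibling (the examples and acceptance
runs use 1200), a scale-down by ~3 orders of magnitude from genome-wide
counts, flagged as such in the text report.

Two structural conditions make recovery counts exact rather than merely
likely: background never collides with planted positions, and at most one
rarity-surviving background variant may be shared by all siblings per gene
— further ones are redrawn as common, and genes hosting planted variants
count as already occupied (otherwise a rare background het could pair with
a planted allele into a spurious shared compound het). Rare background
variants are always het (at ≤1% frequency a homozygote has probability
< 10⁻⁴ per genotype). Planted scenarios follow their model's pattern:
recessive — hom-alt siblings, het parents (or a compound-het pair split
between the parents); X-linked — het siblings and mother; high-impact
de novo — frameshift het in all siblings, absent in both parents, no
database record.

All randomness flows from one seeded NumPy generator per operation
(spawned from the config seed); outputs are byte-identical for a fixed
seed.

**What passing tests do and do not show.** The generator has no linkage,
no realistic allele-frequency spectrum, no recombination, no sequencing
error and no genotype missingness; background sharing is exchangeable
across sites. Recovery of planted variants therefore demonstrates that the
filter logic is correct, not that its operating characteristics on real
WGS data (where annotation errors, population structure and caller
artifacts dominate) would be the same. Genome-scale counts from real
families are not reproducible at this scale and are not attempted.

## Numerical and policy choices

* Rarity threshold 0.01; comparison is `>` threshold to discard, so a
  frequency of exactly 1% survives.
* Frequencies are rounded to 6 decimals on read (absorbing float32 INFO
  storage); the generator emits 4-decimal values, so round-trips are exact.
* Tie-breaks are everywhere lexicographic/positional (canonical transcript,
  overlapping-transcript lookup, report ordering), making every output
  deterministic under input permutation.
* Gene symbols match case-insensitively throughout (panel, compound-het
  grouping).
* The bundled 182-symbol ASD panel is a constructed stand-in of
  well-established ASD-associated gene symbols (filename and docstring say
  so); analyses should supply their own panel file where it matters.

## Problem sizes

The test suite and the acceptance script run families of 1200 background
variants per sibling over 20 seeds per scenario (~0.4 s per family
end-to-end); property suites scan every SNV and short deletion of a ≤1 kb
toy gene and the full 4×4×3 parental-genotype × carrier-count truth table.
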