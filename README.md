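# kindredvar

Variant prioritization for multiplex families: given VCFs for several
affected siblings (and optionally their parents), a reference with transcript
models and a gene panel, `kindredvar` runs the classic post-calling funnel —
quality filtering, population-rarity filtering at 1%, grouping under three
Mendelian inheritance models, cross-sibling intersection and panel
restriction — then annotates the survivors with HGVS coding/protein
consequences and classifies their inheritance origin from parental
genotypes, including the germline-mosaicism pattern.

It is aimed at the analysis that follows variant calling in a family where a
phenotype (e.g. an autism spectrum disorder) segregates in all siblings:
which rare variant, shared by every affected child and compatible with an
inheritance model, explains the phenotype?

## The analysis in brief

Per affected sibling *s*, starting from high-confidence variants
(FILTER = PASS):

* **rarity** — discard any variant with a recorded population frequency
  > 1% in any configured source (1000 Genomes, ESP); unrecorded variants
  survive;
* **recessive model** — autosomal hom-alt variants, plus an unphased
  compound-heterozygote proxy: every het variant in a gene carrying ≥ 2
  distinct het variants in *s*;
* **X-linked model** — variants on chromosome X carried by *s*;
* **high-impact de novo model** — frameshift, nonsense or splice-site
  variants (splice site = the 2 intronic bases flanking each internal exon
  boundary) with **no** database record at all (no rsid, no frequency);
* **shared** — the intersection over all affected siblings on
  (chrom, pos, ref, alt), with compound-het pairs required to be intact in
  every sibling;
* **panel** — restriction to a gene panel (e.g. a 182-gene ASD panel).

A frameshift's protein consequence is written as `p.<Ref><pos><New>fs*N`:
the shifted frame reads through N−1 missense codons and stops at offset N.
A shared candidate that is het in ≥ 2 affected siblings while both parents
are confirmed hom-ref is called *shared de novo, consistent with germline
mosaicism* — one parent carries the mutation in a fraction of germ cells
but not in somatic DNA.

A synthetic-data module generates complete families (reference FASTA, GFF3
transcripts, panel, per-member VCFs, PED) with planted causal variants for
each model, so the whole pipeline is testable end-to-end with no external
data.

## Worked example

```bash
python examples/02_prioritize_family.py
```

simulates a family (three affected brothers, two parents, ~1200 background
variants per sibling, one planted unrecorded frameshift het in all three
siblings and absent from the parents) and runs the pipeline. Output:

```
                                                        SIB1   SIB2   SIB3  shared
High-confidence variants                                1124   1134   1123    1011
In coding regions                                        589    601    595     533
...
Rare (unrecorded or below threshold)                      19     21     21      18
Compliant with the high-impact de novo model               1      1      1       1
In panel genes and compliant with the high-impact
  de novo model                                            1      1      1       1

top candidate : 1:800 CA>C in SHANK3
model / scope : high_impact_rare / shared
origin        : shared de novo, consistent with germline mosaicism
consequence   : c.371del, p.His124Profs*7
```

Reading: of ~1100 high-confidence variants per sibling, 19–21 survive the
1% rarity filter, and exactly one — the planted frameshift — is high-impact,
absent from every database, shared by all three siblings and in a panel
gene. Its deletion shifts the frame at codon 124: six altered codons, then a
premature stop (`fs*7`). Both parents are hom-ref, so the origin call is the
germline-mosaicism pattern.

The other examples show simulation (`01`), the HGVS frameshift arithmetic on
a 6-codon toy gene (`03`), and origin classification across genotype
patterns (`04`). A thin CLI wraps the same library calls:
`kindredvar simulate|run|consequence --help`.

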