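"""Generate a synthetic multiplex family and look at what was written.

Creates a small reference genome with 3-exon genes, a gene panel, per-member
VCFs for three affected brothers and their parents, and a PED file. One
unrecorded frameshift is planted heterozygous in all three siblings and in
neither parent — the genotype signature of germline mosaicism.
"""

from pathlib import Path

from kindredvar import SimConfig, simulate
from kindredvar.prioritization import ModelName
from kindredvar.vcf_io import read_vcf

out = Path("example_output/sim")
config = SimConfig(seed=42, n_background_variants=1200)
reference, family = simulate(config, out)

print(f"reference contigs : {sorted(reference.contigs)}")
print(f"genes / panel     : {len(reference.transcripts)} / {len(reference.panel)}")
for member, path in family.vcf_paths.items():
    print(f"{member:6s} variants : {len(read_vcf(path))}")

(planted,) = family.planted[ModelName.HIGH_IMPACT_RARE]
print(f"\nplanted frameshift: {planted.chrom}:{planted.pos} "
      f"{planted.ref}>{planted.alt} in {planted.gene}")
print("carried het by all three siblings, absent from both parental VCFs,")
print("and carries no rsid or population frequency — it must survive every")
print("filter stage and end up as the single shared de novo candidate.")
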