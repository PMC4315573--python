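"""HGVS frameshift arithmetic on a 6-codon toy gene.

A 1-bp deletion shifts the reading frame: translation runs through a short
missense stretch and then hits a premature stop. HGVS writes this as
p.<Ref><pos><New>fs*<N>, where N counts the new stop from the first changed
residue — so N-1 altered codons precede it.
"""

from kindredvar import (
    VariantRecord, apply_variant_to_cds, hgvs_consequence, parse_hgvs_p,
    translate,
)
from kindredvar.annotation import TranscriptModel

CDS = "ATGAGTCGCATGACTTAA"  # Met Ser Arg Met Thr Stop
UTR = "GGGGG"

transcript = TranscriptModel(
    transcript_id="TX_TOY", gene="TOY", chrom="7", strand="+",
    exons=((0, len(UTR) + len(CDS) + 5),),
    cds_start=len(UTR), cds_end=len(UTR) + len(CDS), cds_seq=CDS)
genome = UTR + CDS + "CCCCC"

print(f"wild type : {CDS} -> {translate(CDS)}")
mutated = apply_variant_to_cds(CDS, 7, "G", "")  # delete coding base 8
print(f"del c.8   : {mutated} -> {translate(mutated)}")

# the same deletion as an anchored VCF-style record (1-based genomic)
variant = VariantRecord(chrom="7", pos=12, ref="CG", alt="C")
ann = hgvs_consequence(transcript, variant)
print(f"\nhgvs      : {ann.hgvs_c}, {ann.hgvs_p}")
print(f"arithmetic: stop offset {ann.stop_offset} => "
      f"{ann.missense_run} missense codon(s) before the new stop")

parsed = parse_hgvs_p("p.Ser1088Profs*6")
print(f"\nparsing p.Ser1088Profs*6: codon {parsed.affected_codon}, "
      f"{parsed.ref_residue}->{parsed.new_residue}, "
      f"{parsed.missense_run} altered codons then a stop")
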