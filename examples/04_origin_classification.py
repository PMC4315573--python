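"""Classify inheritance origin from parental genotypes.

The interesting case: a variant heterozygous in several affected siblings but
absent from both parents' DNA. Independent de novo events at the same site in
three children are essentially impossible, so the parsimonious explanation is
a mutation carried in a fraction of one parent's germ cells — germline
mosaicism. With a carrier parent the call is ordinary inheritance; with a
missing parental genotype it stays ambiguous.
"""

from kindredvar import VariantRecord, classify_origin
from kindredvar.family import ORIGIN_LABELS
from kindredvar.vcf_io import (
    GenotypeCall, Pedigree, PedigreeMember, Role, Sex,
)

HOM_REF, HET, MISSING = GenotypeCall((0, 0)), GenotypeCall((0, 1)), GenotypeCall((None, None))

pedigree = Pedigree(tuple(
    [PedigreeMember(s, Sex.MALE, True, Role.SIBLING, s)
     for s in ("SIB1", "SIB2", "SIB3")]
    + [PedigreeMember("MOTHER", Sex.FEMALE, False, Role.MOTHER, "MOTHER"),
       PedigreeMember("FATHER", Sex.MALE, False, Role.FATHER, "FATHER")]))

scenarios = {
    "three het siblings, both parents hom-ref":
        dict(SIB1=HET, SIB2=HET, SIB3=HET, MOTHER=HOM_REF, FATHER=HOM_REF),
    "one het sibling, mother het":
        dict(SIB1=HET, SIB2=HOM_REF, SIB3=HOM_REF, MOTHER=HET, FATHER=HOM_REF),
    "one het sibling, both parents hom-ref":
        dict(SIB1=HET, SIB2=HOM_REF, SIB3=HOM_REF, MOTHER=HOM_REF, FATHER=HOM_REF),
    "three het siblings, father genotype missing":
        dict(SIB1=HET, SIB2=HET, SIB3=HET, MOTHER=HOM_REF, FATHER=MISSING),
}

for label, genotypes in scenarios.items():
    variant = VariantRecord(chrom="22", pos=100, ref="CA", alt="C",
                            genotypes=dict(genotypes))
    call = classify_origin(variant, pedigree)
    print(f"{label}\n  -> {ORIGIN_LABELS[call.value]}\n")
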