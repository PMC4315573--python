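"""Shared fixtures: toy transcripts, VCF helpers and one simulated family."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest
from Bio.Seq import Seq

from kindredvar.annotation import TranscriptModel
from kindredvar.config import PipelineConfig
from kindredvar.family import run_pipeline
from kindredvar.simulate import SimConfig, simulate
from kindredvar.vcf_io import GenotypeCall, VariantRecord

#: 6-codon toy CDS: Met Ser Arg Met Thr Stop.
TOY_CDS = "ATGAGTCGCATGACTTAA"


def make_variant(chrom="7", pos=1, ref="A", alt="T", genotypes=None, **kw):
    gts = {
        s: GenotypeCall(alleles) if not isinstance(alleles, GenotypeCall) else alleles
        for s, alleles in (genotypes or {}).items()
    }
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         genotypes=gts, **kw)


def single_exon_transcript(cds=TOY_CDS, utr5="GGGGG", utr3="CCCCC",
                           chrom="7", gene="TOY1", strand="+", offset=0):
    """Return (genomic contig sequence, TranscriptModel) for a one-exon gene."""
    sense = utr5 + cds + utr3
    L = len(sense)
    if strand == "+":
        genomic = sense
        cds_lo, cds_hi = len(utr5), len(utr5) + len(cds)
    else:
        genomic = str(Seq(sense).reverse_complement())
        cds_lo, cds_hi = len(utr3), len(utr3) + len(cds)
    model = TranscriptModel(
        transcript_id=f"TX_{gene}", gene=gene, chrom=chrom, strand=strand,
        exons=((offset, offset + L),),
        cds_start=offset + cds_lo, cds_end=offset + cds_hi,
        cds_seq=cds)
    return "N" * 0 + "A" * offset + genomic, model


def three_exon_transcript(chrom="7", gene="TOY3", offset=100):
    """A 3-exon plus-strand transcript with a 18-nt CDS split 9/6/3."""
    utr5, utr3, intron = "GGGGG", "CCCCC", "TTTTTTTTTT"
    c1, c2, c3 = TOY_CDS[:9], TOY_CDS[9:15], TOY_CDS[15:]
    seq = utr5 + c1 + intron + c2 + intron + c3 + utr3
    e1 = (offset, offset + len(utr5) + len(c1))
    e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(c2))
    e3 = (e2[1] + len(intron), e2[1] + len(intron) + len(c3) + len(utr3))
    model = TranscriptModel(
        transcript_id=f"TX_{gene}", gene=gene, chrom=chrom, strand="+",
        exons=(e1, e2, e3),
        cds_start=offset + len(utr5), cds_end=e3[0] + len(c3),
        cds_seq=TOY_CDS)
    return "A" * offset + seq + "A" * 10, model


def write_vcf_text(path: Path, body: str, samples=("S1",), contigs=("22",)):
    """Write a small literal VCF with a minimal valid header."""
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in contigs]
    header += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="AF">',
        '##INFO=<ID=AF_ESP,Number=A,Type=Float,Description="AF">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header) + "\n" + textwrap.dedent(body).strip() + "\n")
    return path


@pytest.fixture(scope="session")
def sim_family(tmp_path_factory):
    """One simulated family (default mosaic plant) plus its pipeline result."""
    root = tmp_path_factory.mktemp("family")
    config = SimConfig(seed=11, n_background_variants=800)
    ref, fam = simulate(config, root / "sim")
    result = run_pipeline(
        PipelineConfig(), list(fam.vcf_paths.values()), fam.ped_path,
        ref.panel_path, ref.gff3_path, ref.fasta_path, root / "out")
    return config, ref, fam, result
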