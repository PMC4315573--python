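"""Transcript loading, splice-site definition, impact classification, panels."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from kindredvar.annotation import (
    HIGH_IMPACT, GenePanel, Impact, bundled_asd_panel, classify_impact,
    is_splice_site, load_gene_panel, load_transcripts,
)
from kindredvar.errors import AnnotationWarning, ConfigurationError

from conftest import TOY_CDS, make_variant, single_exon_transcript, three_exon_transcript


def _write_fasta(path, contigs):
    with path.open("w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


class TestLoadTranscripts:
    BED = ("7\t100\t160\tTX1|TOY\t0\t+\t110\t141\t0\t2\t20,30\t0,30\n")

    def test_bed12_two_exon_gene(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text(self.BED)
        (t,) = load_transcripts(path)
        assert t.gene == "TOY" and t.exons == ((100, 120), (130, 160))
        assert (t.cds_start, t.cds_end) == (110, 141)
        assert t.cds_length == 10 + 11  # CDS split across both exons

    def test_canonical_is_longest_cds_then_smallest_id(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text(
            "7\t0\t60\tTXB|G\t0\t+\t0\t30\t0\t1\t60,\t0,\n"
            "7\t0\t60\tTXC|G\t0\t+\t0\t60\t0\t1\t60,\t0,\n"
            "7\t0\t60\tTXA|G\t0\t+\t0\t60\t0\t1\t60,\t0,\n")
        (t,) = load_transcripts(path)
        assert t.transcript_id == "TXA"  # longest CDS (60), smallest id

    def test_invalid_cds_excluded_from_consequence(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("7\t0\t60\tTX1|G\t0\t+\t0\t31\t0\t1\t60,\t0,\n")
        with pytest.warns(AnnotationWarning, match="not divisible"):
            (t,) = load_transcripts(path)
        assert not t.cds_valid

    def test_minus_strand_cds_is_reverse_complement_of_slice(self, tmp_path):
        genome, model = single_exon_transcript(strand="-", chrom="7")
        fasta = _write_fasta(tmp_path / "r.fa", {"7": genome})
        bed = tmp_path / "t.bed"
        s, e = model.span
        bed.write_text(
            f"7\t{s}\t{e}\tTX_TOY1|TOY1\t0\t-\t{model.cds_start}\t{model.cds_end}"
            f"\t0\t1\t{e - s},\t0,\n")
        (t,) = load_transcripts(bed, reference=fasta)
        manual = str(Seq(genome[model.cds_start:model.cds_end]).reverse_complement())
        assert t.cds_seq == manual == TOY_CDS

    def test_gff3_matches_bed12(self, tmp_path, sim_family):
        _, ref, _, _ = sim_family
        models = load_transcripts(ref.gff3_path, ref.fasta_path)
        assert len(models) == len(ref.transcripts)
        by_id = {t.transcript_id: t for t in ref.transcripts}
        for t in models:
            expect = by_id[t.transcript_id]
            assert t.exons == expect.exons
            assert (t.cds_start, t.cds_end) == (expect.cds_start, expect.cds_end)
            assert t.cds_seq == expect.cds_seq


class TestSpliceSite:
    def test_exhaustive_scan_marks_exactly_two_intronic_bases_per_side(self):
        genome, t = three_exon_transcript()
        span = t.span
        marked = {
            pos for pos in range(span[0] - 5, span[1] + 5)
            if is_splice_site(make_variant("7", pos + 1, genome[pos], "A"
                                           if genome[pos] != "A" else "T"), t)
        }
        expected = set()
        for i, (s, e) in enumerate(t.exons):
            if i < len(t.exons) - 1:
                expected.update((e, e + 1))
            if i > 0:
                expected.update((s - 2, s - 1))
        assert marked == expected
        assert len(marked) == 4 * (len(t.exons) - 1)
        # never inside an exon, and nothing at the terminal transcript edges
        for s, e in t.exons:
            assert not marked & set(range(s, e))
        assert span[0] - 1 not in marked and span[1] not in marked

    def test_deletion_spanning_into_splice_window(self):
        _, t = three_exon_transcript()
        e1_end = t.exons[0][1]
        # 3-bp ref span starting 1 base before the intron touches position e+1
        assert is_splice_site(make_variant("7", e1_end - 1, "AAA", "A"), t)
        # SNV at exon_end + 3 (1-based pos e+3) is outside the 2-base window
        assert not is_splice_site(make_variant("7", e1_end + 3, "A", "T"), t)

    def test_other_chromosome_is_never_splice(self):
        _, t = three_exon_transcript()
        assert not is_splice_site(make_variant("8", t.exons[0][1] + 1, "A", "T"), t)


class TestClassifyImpact:
    @pytest.fixture()
    def toy(self):
        return single_exon_transcript()

    def test_frameshift_and_inframe_deletions(self, toy):
        genome, t = toy
        cds0 = t.cds_start
        one_bp = make_variant("7", cds0 + 4, genome[cds0 + 3: cds0 + 5], genome[cds0 + 3])
        call = classify_impact(one_bp, t)
        assert call.value is Impact.FRAMESHIFT and call.high_impact
        three_bp = make_variant("7", cds0 + 4, genome[cds0 + 3: cds0 + 7], genome[cds0 + 3])
        call = classify_impact(three_bp, t)
        assert call.value is Impact.INFRAME_INDEL and not call.high_impact

    def test_snv_classes_by_codon_translation(self, toy):
        genome, t = toy
        cds0 = t.cds_start
        # c.7 C>T: CGC (Arg) -> TGC (Cys)
        assert classify_impact(
            make_variant("7", cds0 + 7, "C", "T"), t).value is Impact.MISSENSE
        # c.9 C>A: CGC -> CGA, still Arg
        assert classify_impact(
            make_variant("7", cds0 + 9, "C", "A"), t).value is Impact.SYNONYMOUS

    def test_nonsense_snv(self):
        cds = "ATGTGGTGCTAA"  # Met Trp Cys Stop
        genome, t = single_exon_transcript(cds=cds)
        cds0 = t.cds_start
        # c.4 T>T no; TGG (Trp) -> TGA (stop) via c.6 G>A
        call = classify_impact(make_variant("7", cds0 + 6, "G", "A"), t)
        assert call.value is Impact.NONSENSE and call.high_impact

    def test_noncoding_outside_cds_and_splice(self, toy):
        genome, t = toy
        assert classify_impact(make_variant("7", 2, genome[1], "A"
                                            if genome[1] != "A" else "T"), t
                               ).value is Impact.NONCODING

    def test_invalid_cds_transcript_flagged_low_confidence(self, toy):
        genome, t = toy
        t.cds_valid = False
        cds0 = t.cds_start
        call = classify_impact(make_variant("7", cds0 + 7, "C", "T"), t)
        assert call.low_confidence
        assert call.value not in (Impact.MISSENSE, Impact.NONSENSE, Impact.SYNONYMOUS)
        indel = make_variant("7", cds0 + 4, genome[cds0 + 3: cds0 + 5], genome[cds0 + 3])
        assert classify_impact(indel, t).value is Impact.FRAMESHIFT

    def test_high_impact_is_exactly_truncating_plus_splice(self):
        assert HIGH_IMPACT == {Impact.FRAMESHIFT, Impact.NONSENSE, Impact.SPLICE_SITE}


def _oracle_translate(seq):
    seq = seq[: len(seq) // 3 * 3]
    prot = str(Seq(seq).translate()) if seq else ""
    cut = prot.find("*")
    return prot if cut < 0 else prot[: cut + 1]


def _oracle_classify(genome, cds_lo, cds_hi, strand, pos, ref, alt):
    """Brute force: rebuild the mutated CDS, translate, diff proteins."""
    s0, e0 = pos - 1, pos - 1 + len(ref)
    if not (e0 > cds_lo and s0 < cds_hi):
        return Impact.NONCODING  # single-exon toy: no splice sites exist
    change = len(alt) - len(ref)
    if change:
        return Impact.FRAMESHIFT if change % 3 else Impact.INFRAME_INDEL
    mutated = genome[:s0] + alt + genome[e0:]
    wt_cds, mut_cds = genome[cds_lo:cds_hi], mutated[cds_lo:cds_hi]
    if strand == "-":
        wt_cds = str(Seq(wt_cds).reverse_complement())
        mut_cds = str(Seq(mut_cds).reverse_complement())
    wt, mut = _oracle_translate(wt_cds), _oracle_translate(mut_cds)
    if wt == mut:
        return Impact.SYNONYMOUS
    i = next(i for i in range(min(len(wt), len(mut))) if wt[i] != mut[i])
    return Impact.NONSENSE if mut[i] == "*" else Impact.MISSENSE


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classify_impact_matches_rebuild_and_translate_oracle(strand):
    """Every SNV and short deletion of a randomized toy gene, vs brute force."""
    rng = np.random.default_rng(2024)
    codons = [c for c in ("".join(p) for p in
                          __import__("itertools").product("ACGT", repeat=3))
              if c not in ("TAA", "TAG", "TGA")]
    cds = "ATG" + "".join(rng.choice(codons) for _ in range(40)) + "TAA"
    genome, t = single_exon_transcript(cds=cds, utr5="GATTACA", utr3="TTTACCA",
                                       strand=strand)
    mismatches = []
    for pos0 in range(len(genome)):
        for alt in "ACGT":
            if alt == genome[pos0]:
                continue
            v = make_variant("7", pos0 + 1, genome[pos0], alt)
            got = classify_impact(v, t).value
            want = _oracle_classify(genome, t.cds_start, t.cds_end, strand,
                                    v.pos, v.ref, v.alt)
            if got != want:
                mismatches.append((pos0, alt, got, want))
    for pos0 in range(0, len(genome) - 6, 3):
        for dlen in (1, 2, 3, 4):
            v = make_variant("7", pos0 + 1, genome[pos0: pos0 + 1 + dlen],
                             genome[pos0])
            got = classify_impact(v, t).value
            want = _oracle_classify(genome, t.cds_start, t.cds_end, strand,
                                    v.pos, v.ref, v.alt)
            if got != want:
                mismatches.append((pos0, f"del{dlen}", got, want))
    assert not mismatches


class TestGenePanel:
    def test_dedup_and_casefold(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("SHANK3\nNLGN3\nshank3\n# comment\n\n")
        panel = load_gene_panel(path)
        assert len(panel) == 2
        assert "SHANK3" in panel and "Shank3" in panel and "NLGN3" in panel
        assert "NRXN1" not in panel and None not in panel

    def test_bundled_panel_has_182_symbols(self):
        panel = bundled_asd_panel()
        assert len(panel) == 182
        assert "SHANK3" in panel

    def test_empty_panel_is_configuration_error(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("# nothing here\n")
        with pytest.raises(ConfigurationError):
            load_gene_panel(path)
        with pytest.raises(ConfigurationError):
            GenePanel(frozenset())
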