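"""Reference transcript models, functional impact classes and gene panels.

A single canonical transcript is kept per gene (longest CDS; ties broken by
lexicographically smallest transcript id), which keeps the effect model
deterministic and testable. Splice sites follow the strict intronic
definition used throughout this pipeline: the 2 intronic bases immediately
after an exon end or immediately before an exon start, measured only at
internal exon boundaries — never inside exons and never at transcript ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .errors import AnnotationWarning, ConfigurationError, ReferenceMismatchError
from .vcf_io import VariantRecord, normalize_chrom


class Impact(str, Enum):
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SPLICE_SITE = "splice_site"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: Classes counted as high impact: premature truncation or splice disruption.
HIGH_IMPACT = frozenset({Impact.FRAMESHIFT, Impact.NONSENSE, Impact.SPLICE_SITE})

#: Classes lying inside the coding sequence (used by the funnel's coding row).
CODING_CLASSES = frozenset({
    Impact.FRAMESHIFT, Impact.NONSENSE, Impact.MISSENSE,
    Impact.INFRAME_INDEL, Impact.SYNONYMOUS,
})


@dataclass(frozen=True)
class ImpactCall:
    """A functional-impact classification for one variant on one transcript."""

    value: Impact
    low_confidence: bool = False

    @property
    def high_impact(self) -> bool:
        return self.value in HIGH_IMPACT


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one canonical transcript.

    All coordinates are 0-based half-open genomic intervals; ``cds_seq`` is
    the spliced coding sequence in coding orientation (reverse-complemented
    for minus-strand transcripts) when a reference was available.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    cds_seq: Optional[str] = None
    cds_valid: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"{self.transcript_id}: strand must be + or -")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"{self.transcript_id}: exons overlap or are unsorted")
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ConfigurationError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def overlaps_cds(self, start0: int, end0: int) -> bool:
        return any(start0 < e and end0 > s for s, e in self.cds_intervals())

    def genomic_to_cds(self, pos0: int) -> Optional[int]:
        """Coding-sequence offset (0-based, in coding orientation) of a base."""
        acc = 0
        plus_offset = None
        for s, e in self.cds_intervals():
            if s <= pos0 < e:
                plus_offset = acc + (pos0 - s)
                break
            acc += e - s
        if plus_offset is None:
            return None
        if self.strand == "+":
            return plus_offset
        return self.cds_length - 1 - plus_offset

    def splice_positions(self) -> set[int]:
        """0-based genomic positions of the 2+2 intronic bases per internal boundary."""
        pos: set[int] = set()
        last = len(self.exons) - 1
        for i, (s, e) in enumerate(self.exons):
            if i < last:  # intron follows: 2 bases after the exon end
                pos.update((e, e + 1))
            if i > 0:  # intron precedes: 2 bases before the exon start
                pos.update((s - 2, s - 1))
        return pos

    def extract_cds(self, fasta: Fasta) -> str:
        seq = "".join(str(fasta[self.chrom][s:e]) for s, e in self.cds_intervals())
        seq = seq.upper()
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq


def is_splice_site(variant: VariantRecord, transcript: TranscriptModel) -> bool:
    """True iff the variant's reference span touches a 2-base intronic splice window."""
    if normalize_chrom(variant.chrom) != normalize_chrom(transcript.chrom):
        return False
    start0 = variant.pos - 1
    end0 = start0 + len(variant.ref)
    return any(start0 <= p < end0 for p in transcript.splice_positions())


def _translate_codons(seq: str) -> str:
    seq = seq[: len(seq) // 3 * 3]
    return str(Seq(seq).translate()) if seq else ""


def classify_impact(variant: VariantRecord, transcript: TranscriptModel) -> ImpactCall:
    """Classify a normalised variant against a single canonical transcript.

    Coding-region classification takes precedence; outside the CDS the splice
    test runs before falling through to NONCODING. An indel overlapping the
    CDS is classified purely by its length change (frame arithmetic); an SNV
    is classified by translating its codon. Transcripts with an invalid CDS
    (length not divisible by 3) yield frame-arithmetic-only calls flagged
    low-confidence.
    """
    start0 = variant.pos - 1
    end0 = start0 + len(variant.ref)
    if transcript.overlaps_cds(start0, end0):
        change = variant.length_change
        if change != 0:
            value = Impact.FRAMESHIFT if change % 3 else Impact.INFRAME_INDEL
            return ImpactCall(value, low_confidence=not transcript.cds_valid)
        if not transcript.cds_valid or transcript.cds_seq is None:
            # length arithmetic only: in-frame coding change, no translation call
            return ImpactCall(Impact.INFRAME_INDEL, low_confidence=True)
        return _classify_substitution(variant, transcript)
    if is_splice_site(variant, transcript):
        return ImpactCall(Impact.SPLICE_SITE)
    return ImpactCall(Impact.NONCODING)


def _classify_substitution(variant: VariantRecord, transcript: TranscriptModel) -> ImpactCall:
    cds = transcript.cds_seq
    assert cds is not None
    start0 = variant.pos - 1
    if transcript.strand == "+":
        off = transcript.genomic_to_cds(start0)
        ref_c, alt_c = variant.ref, variant.alt
    else:
        off = transcript.genomic_to_cds(start0 + len(variant.ref) - 1)
        ref_c = str(Seq(variant.ref).reverse_complement())
        alt_c = str(Seq(variant.alt).reverse_complement())
    if off is None or off + len(ref_c) > len(cds):
        # substitution straddling a CDS edge: no translation call possible
        return ImpactCall(Impact.INFRAME_INDEL, low_confidence=True)
    if cds[off:off + len(ref_c)] != ref_c:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} REF {variant.ref!r} does not match "
            f"the CDS of {transcript.transcript_id}")
    codon_start = off // 3 * 3
    codon_end = -(-(off + len(ref_c)) // 3) * 3
    wt_pep = _translate_codons(cds[codon_start:codon_end])
    mut_region = cds[codon_start:off] + alt_c + cds[off + len(ref_c):codon_end]
    mut_pep = _translate_codons(mut_region)
    if "*" in mut_pep and "*" not in wt_pep:
        return ImpactCall(Impact.NONSENSE)
    if mut_pep != wt_pep:
        return ImpactCall(Impact.MISSENSE)
    return ImpactCall(Impact.SYNONYMOUS)


# ---------------------------------------------------------------------------
# Transcript loading
# ---------------------------------------------------------------------------

def _from_bed12(path: Path) -> list[TranscriptModel]:
    """Parse BED12; the name field may be 'transcript_id|gene_symbol'."""
    out = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ConfigurationError(f"{path}: BED12 line with {len(cols)} columns: {raw!r}")
        chrom, start = cols[0], int(cols[1])
        name, strand = cols[3], cols[5]
        thick_start, thick_end = int(cols[6]), int(cols[7])
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        starts = [int(x) for x in cols[11].rstrip(",").split(",")]
        exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
        tid, _, gene = name.partition("|")
        out.append(TranscriptModel(
            transcript_id=tid, gene=gene or tid, chrom=chrom, strand=strand,
            exons=exons, cds_start=thick_start, cds_end=thick_end))
    return out


def _from_gff3(path: Path) -> list[TranscriptModel]:
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons or not cds:
            continue
        gene = None
        for key in ("gene_name", "gene", "Name"):
            if key in mrna.attributes:
                gene = mrna.attributes[key][0]
                break
        if gene is None:
            for parent in db.parents(mrna, featuretype="gene"):
                gene = parent.attributes.get("Name", [parent.id])[0]
                break
        out.append(TranscriptModel(
            transcript_id=mrna.id, gene=gene or mrna.id, chrom=mrna.seqid,
            strand=mrna.strand, exons=tuple(exons),
            cds_start=min(s for s, _ in cds), cds_end=max(e for _, e in cds)))
    return out


def load_transcripts(path, reference=None) -> list[TranscriptModel]:
    """Load transcripts (BED12 or GFF3) and keep one canonical model per gene.

    Canonical = longest CDS, ties broken by smallest transcript id. A CDS
    whose spliced length is not divisible by 3 triggers an AnnotationWarning
    and is excluded from consequence prediction (``cds_valid=False``) while
    remaining available for splice-site classification. With a ``reference``
    FASTA the coding sequence of each valid transcript is attached.
    """
    path = Path(path)
    raw = _from_bed12(path) if path.suffix.lower() == ".bed" else _from_gff3(path)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in raw:
        by_gene.setdefault(t.gene, []).append(t)
    chosen = []
    for gene in sorted(by_gene):
        models = by_gene[gene]
        best = min(models, key=lambda t: (-t.cds_length, t.transcript_id))
        if best.cds_length % 3 != 0:
            warnings.warn(
                f"{best.transcript_id} ({gene}): CDS length {best.cds_length} not "
                "divisible by 3; excluded from consequence prediction",
                AnnotationWarning, stacklevel=2)
            best.cds_valid = False
        chosen.append(best)
    if reference is not None:
        fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
        for t in chosen:
            if t.cds_valid:
                t.cds_seq = t.extract_cds(fasta)
    chosen.sort(key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    return chosen


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePanel:
    """A named, case-folded set of gene symbols."""

    symbols: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ConfigurationError(f"gene panel {self.name!r} is empty")

    def __contains__(self, symbol: Optional[str]) -> bool:
        return symbol is not None and symbol.casefold() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], name: str = "panel") -> "GenePanel":
        return cls(frozenset(s.casefold() for s in symbols if s.strip()), name)


def load_gene_panel(path, name: Optional[str] = None) -> GenePanel:
    """Load a newline-delimited gene panel ('#' comments allowed, case-folded)."""
    path = Path(path)
    symbols = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise ConfigurationError(f"{path}: gene panel file is empty")
    return GenePanel.from_symbols(symbols, name or path.stem)


def bundled_asd_panel() -> GenePanel:
    """The packaged 182-symbol ASD gene panel.

    This is a synthetic stand-in assembled from well-established ASD-associated
    gene symbols (SHANK3 included); it is not a redistribution of any published
    supplementary table.
    """
    from importlib.resources import files

    panel_path = files("kindredvar") / "data" / "asd_panel_182.synthetic.txt"
    symbols = [
        line.strip() for line in panel_path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GenePanel.from_symbols(symbols, "asd_panel_182")
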