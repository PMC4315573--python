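"""Protein-level consequence prediction and HGVS c./p. nomenclature.

Supports substitutions, deletions and insertions within the CDS of a single
canonical transcript. Frameshift notation follows the HGVS convention
``p.<Ref3><pos><New3>fs*<N>``: N is the 1-based position of the new stop
codon counting the first changed residue as 1, so a frameshift runs through
N−1 altered (missense) residues before terminating. Coding-DNA positions are
3'-most shifted within the CDS as HGVS requires, even though the VCF
representation of the same variant is left-aligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .annotation import TranscriptModel
from .errors import HgvsParseError, ReferenceMismatchError, TranslationError
from .vcf_io import VariantRecord

_VALID_AA3 = frozenset(
    seq3(a) for a in "ACDEFGHIKLMNPQRSTVWY"
) | {"Ter"}


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """HGVS c. and p. description of one coding variant."""

    hgvs_c: str
    hgvs_p: str
    affected_codon: int          # 1-based codon index of the first changed residue
    ref_residue: str             # three-letter code
    new_residue: str             # three-letter code, or "*" for a direct stop
    stop_offset: Optional[int]   # N in fs*N; None for non-frameshift or fs*?
    kind: str                    # "frameshift" | "nonsense" | "missense"
    no_stop: bool = False        # frameshift reads through the CDS end (fs*?)

    @property
    def missense_run(self) -> Optional[int]:
        """Number of altered residues before the premature stop (fs*N → N−1)."""
        return None if self.stop_offset is None else self.stop_offset - 1


def apply_variant_to_cds(cds: str, offset: int, ref: str, alt: str) -> str:
    """Apply an edit (0-based CDS offset) to a coding sequence."""
    if cds[offset:offset + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"CDS has {cds[offset:offset + len(ref)]!r} at offset {offset}, "
            f"variant states REF {ref!r}")
    return cds[:offset] + alt + cds[offset + len(ref):]


def translate(cds: str) -> str:
    """Translate with the standard code, stopping at (and including) the first stop.

    A trailing partial codon is ignored; the empty sequence translates to "".
    """
    seq = cds.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise TranslationError(f"ambiguous or invalid bases in CDS: {sorted(bad)}")
    seq = seq[: len(seq) // 3 * 3]
    if not seq:
        return ""
    prot = str(Seq(seq).translate())
    cut = prot.find("*")
    return prot if cut < 0 else prot[: cut + 1]


def _cds_space_edit(transcript: TranscriptModel, variant: VariantRecord
                    ) -> tuple[int, str, str]:
    """Map a genomic variant into (offset, ref, alt) in coding orientation."""
    start0 = variant.pos - 1
    positions = range(start0, start0 + len(variant.ref))
    offsets = [transcript.genomic_to_cds(p) for p in positions]
    if variant.ref and any(o is None for o in offsets):
        raise ValueError(
            f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} is not "
            f"fully contained in the CDS of {transcript.transcript_id}")
    if transcript.strand == "+":
        off = offsets[0] if offsets else transcript.genomic_to_cds(start0)
        ref_c, alt_c = variant.ref, variant.alt
    else:
        off = offsets[-1] if offsets else transcript.genomic_to_cds(start0)
        ref_c = str(Seq(variant.ref).reverse_complement())
        alt_c = str(Seq(variant.alt).reverse_complement())
    if off is None:
        raise ValueError("variant position not in CDS")
    return off, ref_c, alt_c


def _minimal_edit(off: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared prefix then suffix down to the minimal ref/alt pair."""
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        off += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return off, ref, alt


def _shift_3prime(cds: str, off: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Roll a pure insertion/deletion to its 3'-most equivalent position."""
    if ref and not alt:  # deletion
        while off + len(ref) < len(cds) and cds[off] == cds[off + len(ref)]:
            ref = ref[1:] + cds[off + len(ref)]
            off += 1
    elif alt and not ref:  # insertion
        while off < len(cds) and cds[off] == alt[0]:
            alt = alt[1:] + alt[0]
            off += 1
    return off, ref, alt


def _format_hgvs_c(off: int, ref: str, alt: str) -> str:
    if ref and not alt:
        start, end = off + 1, off + len(ref)
        return f"c.{start}del" if start == end else f"c.{start}_{end}del"
    if alt and not ref:
        return f"c.{off}_{off + 1}ins{alt}"
    if len(ref) == 1 and len(alt) == 1:
        return f"c.{off + 1}{ref}>{alt}"
    return f"c.{off + 1}_{off + len(ref)}delins{alt}"


def hgvs_consequence(
    transcript: TranscriptModel,
    variant: VariantRecord,
    reference=None,
) -> ConsequenceAnnotation:
    """HGVS c./p. annotation for a coding frameshift, nonsense or missense variant.

    The protein description is derived by diffing the wild-type translation
    against the translation of the edited CDS; the first differing codon gives
    the affected residue and, for frameshifts, the offset of the first stop in
    the shifted frame. In-frame events are out of contract and raise ValueError.
    """
    if not transcript.cds_valid:
        raise ValueError(f"{transcript.transcript_id}: CDS invalid, no consequence call")
    cds = transcript.cds_seq
    if cds is None:
        if reference is None:
            raise ValueError(f"{transcript.transcript_id}: no CDS sequence attached")
        from pyfaidx import Fasta

        fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
        cds = transcript.extract_cds(fasta)

    off, ref_c, alt_c = _cds_space_edit(transcript, variant)
    if cds[off:off + len(ref_c)] != ref_c:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: REF disagrees with the CDS of "
            f"{transcript.transcript_id}")
    off, ref_m, alt_m = _minimal_edit(off, ref_c, alt_c)
    if len(ref_m) == len(alt_m) == 0:
        raise ValueError("variant reduces to the identity after trimming")
    frameshift = (len(alt_m) - len(ref_m)) % 3 != 0
    if not frameshift and len(ref_m) != len(alt_m):
        raise ValueError("in-frame indels are out of contract for hgvs_consequence")

    off_s, ref_s, alt_s = _shift_3prime(cds, off, ref_m, alt_m)
    hgvs_c = _format_hgvs_c(off_s, ref_s, alt_s)

    wt = translate(cds)
    mut = translate(apply_variant_to_cds(cds, off, ref_m, alt_m))
    i0 = next(
        (i for i, (a, b) in enumerate(zip(wt, mut)) if a != b),
        min(len(wt), len(mut)),
    )
    if i0 >= len(wt):
        raise ValueError("edit does not change the protein before the stop codon")
    ref_res = seq3(wt[i0]) if wt[i0] != "*" else "Ter"
    new_aa = mut[i0] if i0 < len(mut) else None

    if frameshift:
        if new_aa == "*":
            # the first altered codon is itself a stop: nonsense-style notation
            return ConsequenceAnnotation(
                hgvs_c=hgvs_c, hgvs_p=f"p.{ref_res}{i0 + 1}*",
                affected_codon=i0 + 1, ref_residue=ref_res, new_residue="*",
                stop_offset=1, kind="frameshift")
        stop_idx = mut.find("*", i0)
        new_res = seq3(new_aa) if new_aa else "Ter"
        if stop_idx < 0 or new_aa is None:
            return ConsequenceAnnotation(
                hgvs_c=hgvs_c, hgvs_p=f"p.{ref_res}{i0 + 1}{new_res}fs*?",
                affected_codon=i0 + 1, ref_residue=ref_res, new_residue=new_res,
                stop_offset=None, kind="frameshift", no_stop=True)
        stop_offset = stop_idx - i0 + 1
        return ConsequenceAnnotation(
            hgvs_c=hgvs_c, hgvs_p=f"p.{ref_res}{i0 + 1}{new_res}fs*{stop_offset}",
            affected_codon=i0 + 1, ref_residue=ref_res, new_residue=new_res,
            stop_offset=stop_offset, kind="frameshift")

    if new_aa == "*":
        return ConsequenceAnnotation(
            hgvs_c=hgvs_c, hgvs_p=f"p.{ref_res}{i0 + 1}*",
            affected_codon=i0 + 1, ref_residue=ref_res, new_residue="*",
            stop_offset=None, kind="nonsense")
    new_res = seq3(new_aa)
    return ConsequenceAnnotation(
        hgvs_c=hgvs_c, hgvs_p=f"p.{ref_res}{i0 + 1}{new_res}",
        affected_codon=i0 + 1, ref_residue=ref_res, new_residue=new_res,
        stop_offset=None, kind="missense")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsedProteinChange:
    affected_codon: int
    ref_residue: str
    new_residue: str             # "*" for nonsense
    stop_offset: Optional[int]   # None for non-frameshift or fs*?
    kind: str

    @property
    def missense_run(self) -> Optional[int]:
        return None if self.stop_offset is None else self.stop_offset - 1


_FS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs\*(\d+|\?)$")
_NONSENSE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)(\*|Ter)$")
_MISSENSE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def _check_aa(code: str, notation: str) -> str:
    if code not in _VALID_AA3:
        raise HgvsParseError(f"{notation!r}: unknown amino-acid code {code!r}")
    return code


def parse_hgvs_p(notation: str) -> ParsedProteinChange:
    """Parse missense / nonsense / frameshift protein HGVS strings.

    ``p.Ser1088Profs*6`` → codon 1088, Ser→Pro, stop offset 6 (so 5 altered
    residues precede the premature stop).
    """
    m = _FS_RE.match(notation)
    if m:
        ref3, pos, new3, stop = m.groups()
        return ParsedProteinChange(
            affected_codon=int(pos),
            ref_residue=_check_aa(ref3, notation),
            new_residue=_check_aa(new3, notation),
            stop_offset=None if stop == "?" else int(stop),
            kind="frameshift")
    m = _NONSENSE_RE.match(notation)
    if m:
        ref3, pos, _ = m.groups()
        return ParsedProteinChange(
            affected_codon=int(pos), ref_residue=_check_aa(ref3, notation),
            new_residue="*", stop_offset=None, kind="nonsense")
    m = _MISSENSE_RE.match(notation)
    if m:
        ref3, pos, new3 = m.groups()
        return ParsedProteinChange(
            affected_codon=int(pos), ref_residue=_check_aa(ref3, notation),
            new_residue=_check_aa(new3, notation),
            stop_offset=None, kind="missense")
    raise HgvsParseError(f"unsupported protein HGVS notation: {notation!r}")
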