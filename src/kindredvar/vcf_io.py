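"""Reading, normalising and writing variant and pedigree data.

Coordinates are 1-based inclusive at the interface (VCF convention); interval
arithmetic elsewhere in the package uses 0-based half-open coordinates.

VCF reading and writing go through :mod:`pysam`; multi-allelic sites are split
into one biallelic record per ALT allele, and indels are trimmed and (when a
reference is supplied) left-aligned. Note that left-alignment is the VCF
convention only — the HGVS consequence module independently applies 3'-most
shifting in coding-sequence space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, TYPE_CHECKING

import pysam

from .errors import ConfigurationError, DataError, PedigreeError, VcfFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .consequence import ConsequenceAnnotation
    from .family import OriginCall
    from .prioritization import CandidateSet

#: Default mapping from population-frequency source name to VCF INFO key.
#: The sources mirror the annotation databases commonly used for rarity
#: filtering (1000 Genomes Project, NHLBI Exome Sequencing Project).
DEFAULT_FREQUENCY_KEYS: dict[str, str] = {"1000G": "AF_1000G", "ESP": "AF_ESP"}

#: Default INFO key carrying the annotated gene symbol.
DEFAULT_GENE_KEY = "GENE"

#: Fixed header of the candidate TSV report.
CANDIDATE_TSV_HEADER = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "impact",
    "model",
    "scope",
    "hgvs_c",
    "hgvs_p",
    "origin_call",
)


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class FilterStatus(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    UNFILTERED = "unfiltered"


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype for one sample at one biallelic site.

    ``alleles`` is an unordered pair over {0 (ref), 1 (alt), None (missing)}.
    Zygosity is derived, never stored: a pair containing any missing allele is
    ``MISSING`` and is never counted as hom_ref (absence of evidence).
    """

    alleles: tuple[Optional[int], Optional[int]]

    @property
    def zygosity(self) -> Zygosity:
        a, b = self.alleles
        if a is None or b is None:
            return Zygosity.MISSING
        n_alt = (a != 0) + (b != 0)
        return (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[n_alt]

    @property
    def is_carrier(self) -> bool:
        return self.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)

    def gt_string(self) -> str:
        return "/".join("." if a is None else str(a) for a in sorted(
            self.alleles, key=lambda x: (x is None, x)))


HOM_REF_CALL = GenotypeCall((0, 0))
HET_CALL = GenotypeCall((0, 1))
HOM_ALT_CALL = GenotypeCall((1, 1))
MISSING_CALL = GenotypeCall((None, None))


def normalize_chrom(name: str) -> str:
    """Map 'chrX'/'X' style names onto a bare canonical form."""
    n = name[3:] if name.lower().startswith("chr") else name
    return "MT" if n.upper() in ("M", "MT") else n


_CHROM_RANK = {"X": 100, "Y": 101, "MT": 102}


def chrom_sort_key(name: str) -> tuple[int, str]:
    n = normalize_chrom(name)
    if n.isdigit():
        return (int(n), "")
    return (_CHROM_RANK.get(n.upper(), 200), n)


@dataclass
class VariantRecord:
    """One normalised biallelic variant with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    filter_status: FilterStatus = FilterStatus.UNFILTERED
    rsid: Optional[str] = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    gene: Optional[str] = None
    impact: Optional["object"] = None  # ImpactCall, set by the annotation stage

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for src, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise DataError(f"frequency {f} from {src!r} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-sample intersection."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def zygosity(self, sample: str) -> Zygosity:
        call = self.genotypes.get(sample)
        return call.zygosity if call is not None else Zygosity.MISSING

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    base_at: Optional[Callable[[str, int], str]] = None,
) -> tuple[int, str, str]:
    """Trim shared flanking bases and left-align indels.

    ``base_at(chrom, pos)`` returns the 1-based reference base; without it only
    trimming is performed. The operation is idempotent.
    """
    # right-trim / left-align (classic vt-normalize loop)
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (
            ref and alt and ref[-1] == alt[-1]
            and base_at is not None and pos > 1
        ):
            prev = base_at(chrom, pos - 1).upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    # left-trim shared leading bases (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _filter_status(rec: "pysam.VariantRecord") -> FilterStatus:
    keys = list(rec.filter.keys())
    if not keys:
        return FilterStatus.UNFILTERED
    if keys == ["PASS"]:
        return FilterStatus.PASS
    return FilterStatus.FAIL


def _per_allele(value, alt_index: int, n_alts: int):
    """Pick the value for one ALT from a Number=A (or scalar) INFO field."""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if value else None
    return value


def vcf_sample_ids(path) -> list[str]:
    """Sample columns declared in a VCF header."""
    with pysam.VariantFile(str(path)) as vf:
        return list(vf.header.samples)


def read_vcf(
    path,
    sample_filter: Optional[set[str]] = None,
    *,
    frequency_keys: Optional[Mapping[str, str]] = None,
    gene_key: str = DEFAULT_GENE_KEY,
    base_at: Optional[Callable[[str, int], str]] = None,
) -> list[VariantRecord]:
    """Read a VCF v4.x file into normalised :class:`VariantRecord` objects.

    Multi-allelic sites are emitted as one record per ALT allele, with GT
    alleles mapped onto {0, 1, missing} (other ALTs collapse to 0, the
    convention used by ``bcftools norm``). Symbolic and spanning-deletion
    ALT alleles are skipped.
    """
    freq_keys = dict(DEFAULT_FREQUENCY_KEYS if frequency_keys is None else frequency_keys)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"{path}: cannot open VCF ({exc})") from exc

    with vf:
        samples = list(vf.header.samples)
        if sample_filter is not None:
            missing = set(sample_filter) - set(samples)
            if missing:
                raise ConfigurationError(
                    f"{path}: samples not present in VCF: {sorted(missing)}")
            samples = [s for s in samples if s in sample_filter]

        records: list[VariantRecord] = []
        line_no = 0
        try:
            for rec in vf:
                line_no += 1
                alts = rec.alts or ()
                status = _filter_status(rec)
                for ai, alt in enumerate(alts):
                    if alt is None or alt == "*" or alt.startswith("<"):
                        continue
                    genotypes = {}
                    for s in samples:
                        gt = rec.samples[s].get("GT", (None, None))
                        if gt is None:
                            gt = (None, None)
                        mapped = tuple(
                            None if a is None else (1 if a == ai + 1 else 0)
                            for a in gt
                        )
                        if len(mapped) == 1:  # haploid call, e.g. male X
                            mapped = (mapped[0], mapped[0])
                        genotypes[s] = GenotypeCall(mapped)  # type: ignore[arg-type]
                    freqs = {}
                    for src, key in freq_keys.items():
                        if key in rec.info:
                            val = _per_allele(rec.info[key], ai, len(alts))
                            if val is not None:
                                freqs[src] = round(float(val), 6)
                    gene = None
                    if gene_key in rec.info:
                        g = _per_allele(rec.info[gene_key], ai, len(alts))
                        gene = str(g) if g is not None else None
                    pos, ref, alt_n = normalize_variant(
                        rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), base_at)
                    records.append(VariantRecord(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        filter_status=status,
                        rsid=rec.id,
                        pop_freqs=freqs,
                        genotypes=genotypes,
                        gene=gene,
                    ))
        except (ValueError, OSError) as exc:
            raise VcfFormatError(
                f"{path}: malformed VCF near record {line_no + 1} ({exc})") from exc
    return records


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Role(str, Enum):
    SIBLING = "sibling"
    MOTHER = "mother"
    FATHER = "father"


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    sex: Sex
    affected: bool
    role: Role
    sample_id: Optional[str] = None


@dataclass
class Pedigree:
    """A nuclear family: up to two parents and one or more siblings."""

    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        roles = Counter(m.role for m in self.members)
        if roles[Role.MOTHER] > 1 or roles[Role.FATHER] > 1:
            raise PedigreeError("more than one mother or father")
        if not any(m.affected and m.role is Role.SIBLING for m in self.members):
            raise PedigreeError("pedigree has no affected sibling")

    def _by_role(self, role: Role) -> Optional[PedigreeMember]:
        for m in self.members:
            if m.role is role:
                return m
        return None

    @property
    def mother(self) -> Optional[PedigreeMember]:
        return self._by_role(Role.MOTHER)

    @property
    def father(self) -> Optional[PedigreeMember]:
        return self._by_role(Role.FATHER)

    @property
    def parents(self) -> list[PedigreeMember]:
        return [p for p in (self.mother, self.father) if p is not None]

    @property
    def affected_siblings(self) -> list[PedigreeMember]:
        return [m for m in self.members
                if m.role is Role.SIBLING and m.affected]

    def sample_of(self, member_id: str) -> Optional[str]:
        for m in self.members:
            if m.member_id == member_id:
                return m.sample_id
        return None


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


def read_pedigree(path) -> Pedigree:
    """Parse a 6-column PED file (FID IID PAT MAT SEX PHENO).

    The sample id bound to each member defaults to the individual id; roles are
    inferred from the parent-id columns, affected status from phenotype 2.
    """
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"{path}: expected 6 PED columns, got {len(cols)}: {raw!r}")
        rows.append(cols[:6])
    if not rows:
        raise PedigreeError(f"{path}: empty pedigree")

    ids = {r[1] for r in rows}
    fathers = {r[2] for r in rows if r[2] != "0"}
    mothers = {r[3] for r in rows if r[3] != "0"}
    for pid in (fathers | mothers) - ids:
        raise PedigreeError(f"{path}: parent id {pid!r} has no row of its own")
    if len(fathers) > 1 or len(mothers) > 1:
        raise PedigreeError(f"{path}: more than one father or mother referenced")

    members = []
    for fid, iid, pat, mat, sex, pheno in rows:
        if iid in fathers:
            role = Role.FATHER
        elif iid in mothers:
            role = Role.MOTHER
        else:
            role = Role.SIBLING
        members.append(PedigreeMember(
            member_id=iid,
            sex=_PED_SEX.get(sex, Sex.UNKNOWN),
            affected=(pheno == "2"),
            role=role,
            sample_id=iid,
        ))
    return Pedigree(tuple(members))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_vcf(
    records: Sequence[VariantRecord],
    path,
    *,
    samples: Optional[Sequence[str]] = None,
    contig_lengths: Optional[Mapping[str, int]] = None,
    frequency_keys: Optional[Mapping[str, str]] = None,
    gene_key: str = DEFAULT_GENE_KEY,
) -> None:
    """Write records as a valid, sorted VCF v4.2 that round-trips via read_vcf."""
    freq_keys = dict(DEFAULT_FREQUENCY_KEYS if frequency_keys is None else frequency_keys)
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)

    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    for r in records:
        end = r.pos + len(r.ref)
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), end + 1)
    if contig_lengths:
        contigs.update(contig_lengths)
    for name in sorted(contigs, key=chrom_sort_key):
        header.add_line(f"##contig=<ID={name},length={contigs[name]}>")
    header.add_line('##FILTER=<ID=FAIL,Description="Failed upstream quality filtering">')
    header.add_line(f'##INFO=<ID={gene_key},Number=1,Type=String,Description="Gene symbol">')
    for src, key in freq_keys.items():
        header.add_line(
            f'##INFO=<ID={key},Number=A,Type=Float,'
            f'Description="Alternate allele frequency ({src})">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)

    out = pysam.VariantFile(str(path), "w", header=header)
    with out:
        for r in sorted(records, key=VariantRecord.sort_key):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt),
                id=r.rsid)
            if r.filter_status is FilterStatus.PASS:
                rec.filter.add("PASS")
            elif r.filter_status is FilterStatus.FAIL:
                rec.filter.add("FAIL")
            # UNFILTERED: leave FILTER as '.'
            if r.gene is not None:
                rec.info[gene_key] = r.gene
            for src, key in freq_keys.items():
                if src in r.pop_freqs:
                    rec.info[key] = (r.pop_freqs[src],)
            for s in samples:
                call = r.genotypes.get(s)
                rec.samples[s]["GT"] = call.alleles if call else (None, None)
            out.write(rec)


def _tsv_row(variant: VariantRecord, model, scope,
             consequences=None, origins=None) -> str:
    from .annotation import ImpactCall  # local import to avoid a cycle

    cons = (consequences or {}).get(variant.key)
    orig = (origins or {}).get(variant.key)
    impact = variant.impact.value.value if isinstance(variant.impact, ImpactCall) else ""
    return "\t".join([
        variant.chrom,
        str(variant.pos),
        variant.ref,
        variant.alt,
        variant.gene or "",
        impact,
        model.value if model is not None else "",
        scope,
        cons.hgvs_c if cons else "",
        cons.hgvs_p if cons else "",
        orig.value.value if orig else "",
    ])


def write_candidates(
    candidates: "CandidateSet",
    path,
    format: str = "tsv",
    *,
    restricted: bool = False,
    consequences: Optional[Mapping[tuple, "ConsequenceAnnotation"]] = None,
    origins: Optional[Mapping[tuple, "OriginCall"]] = None,
) -> None:
    """Write a candidate set as a fixed-header TSV or a round-trippable VCF.

    TSV emits one row per (variant, model, scope) with scope either a sample id
    or ``shared``; ``restricted=True`` writes the panel-restricted sets.
    """
    per_sample = candidates.panel_per_sample if restricted else candidates.per_sample
    shared = candidates.panel_shared if restricted else candidates.shared

    if format == "tsv":
        lines = ["\t".join(CANDIDATE_TSV_HEADER)]
        for model in sorted(shared, key=lambda m: m.value):
            for v in sorted(shared[model], key=VariantRecord.sort_key):
                lines.append(_tsv_row(v, model, "shared", consequences, origins))
        for sample in sorted(per_sample):
            for model in sorted(per_sample[sample], key=lambda m: m.value):
                for v in sorted(per_sample[sample][model], key=VariantRecord.sort_key):
                    lines.append(_tsv_row(v, model, sample, consequences, origins))
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "vcf":
        unique: dict[tuple, VariantRecord] = {}
        for model_map in [shared] + [per_sample[s] for s in per_sample]:
            for variants in model_map.values():
                for v in variants:
                    unique.setdefault(v.key, v)
        write_vcf(list(unique.values()), path)
    else:
        raise ConfigurationError(f"unknown candidate format {format!r}")
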