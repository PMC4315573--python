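"""Inheritance-origin classification and the end-to-end pipeline.

A variant shared by several affected siblings but absent from both parents'
DNA cannot be an ordinary inherited allele, and several independent de novo
events at the same site are vanishingly unlikely — the parsimonious
explanation is a mutation present in a fraction of one parent's germ cells
(germline mosaicism). Genotypes alone cannot distinguish germline from
low-level somatic mosaicism, so the call is reported as "shared de novo,
consistent with germline mosaicism", and no recurrence risk is quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

from intervaltree import IntervalTree
from pyfaidx import Fasta

from .annotation import (
    GenePanel, Impact, ImpactCall, TranscriptModel, classify_impact,
    load_gene_panel, load_transcripts,
)
from .config import PipelineConfig
from .consequence import ConsequenceAnnotation, hgvs_consequence
from .errors import ConfigurationError
from .prioritization import (
    MODEL_FUNCTIONS, CandidateSet, FunnelReport, ModelName, StageSets,
    apply_panel, build_funnel, filter_quality, filter_rare, shared_candidates,
)
from .vcf_io import (
    CANDIDATE_TSV_HEADER, GenotypeCall, HOM_REF_CALL, Pedigree, VariantRecord,
    Zygosity, normalize_chrom, read_pedigree, read_vcf, vcf_sample_ids,
    write_candidates,
)


class Origin(str, Enum):
    INHERITED = "inherited"
    DE_NOVO_SINGLE = "de_novo_single"
    SHARED_DE_NOVO_GERMLINE_MOSAIC = "shared_de_novo_germline_mosaic"
    AMBIGUOUS = "ambiguous"


ORIGIN_LABELS = {
    Origin.INHERITED: "inherited from a carrier parent",
    Origin.DE_NOVO_SINGLE: "de novo (single affected carrier)",
    Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC:
        "shared de novo, consistent with germline mosaicism",
    Origin.AMBIGUOUS: "ambiguous (insufficient parental genotypes)",
}

#: Ranking weight: de novo / mosaic candidates sort before inherited ones.
_ORIGIN_RANK = {
    Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC: 0,
    Origin.DE_NOVO_SINGLE: 0,
    Origin.INHERITED: 1,
    Origin.AMBIGUOUS: 2,
}


@dataclass(frozen=True)
class OriginCall:
    value: Origin
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value is Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC:
            if self.evidence.get("n_affected_carriers", 0) < 2:
                raise ValueError("mosaic call requires >= 2 affected carriers")


def classify_origin(
    variant: VariantRecord,
    pedigree: Pedigree,
    genotypes: Optional[Mapping[str, GenotypeCall]] = None,
) -> OriginCall:
    """Classify the inheritance origin of a variant from parental genotypes.

    Decision order: any carrier parent → INHERITED; otherwise any absent or
    missing parental genotype (or a one-parent/no-parent pedigree) →
    AMBIGUOUS; otherwise both parents hom-ref and ≥2 affected carriers →
    SHARED_DE_NOVO_GERMLINE_MOSAIC, exactly 1 → DE_NOVO_SINGLE.
    """
    if genotypes is None:
        genotypes = {
            m.member_id: variant.genotypes[m.sample_id]
            for m in pedigree.members
            if m.sample_id is not None and m.sample_id in variant.genotypes
        }

    def call_of(member) -> Zygosity:
        if member is None:
            return Zygosity.MISSING
        gt = genotypes.get(member.member_id)
        return gt.zygosity if gt is not None else Zygosity.MISSING

    carriers = [
        m.member_id for m in pedigree.affected_siblings
        if call_of(m) in (Zygosity.HET, Zygosity.HOM_ALT)
    ]
    if not carriers:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: no affected sibling carries the variant")

    mother_z = call_of(pedigree.mother)
    father_z = call_of(pedigree.father)
    evidence = {
        "mother": mother_z.value,
        "father": father_z.value,
        "n_affected_carriers": len(carriers),
        "carriers": tuple(sorted(carriers)),
    }
    parental = (mother_z, father_z)
    if any(z in (Zygosity.HET, Zygosity.HOM_ALT) for z in parental):
        return OriginCall(Origin.INHERITED, evidence)
    if not pedigree.parents:
        evidence["note"] = "no parents in pedigree"
        return OriginCall(Origin.AMBIGUOUS, evidence)
    if any(z is Zygosity.MISSING for z in parental):
        return OriginCall(Origin.AMBIGUOUS, evidence)
    if len(carriers) >= 2:
        return OriginCall(Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC, evidence)
    return OriginCall(Origin.DE_NOVO_SINGLE, evidence)


# ---------------------------------------------------------------------------
# Ranked report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportRow:
    variant: VariantRecord
    model: ModelName
    scope: str  # "shared" or a sample id
    origin: Optional[OriginCall] = None
    consequence: Optional[ConsequenceAnnotation] = None

    def to_tsv(self) -> str:
        v = self.variant
        impact = v.impact.value.value if isinstance(v.impact, ImpactCall) else ""
        return "\t".join([
            v.chrom, str(v.pos), v.ref, v.alt, v.gene or "", impact,
            self.model.value, self.scope,
            self.consequence.hgvs_c if self.consequence else "",
            self.consequence.hgvs_p if self.consequence else "",
            self.origin.value.value if self.origin else "",
        ])


def rank_report(
    candidates: CandidateSet,
    origins: Mapping[tuple, OriginCall],
    consequences: Mapping[tuple, ConsequenceAnnotation],
    *,
    restricted: bool = True,
) -> list[ReportRow]:
    """Deterministically order candidates for review.

    Order: shared before per-sample scope, high-impact before other classes,
    de novo / mosaic origin before inherited, then genomic position. The
    ordering is this pipeline's own ranking policy, standing in for a manual
    review step; it is stable under permutation of the input.
    """
    per_sample = candidates.panel_per_sample if restricted else candidates.per_sample
    shared = candidates.panel_shared if restricted else candidates.shared

    rows = []
    for model, variants in shared.items():
        for v in variants:
            rows.append(ReportRow(v, model, "shared",
                                  origins.get(v.key), consequences.get(v.key)))
    for sample, models in per_sample.items():
        for model, variants in models.items():
            for v in variants:
                rows.append(ReportRow(v, model, sample,
                                      origins.get(v.key), consequences.get(v.key)))

    def sort_key(row: ReportRow):
        v = row.variant
        high = isinstance(v.impact, ImpactCall) and v.impact.high_impact
        origin_rank = _ORIGIN_RANK.get(row.origin.value, 3) if row.origin else 3
        return (
            0 if row.scope == "shared" else 1,
            0 if high else 1,
            origin_rank,
            v.sort_key(),
            row.model.value,
            row.scope,
        )

    return sorted(rows, key=sort_key)


def report_to_tsv(rows: Sequence[ReportRow]) -> str:
    lines = ["\t".join(CANDIDATE_TSV_HEADER)]
    lines += [r.to_tsv() for r in rows]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    funnel: FunnelReport
    report: list[ReportRow]
    candidates: CandidateSet
    origins: dict[tuple, OriginCall]
    consequences: dict[tuple, ConsequenceAnnotation]
    output_paths: dict[str, Path] = field(default_factory=dict)


def merge_member_vcfs(
    vcf_paths: Sequence,
    config: PipelineConfig,
) -> tuple[list[VariantRecord], list[str]]:
    """Merge per-member (or joint) VCFs into records with full genotype maps.

    A sample whose VCF carries no record at a site observed in another member
    is assigned hom-ref there: each member was assayed genome-wide, so absence
    of a call is absence of the allele. Explicit './.' calls stay missing.
    """
    all_samples: list[str] = []
    merged: dict[tuple, VariantRecord] = {}
    for path in vcf_paths:
        for s in vcf_sample_ids(path):
            if s not in all_samples:
                all_samples.append(s)
        for rec in read_vcf(path, frequency_keys=config.frequency_sources,
                            gene_key=config.gene_info_key):
            existing = merged.get(rec.key)
            if existing is None:
                merged[rec.key] = rec
            else:
                existing.genotypes.update(rec.genotypes)
                existing.pop_freqs.update(rec.pop_freqs)
                if existing.rsid is None:
                    existing.rsid = rec.rsid
                if existing.gene is None:
                    existing.gene = rec.gene
    records = sorted(merged.values(), key=VariantRecord.sort_key)
    for rec in records:
        for s in all_samples:
            rec.genotypes.setdefault(s, HOM_REF_CALL)
    return records, all_samples


class _TranscriptIndex:
    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            s, e = t.span
            # pad by 2 so the intronic splice window at transcript edges resolves
            self._trees.setdefault(normalize_chrom(t.chrom), IntervalTree()).addi(
                max(0, s - 2), e + 2, t)

    def lookup(self, variant: VariantRecord) -> Optional[TranscriptModel]:
        tree = self._trees.get(normalize_chrom(variant.chrom))
        if tree is None:
            return None
        start0 = variant.pos - 1
        hits = sorted(tree.overlap(start0, start0 + len(variant.ref)),
                      key=lambda iv: iv.data.transcript_id)
        return hits[0].data if hits else None


def annotate_variants(
    records: Sequence[VariantRecord],
    transcripts: Sequence[TranscriptModel],
) -> dict[tuple, TranscriptModel]:
    """Assign gene symbols and impact classes in place; return transcript hits."""
    index = _TranscriptIndex(transcripts)
    hits: dict[tuple, TranscriptModel] = {}
    for rec in records:
        t = index.lookup(rec)
        if t is None:
            rec.impact = ImpactCall(Impact.NONCODING)
            continue
        hits[rec.key] = t
        rec.impact = classify_impact(rec, t)
        if rec.impact.value is not Impact.NONCODING:
            rec.gene = t.gene
        elif rec.gene is None:
            rec.gene = t.gene
    return hits


def run_pipeline(
    config: PipelineConfig,
    vcf_paths: Sequence,
    pedigree_path,
    panel_path,
    transcripts_path,
    reference_path,
    out_dir=None,
) -> PipelineResult:
    """Run quality → rarity → impact → models → intersection → panel → origin → rank.

    Writes (when ``out_dir`` is given) a funnel table, candidate TSV/VCF and a
    ranked report; all outputs are byte-deterministic for fixed inputs.
    """
    pedigree = read_pedigree(pedigree_path)
    panel = load_gene_panel(panel_path)
    reference = Fasta(str(reference_path))
    transcripts = load_transcripts(transcripts_path, reference)

    records, assayed = merge_member_vcfs(vcf_paths, config)
    bound = {m.sample_id for m in pedigree.members if m.sample_id is not None}
    missing = {s for s in bound if s not in assayed}
    affected = [m.sample_id for m in pedigree.affected_siblings]
    if any(s in missing for s in affected):
        raise ConfigurationError(
            f"affected siblings without a VCF sample column: "
            f"{sorted(s for s in affected if s in missing)}")

    hits = annotate_variants(records, transcripts)

    # per-sibling stages; each sibling's variant set = sites it carries
    hc_all = filter_quality(records, strict_pass=config.strict_pass)
    hc = {s: [v for v in hc_all
              if v.zygosity(s) in (Zygosity.HET, Zygosity.HOM_ALT)]
          for s in affected}
    rare = {s: filter_rare(hc[s], config.rarity_threshold) for s in affected}
    models = {
        s: {m: fn(rare[s], s) for m, fn in MODEL_FUNCTIONS.items()}
        for s in affected
    }
    shared_models = {
        m: shared_candidates({s: models[s][m] for s in affected}, m,
                             pair_identical=config.pair_identical)
        for m in ModelName
    }
    stages = StageSets(
        hc=hc, rare=rare, models=models,
        shared_hc=shared_candidates(hc),
        shared_rare=shared_candidates(rare),
        shared_models=shared_models,
    )
    candidates = CandidateSet(per_sample=models, shared=shared_models)
    candidates.restrict_to_panel(panel)
    candidates.validate()

    # origin + consequence annotation for every candidate in any final set
    final_keys: dict[tuple, VariantRecord] = {}
    for model_map in [candidates.shared, *candidates.per_sample.values()]:
        for vs in model_map.values():
            for v in vs:
                final_keys.setdefault(v.key, v)
    origins: dict[tuple, OriginCall] = {}
    consequences: dict[tuple, ConsequenceAnnotation] = {}
    for key, v in final_keys.items():
        if any(v.zygosity(s) in (Zygosity.HET, Zygosity.HOM_ALT) for s in affected):
            origins[key] = classify_origin(v, pedigree)
        t = hits.get(key)
        if (t is not None and t.cds_valid and isinstance(v.impact, ImpactCall)
                and v.impact.value in (Impact.FRAMESHIFT, Impact.NONSENSE,
                                       Impact.MISSENSE)):
            try:
                consequences[key] = hgvs_consequence(t, v, reference)
            except ValueError:
                pass  # e.g. indel spanning an exon boundary: no HGVS call

    funnel = build_funnel(stages, panel)
    report = rank_report(candidates, origins, consequences, restricted=True)

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["funnel_tsv"] = out / "funnel.tsv"
        paths["funnel_tsv"].write_text(funnel.to_tsv())
        paths["funnel_txt"] = out / "funnel.txt"
        paths["funnel_txt"].write_text(funnel.to_text())
        paths["candidates_tsv"] = out / "candidates.tsv"
        write_candidates(candidates, paths["candidates_tsv"], "tsv",
                         consequences=consequences, origins=origins)
        paths["candidates_vcf"] = out / "candidates.vcf"
        write_candidates(candidates, paths["candidates_vcf"], "vcf")
        paths["report_tsv"] = out / "ranked_report.tsv"
        paths["report_tsv"].write_text(report_to_tsv(report))
    return PipelineResult(
        funnel=funnel, report=report, candidates=candidates,
        origins=origins, consequences=consequences, output_paths=paths)
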