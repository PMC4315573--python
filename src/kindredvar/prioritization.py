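"""The variant-prioritization funnel.

Stages run in a fixed order: quality → rarity → inheritance-model grouping →
cross-sibling intersection → gene-panel restriction. Three inheritance models
are implemented for a family of affected siblings:

* recessive — autosomal homozygous-alternate variants, plus an unphased
  compound-heterozygote proxy (every het variant in a gene carrying ≥2
  distinct het variants in that sample);
* X-linked — variants on chromosome X carried by the sample, any zygosity;
* high-impact de novo — frameshift / nonsense / splice-site variants with no
  database record at all (no rsid and no population frequency), a stricter
  condition than merely passing the rarity threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import CODING_CLASSES, GenePanel, Impact, ImpactCall
from .errors import DataError
from .vcf_io import FilterStatus, VariantRecord, Zygosity, normalize_chrom

#: Chromosomes excluded from the autosomal ("somatic chromosome") recessive model.
NON_AUTOSOMES = frozenset({"X", "Y", "MT"})


class ModelName(str, Enum):
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"
    HIGH_IMPACT_RARE = "high_impact_rare"


MODEL_LABELS = {
    ModelName.RECESSIVE: "recessive",
    ModelName.X_LINKED: "X-linked",
    ModelName.HIGH_IMPACT_RARE: "high-impact de novo",
}


def filter_quality(variants: Iterable[VariantRecord], *,
                   strict_pass: bool = False) -> list[VariantRecord]:
    """Keep variants that survived upstream quality recalibration.

    PASS records are always kept; records with no FILTER annotation ('.') are
    kept unless ``strict_pass``; anything else (tranche labels etc.) is dropped.
    """
    keep = {FilterStatus.PASS} if strict_pass else {FilterStatus.PASS, FilterStatus.UNFILTERED}
    return [v for v in variants if v.filter_status in keep]


def filter_rare(variants: Iterable[VariantRecord],
                threshold: float = 0.01) -> list[VariantRecord]:
    """Drop a variant iff ANY frequency source records a frequency > threshold.

    Variants with no recorded frequency are retained — an unrecorded (novel)
    variant must survive this stage for the de novo model to see it.
    """
    out = []
    for v in variants:
        for src, f in v.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise DataError(f"{v.chrom}:{v.pos}: frequency {f} from {src!r} outside [0, 1]")
        if all(f <= threshold for f in v.pop_freqs.values()):
            out.append(v)
    return out


def _is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() not in NON_AUTOSOMES


def model_recessive(sample_variants: Iterable[VariantRecord],
                    sample: str) -> list[VariantRecord]:
    """Autosomal hom-alt variants plus unphased compound-het candidates."""
    variants = [v for v in sample_variants if _is_autosome(v.chrom)]
    hets_by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    out = []
    for v in variants:
        zyg = v.zygosity(sample)
        if zyg is Zygosity.HOM_ALT:
            out.append(v)
        elif zyg is Zygosity.HET and v.gene is not None:
            hets_by_gene[v.gene.casefold()].append(v)
    for gene, hets in hets_by_gene.items():
        if len({v.key for v in hets}) >= 2:
            out.extend(hets)
    out.sort(key=VariantRecord.sort_key)
    return out


def model_x_linked(sample_variants: Iterable[VariantRecord],
                   sample: str) -> list[VariantRecord]:
    """Variants on chromosome X carried by the sample (no zygosity constraint)."""
    return sorted(
        (v for v in sample_variants
         if normalize_chrom(v.chrom).upper() == "X"
         and v.zygosity(sample) in (Zygosity.HET, Zygosity.HOM_ALT)),
        key=VariantRecord.sort_key)


def model_high_impact_rare(sample_variants: Iterable[VariantRecord],
                           sample: str) -> list[VariantRecord]:
    """High-impact variants absent from every configured database.

    "Absent" means no rsid and no recorded population frequency — a stricter
    de novo proxy than the ≤1% rarity filter upstream.
    """
    out = []
    for v in sample_variants:
        if v.zygosity(sample) not in (Zygosity.HET, Zygosity.HOM_ALT):
            continue
        if not isinstance(v.impact, ImpactCall) or not v.impact.high_impact:
            continue
        if v.rsid is None and not v.pop_freqs:
            out.append(v)
    out.sort(key=VariantRecord.sort_key)
    return out


MODEL_FUNCTIONS = {
    ModelName.RECESSIVE: model_recessive,
    ModelName.X_LINKED: model_x_linked,
    ModelName.HIGH_IMPACT_RARE: model_high_impact_rare,
}


def shared_candidates(
    per_sample: Mapping[str, Sequence[VariantRecord]],
    model: Optional[ModelName] = None,
    *,
    pair_identical: bool = True,
) -> list[VariantRecord]:
    """Variants identical in (chrom, pos, ref, alt) across ALL samples.

    For the recessive model with ``pair_identical`` (the default), the
    compound-het route is re-derived on the intersection: a shared het variant
    survives only if its gene still carries ≥2 variants that are het in every
    sample; hom-alt variants survive only if hom-alt in every sample. With
    ``pair_identical=False`` the plain variant-by-variant intersection of the
    per-sample model outputs is returned.
    """
    samples = list(per_sample)
    if len(samples) < 2:
        return sorted(per_sample[samples[0]], key=VariantRecord.sort_key) if samples else []
    by_key = {s: {v.key: v for v in per_sample[s]} for s in samples}
    common = set.intersection(*(set(m) for m in by_key.values()))
    first = samples[0]
    shared = [by_key[first][k] for k in common]

    if model is ModelName.RECESSIVE and pair_identical:
        def zyg(key, s):
            rec = by_key[s][key]
            return rec.zygosity(s)

        kept = [v for v in shared
                if all(zyg(v.key, s) is Zygosity.HOM_ALT for s in samples)]
        het_by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
        for v in shared:
            if v.gene is not None and all(zyg(v.key, s) is Zygosity.HET for s in samples):
                het_by_gene[v.gene.casefold()].append(v)
        for gene, hets in het_by_gene.items():
            if len({v.key for v in hets}) >= 2:
                kept.extend(hets)
        shared = kept
    return sorted(shared, key=VariantRecord.sort_key)


def apply_panel(candidates: Iterable[VariantRecord],
                panel: GenePanel) -> list[VariantRecord]:
    """Restrict to variants whose gene symbol matches the panel (case-insensitive)."""
    return [v for v in candidates if v.gene in panel]


# ---------------------------------------------------------------------------
# Candidate set and funnel report
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Per-sample and shared surviving variants for each inheritance model."""

    per_sample: dict[str, dict[ModelName, list[VariantRecord]]]
    shared: dict[ModelName, list[VariantRecord]]
    panel_per_sample: dict[str, dict[ModelName, list[VariantRecord]]] = field(default_factory=dict)
    panel_shared: dict[ModelName, list[VariantRecord]] = field(default_factory=dict)

    def validate(self) -> None:
        for model, shared in self.shared.items():
            shared_keys = {v.key for v in shared}
            for sample, models in self.per_sample.items():
                sample_keys = {v.key for v in models.get(model, [])}
                if not shared_keys <= sample_keys:
                    raise DataError(
                        f"shared {model.value} variants missing from sample {sample}")
        for model, restricted in self.panel_shared.items():
            if not {v.key for v in restricted} <= {v.key for v in self.shared.get(model, [])}:
                raise DataError(f"panel-restricted shared set not a subset ({model.value})")
        for sample, models in self.panel_per_sample.items():
            for model, restricted in models.items():
                full = {v.key for v in self.per_sample.get(sample, {}).get(model, [])}
                if not {v.key for v in restricted} <= full:
                    raise DataError(
                        f"panel-restricted set not a subset ({sample}, {model.value})")

    def restrict_to_panel(self, panel: GenePanel) -> None:
        self.panel_per_sample = {
            s: {m: apply_panel(vs, panel) for m, vs in models.items()}
            for s, models in self.per_sample.items()
        }
        self.panel_shared = {m: apply_panel(vs, panel) for m, vs in self.shared.items()}


@dataclass(frozen=True)
class FunnelRow:
    label: str
    per_sample: dict[str, int]
    shared: int


@dataclass
class FunnelReport:
    """Staged count table: one column per sample plus a Shared column."""

    samples: tuple[str, ...]
    rows: tuple[FunnelRow, ...]

    def row(self, label: str) -> FunnelRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_tsv(self) -> str:
        lines = ["\t".join(["stage", *self.samples, "shared"])]
        for r in self.rows:
            lines.append("\t".join(
                [r.label, *(str(r.per_sample[s]) for s in self.samples), str(r.shared)]))
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        width = max(len(r.label) for r in self.rows) + 2
        cols = [*self.samples, "shared"]
        head = "".join(c.rjust(12) for c in cols)
        lines = ["Variant funnel (counts are scaled-down synthetic data, not genome-scale)",
                 " " * width + head]
        for r in self.rows:
            vals = [*(r.per_sample[s] for s in self.samples), r.shared]
            lines.append(r.label.ljust(width) + "".join(str(v).rjust(12) for v in vals))
        return "\n".join(lines) + "\n"


@dataclass
class StageSets:
    """Outputs of each funnel stage, per sample and intersected."""

    hc: dict[str, list[VariantRecord]]
    rare: dict[str, list[VariantRecord]]
    models: dict[str, dict[ModelName, list[VariantRecord]]]
    shared_hc: list[VariantRecord]
    shared_rare: list[VariantRecord]
    shared_models: dict[ModelName, list[VariantRecord]]


def _count_genes(variants: Iterable[VariantRecord]) -> int:
    return len({v.gene.casefold() for v in variants if v.gene is not None})


def build_funnel(stages: StageSets, panel: GenePanel) -> FunnelReport:
    """Assemble the staged count table from executed stage outputs."""
    samples = tuple(sorted(stages.hc))

    def per(fn) -> dict[str, int]:
        return {s: fn(stages.hc[s]) for s in samples}

    def impact_count(variants, predicate) -> int:
        return sum(1 for v in variants
                   if isinstance(v.impact, ImpactCall) and predicate(v.impact))

    rows = [
        FunnelRow("High-confidence variants",
                  {s: len(stages.hc[s]) for s in samples}, len(stages.shared_hc)),
        FunnelRow("In coding regions",
                  per(lambda vs: impact_count(vs, lambda i: i.value in CODING_CLASSES)),
                  impact_count(stages.shared_hc, lambda i: i.value in CODING_CLASSES)),
        FunnelRow("At splice sites",
                  per(lambda vs: impact_count(vs, lambda i: i.value is Impact.SPLICE_SITE)),
                  impact_count(stages.shared_hc, lambda i: i.value is Impact.SPLICE_SITE)),
        FunnelRow("SNVs",
                  per(lambda vs: sum(1 for v in vs if v.is_snv)),
                  sum(1 for v in stages.shared_hc if v.is_snv)),
        FunnelRow("Short indels",
                  per(lambda vs: sum(1 for v in vs if not v.is_snv)),
                  sum(1 for v in stages.shared_hc if not v.is_snv)),
        FunnelRow("In panel genes",
                  per(lambda vs: len(apply_panel(vs, panel))),
                  len(apply_panel(stages.shared_hc, panel))),
        FunnelRow("Rare (unrecorded or below threshold)",
                  {s: len(stages.rare[s]) for s in samples}, len(stages.shared_rare)),
    ]
    for model in ModelName:
        label = MODEL_LABELS[model]
        shared_m = stages.shared_models.get(model, [])
        per_m = {s: stages.models[s].get(model, []) for s in samples}
        rows += [
            FunnelRow(f"Compliant with the {label} model",
                      {s: len(per_m[s]) for s in samples}, len(shared_m)),
            FunnelRow(f"Genes with variants compliant with the {label} model",
                      {s: _count_genes(per_m[s]) for s in samples},
                      _count_genes(shared_m)),
            FunnelRow(f"In panel genes and compliant with the {label} model",
                      {s: len(apply_panel(per_m[s], panel)) for s in samples},
                      len(apply_panel(shared_m, panel))),
            FunnelRow(f"Panel genes with variants compliant with the {label} model",
                      {s: _count_genes(apply_panel(per_m[s], panel)) for s in samples},
                      _count_genes(apply_panel(shared_m, panel))),
        ]
    return FunnelReport(samples=samples, rows=tuple(rows))
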