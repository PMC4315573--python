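"""Run the full prioritization pipeline on a synthetic family.

Stages: quality -> rarity (1%) -> impact annotation -> three inheritance
models -> cross-sibling intersection -> gene-panel restriction -> origin
classification -> ranked report. The funnel table mirrors the per-proband /
Shared count structure of a multiplex-family study; the top-ranked candidate
should be the planted frameshift with a germline-mosaicism-consistent call.
"""

from pathlib import Path

from kindredvar import PipelineConfig, SimConfig, run_pipeline, simulate
from kindredvar.family import ORIGIN_LABELS

out = Path("example_output/sim")
reference, family = simulate(SimConfig(seed=42, n_background_variants=1200), out)

result = run_pipeline(
    PipelineConfig(),
    list(family.vcf_paths.values()),
    family.ped_path,
    reference.panel_path,
    reference.gff3_path,
    reference.fasta_path,
    Path("example_output/run"),
)

print(result.funnel.to_text())

top = result.report[0]
v = top.variant
print(f"top candidate : {v.chrom}:{v.pos} {v.ref}>{v.alt} in {v.gene}")
print(f"model / scope : {top.model.value} / {top.scope}")
print(f"origin        : {ORIGIN_LABELS[top.origin.value]}")
print(f"consequence   : {top.consequence.hgvs_c}, {top.consequence.hgvs_p}")
print(f"  -> {top.consequence.missense_run} altered codons, then a premature stop")
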