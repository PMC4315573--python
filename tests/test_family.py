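"""Origin classification, ranked reporting and the end-to-end pipeline."""

from __future__ import annotations

import itertools
import random

import pytest

from kindredvar.config import PipelineConfig
from kindredvar.errors import ConfigurationError
from kindredvar.family import (
    Origin, classify_origin, rank_report, report_to_tsv, run_pipeline,
)
from kindredvar.prioritization import CandidateSet, ModelName
from kindredvar.vcf_io import (
    GenotypeCall, Pedigree, PedigreeMember, Role, Sex, Zygosity,
)
from kindredvar.annotation import Impact, ImpactCall

from conftest import make_variant

ZYG_CALLS = {
    Zygosity.HOM_REF: GenotypeCall((0, 0)),
    Zygosity.HET: GenotypeCall((0, 1)),
    Zygosity.HOM_ALT: GenotypeCall((1, 1)),
    Zygosity.MISSING: GenotypeCall((None, None)),
}

SIBS = ("SIB1", "SIB2", "SIB3")


def nuclear_pedigree(with_parents=True):
    members = [
        PedigreeMember(s, Sex.MALE, True, Role.SIBLING, s) for s in SIBS
    ]
    if with_parents:
        members += [
            PedigreeMember("MOTHER", Sex.FEMALE, False, Role.MOTHER, "MOTHER"),
            PedigreeMember("FATHER", Sex.MALE, False, Role.FATHER, "FATHER"),
        ]
    return Pedigree(tuple(members))


def _origin_oracle(mother, father, n_carriers):
    """Independent truth table for the origin decision."""
    carrier = (Zygosity.HET, Zygosity.HOM_ALT)
    if mother in carrier or father in carrier:
        return Origin.INHERITED
    if mother is Zygosity.MISSING or father is Zygosity.MISSING:
        return Origin.AMBIGUOUS
    return (Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC if n_carriers >= 2
            else Origin.DE_NOVO_SINGLE)


class TestClassifyOrigin:
    def test_exhaustive_truth_table(self):
        """All parental zygosity pairs x carrier counts match the oracle."""
        ped = nuclear_pedigree()
        for mother, father, n_carriers in itertools.product(
                Zygosity, Zygosity, (1, 2, 3)):
            gts = {s: ZYG_CALLS[Zygosity.HET if i < n_carriers else Zygosity.HOM_REF]
                   for i, s in enumerate(SIBS)}
            gts["MOTHER"] = ZYG_CALLS[mother]
            gts["FATHER"] = ZYG_CALLS[father]
            v = make_variant("22", 100, "CA", "C", genotypes=gts)
            call = classify_origin(v, ped)
            assert call.value is _origin_oracle(mother, father, n_carriers), (
                mother, father, n_carriers)
            # never a mosaic call while a parent carries the allele
            if call.value is Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC:
                assert mother not in (Zygosity.HET, Zygosity.HOM_ALT)
                assert father not in (Zygosity.HET, Zygosity.HOM_ALT)

    def test_multiplex_family_mosaic_pattern(self):
        """Three het siblings, both parents hom-ref: germline mosaicism."""
        ped = nuclear_pedigree()
        gts = {s: ZYG_CALLS[Zygosity.HET] for s in SIBS}
        gts.update(MOTHER=ZYG_CALLS[Zygosity.HOM_REF],
                   FATHER=ZYG_CALLS[Zygosity.HOM_REF])
        call = classify_origin(make_variant("22", 1, "CA", "C", genotypes=gts), ped)
        assert call.value is Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC
        assert call.evidence["n_affected_carriers"] == 3

    def test_no_parents_is_ambiguous(self):
        ped = nuclear_pedigree(with_parents=False)
        gts = {s: ZYG_CALLS[Zygosity.HET] for s in SIBS}
        call = classify_origin(make_variant(genotypes=gts), ped)
        assert call.value is Origin.AMBIGUOUS

    def test_no_carrier_sibling_violates_precondition(self):
        ped = nuclear_pedigree()
        gts = {s: ZYG_CALLS[Zygosity.HOM_REF] for s in SIBS}
        with pytest.raises(ValueError):
            classify_origin(make_variant(genotypes=gts), ped)


class TestRankReport:
    def _candidates(self):
        fs = make_variant("22", 100, "CA", "C", gene="SHANK3",
                          genotypes={s: (0, 1) for s in SIBS},
                          impact=ImpactCall(Impact.FRAMESHIFT))
        mis = make_variant("7", 50, gene="NRXN1",
                           genotypes={"SIB1": (1, 1)},
                           impact=ImpactCall(Impact.MISSENSE))
        cs = CandidateSet(
            per_sample={"SIB1": {ModelName.RECESSIVE: [mis]}},
            shared={ModelName.HIGH_IMPACT_RARE: [fs]},
        )
        cs.panel_per_sample = cs.per_sample
        cs.panel_shared = cs.shared
        return cs, fs, mis

    def test_shared_high_impact_mosaic_ranks_first(self):
        cs, fs, mis = self._candidates()
        ped = nuclear_pedigree()
        fs.genotypes.update(MOTHER=ZYG_CALLS[Zygosity.HOM_REF],
                            FATHER=ZYG_CALLS[Zygosity.HOM_REF])
        origins = {fs.key: classify_origin(fs, ped)}
        rows = rank_report(cs, origins, {})
        assert [r.variant.key for r in rows] == [fs.key, mis.key]
        assert rows[0].scope == "shared"

    def test_empty_candidates_empty_report(self):
        cs = CandidateSet(per_sample={}, shared={})
        assert rank_report(cs, {}, {}) == []

    def test_deterministic_under_input_permutation(self):
        cs, fs, mis = self._candidates()
        baseline = report_to_tsv(rank_report(cs, {}, {}))
        rng = random.Random(0)
        for _ in range(5):
            for model_map in (cs.per_sample, cs.panel_per_sample):
                for models in model_map.values():
                    for vs in models.values():
                        rng.shuffle(vs)
            assert report_to_tsv(rank_report(cs, {}, {})) == baseline


class TestRunPipeline:
    def test_planted_frameshift_tops_report_with_mosaic_call(self, sim_family):
        _, ref, fam, result = sim_family
        (planted,) = fam.planted[ModelName.HIGH_IMPACT_RARE]
        top = result.report[0]
        assert top.variant.key == planted.key
        assert top.scope == "shared"
        assert top.origin.value is Origin.SHARED_DE_NOVO_GERMLINE_MOSAIC
        assert top.consequence is not None
        assert top.consequence.kind == "frameshift"
        assert "fs*" in top.consequence.hgvs_p
        # fs*N arithmetic holds on the emitted annotation
        assert top.consequence.missense_run == top.consequence.stop_offset - 1

    def test_panel_without_planted_gene_empties_shared_panel_set(
            self, sim_family, tmp_path):
        config, ref, fam, _ = sim_family
        (planted,) = fam.planted[ModelName.HIGH_IMPACT_RARE]
        other = [s for s in sorted(ref.panel.symbols) if s != "shank3"]
        panel_path = tmp_path / "panel_no_target.txt"
        panel_path.write_text("\n".join(other) + "\n")
        result = run_pipeline(
            PipelineConfig(), list(fam.vcf_paths.values()), fam.ped_path,
            panel_path, ref.gff3_path, ref.fasta_path, None)
        assert result.candidates.panel_shared[ModelName.HIGH_IMPACT_RARE] == []
        unrestricted = {v.key for v in
                        result.candidates.shared[ModelName.HIGH_IMPACT_RARE]}
        assert planted.key in unrestricted

    def test_rerun_outputs_byte_identical(self, sim_family, tmp_path):
        config, ref, fam, result = sim_family
        again = run_pipeline(
            PipelineConfig(), list(fam.vcf_paths.values()), fam.ped_path,
            ref.panel_path, ref.gff3_path, ref.fasta_path, tmp_path / "out2")
        for name, path in result.output_paths.items():
            assert again.output_paths[name].read_bytes() == path.read_bytes(), name

    def test_candidate_set_invariants_hold(self, sim_family):
        _, _, _, result = sim_family
        result.candidates.validate()
        for model, shared in result.candidates.shared.items():
            shared_keys = {v.key for v in shared}
            for sample, models in result.candidates.per_sample.items():
                assert shared_keys <= {v.key for v in models[model]}

    def test_pedigree_sample_mismatch_is_configuration_error(
            self, sim_family, tmp_path):
        _, ref, fam, _ = sim_family
        bad_ped = tmp_path / "bad.ped"
        bad_ped.write_text(
            "FAM1 FATHER 0 0 1 1\nFAM1 MOTHER 0 0 2 1\n"
            "FAM1 GHOST FATHER MOTHER 1 2\n")
        with pytest.raises(ConfigurationError, match="GHOST"):
            run_pipeline(PipelineConfig(), list(fam.vcf_paths.values()),
                         bad_ped, ref.panel_path, ref.gff3_path,
                         ref.fasta_path, None)

    def test_funnel_written_as_tsv_and_text(self, sim_family):
        _, _, _, result = sim_family
        tsv = result.output_paths["funnel_tsv"].read_text()
        header = tsv.splitlines()[0].split("\t")
        assert header == ["stage", "SIB1", "SIB2", "SIB3", "shared"]
        assert "germline mosaicism" not in tsv  # funnel holds counts only
        report = result.output_paths["report_tsv"].read_text()
        assert "shared_de_novo_germline_mosaic" in report
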