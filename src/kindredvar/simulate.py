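"""Self-contained synthetic families for exercising the full pipeline.

The generator emulates, at desk scale, the data shape the prioritization
assumes: three affected brothers sharing ~75% of their variants, unaffected
parents, background variation annotated with population frequencies, and
planted causal variants for each inheritance model — including a shared
heterozygous frameshift absent from both parents (the germline-mosaicism
pattern). Sibling sharing is a single Bernoulli draw per background variant
rather than a meiosis simulation: the downstream analysis consumes genotype
patterns, not haplotypes.

Two structural guards keep planted-variant recovery interpretable:
background variants never collide with planted positions, and at most one
rarity-surviving background variant may be shared by all siblings per gene
(further ones are redrawn as common). Rare background variants are always
heterozygous — at frequencies ≤1% a homozygote (probability f²) would be
unrealistically lucky in a five-member family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from intervaltree import IntervalTree

from .annotation import GenePanel, TranscriptModel, bundled_asd_panel
from .errors import ConfigurationError
from .prioritization import ModelName
from .vcf_io import (
    FilterStatus, GenotypeCall, HET_CALL, HOM_ALT_CALL, VariantRecord,
    write_vcf,
)

SIBLINGS = ("SIB1", "SIB2", "SIB3")
PARENTS = ("FATHER", "MOTHER")
MEMBERS = SIBLINGS + PARENTS

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
_AA = {c: str(Seq(c).translate()) for c in _CODONS}


@dataclass(frozen=True)
class PlantedScenario:
    """One causal variant to inject, per inheritance model.

    ``gene=None`` lets the generator pick a suitable panel gene (autosomal for
    recessive/high-impact, X for the X-linked model). Kinds: ``frameshift_del``
    (default for HIGH_IMPACT_RARE), ``hom_snv`` (default for RECESSIVE),
    ``compound_het``, ``het_snv`` (default for X_LINKED).
    """

    model: ModelName
    gene: Optional[str] = None
    kind: Optional[str] = None


_DEFAULT_KIND = {
    ModelName.HIGH_IMPACT_RARE: "frameshift_del",
    ModelName.RECESSIVE: "hom_snv",
    ModelName.X_LINKED: "het_snv",
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic family.

    Defaults are the conditions the analysis assumes: three affected brothers
    sharing ~75% of background variants, ~2000 background variants per sibling
    (a deliberate scale-down from genome-wide counts in the millions), all
    background variation recorded in population databases, and one planted
    unrecorded frameshift in a panel gene absent from both parents.
    """

    seed: int = 0
    n_genes: int = 40
    gene_length: int = 1200
    n_background_variants: int = 2000
    background_freq_range: tuple[float, float] = (0.001, 0.5)
    fraction_recorded: float = 1.0
    sibling_share_rate: float = 0.75
    fraction_fail_filter: float = 0.05
    indel_fraction: float = 0.1
    panel_size: int = 12
    planted_scenarios: tuple[PlantedScenario, ...] = (
        PlantedScenario(ModelName.HIGH_IMPACT_RARE),
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.sibling_share_rate <= 1.0:
            raise ConfigurationError("sibling_share_rate must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.background_freq_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigurationError("background_freq_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class SyntheticReference:
    fasta_path: Path
    gff3_path: Path
    panel_path: Path
    contigs: dict[str, str]
    transcripts: list[TranscriptModel]
    panel: GenePanel


@dataclass
class SimulatedFamily:
    vcf_paths: dict[str, Path]
    ped_path: Path
    planted: dict[ModelName, list[VariantRecord]]
    background: list[VariantRecord] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _build_gene(rng: np.random.Generator, gene: str, tid: str, chrom: str,
                offset: int, gene_length: int, strand: str):
    """Return (genomic sequence slice, TranscriptModel) for one 3-exon gene."""
    utr = 30
    intron = max(60, gene_length // 6)
    cds_len = (gene_length - 2 * utr - 2 * intron) // 3 * 3
    if cds_len < 90:
        raise ConfigurationError(
            f"gene_length {gene_length} too small for a valid CDS (needs >= "
            f"{2 * utr + 2 * intron + 90})")
    n_codons = cds_len // 3
    a = int(rng.integers(5, n_codons - 10))
    b = int(rng.integers(a + 5, n_codons - 5))
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    ] + ["TAA"]
    cds = "".join(codons)
    chunks = (cds[: 3 * a], cds[3 * a: 3 * b], cds[3 * b:])

    sense = (_random_seq(rng, utr) + chunks[0] + _random_seq(rng, intron)
             + chunks[1] + _random_seq(rng, intron) + chunks[2]
             + _random_seq(rng, utr))
    L = len(sense)
    # local sense-strand structure (0-based half-open)
    e1 = (0, utr + len(chunks[0]))
    e2 = (e1[1] + intron, e1[1] + intron + len(chunks[1]))
    e3 = (e2[1] + intron, L)
    exons_local = [e1, e2, e3]
    cds_lo, cds_hi = utr, L - utr

    if strand == "-":
        genomic = str(Seq(sense).reverse_complement())
        exons_local = sorted((L - e, L - s) for s, e in exons_local)
        cds_lo, cds_hi = L - cds_hi, L - cds_lo
    else:
        genomic = sense

    model = TranscriptModel(
        transcript_id=tid, gene=gene, chrom=chrom, strand=strand,
        exons=tuple((offset + s, offset + e) for s, e in exons_local),
        cds_start=offset + cds_lo, cds_end=offset + cds_hi,
        cds_seq=cds)
    return genomic, model


def make_reference(config: SimConfig, out_dir) -> SyntheticReference:
    """Generate a FASTA reference, GFF3 transcript models and a panel file.

    Every gene gets one 3-exon transcript with a valid CDS (starts ATG, ends
    TAA, length divisible by 3, no internal stops). The first ``panel_size``
    genes carry real ASD-panel symbols (SHANK3 first) and form the written
    panel; the rest are filler genes outside the panel. One contig is named
    "X" and always carries at least one panel gene.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    bundled = sorted(bundled_asd_panel().symbols)
    panel_symbols = ["SHANK3"] + [s.upper() for s in bundled if s.upper() != "SHANK3"]
    if config.panel_size > len(panel_symbols):
        raise ConfigurationError(
            f"panel_size {config.panel_size} exceeds bundled symbol pool")
    symbols = [panel_symbols[i].upper() for i in range(min(config.panel_size, config.n_genes))]
    symbols += [f"SIMG{i:03d}" for i in range(config.n_genes - len(symbols))]

    # contig of gene i: index 1 goes to X (a panel gene when panel_size >= 2),
    # plus every 8th gene; the rest round-robin over four autosomes
    def contig_of(i: int) -> str:
        if i % 8 == 1:
            return "X"
        return str(1 + i % 4)

    spacer = 200
    contig_seqs: dict[str, list[str]] = {}
    contig_len: dict[str, int] = {}
    transcripts: list[TranscriptModel] = []
    for i, gene in enumerate(symbols):
        chrom = contig_of(i)
        parts = contig_seqs.setdefault(chrom, [])
        if not parts:
            parts.append(_random_seq(rng, spacer))
            contig_len[chrom] = spacer
        strand = "-" if rng.random() < 0.3 else "+"
        seq, model = _build_gene(
            rng, gene, f"TX_{gene}", chrom, contig_len[chrom],
            config.gene_length, strand)
        parts.append(seq + _random_seq(rng, spacer))
        contig_len[chrom] += len(seq) + spacer
        transcripts.append(model)

    contigs = {name: "".join(parts) for name, parts in contig_seqs.items()}

    fasta_path = out / "reference.fa"
    with fasta_path.open("w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(contigs[name]), id=name, description="")
             for name in sorted(contigs)),
            fh, "fasta")

    gff3_path = out / "transcripts.gff3"
    gff3_path.write_text(_to_gff3(transcripts))

    panel_path = out / "panel.txt"
    written = symbols[: min(config.panel_size, config.n_genes)]
    panel_path.write_text("\n".join(written) + "\n")

    return SyntheticReference(
        fasta_path=fasta_path, gff3_path=gff3_path, panel_path=panel_path,
        contigs=contigs, transcripts=transcripts,
        panel=GenePanel.from_symbols(written, "sim_panel"))


def _to_gff3(transcripts: Sequence[TranscriptModel]) -> str:
    lines = ["##gff-version 3"]
    for t in transcripts:
        s, e = t.span
        attrs = f"ID=gene:{t.gene};Name={t.gene}"
        lines.append("\t".join([t.chrom, "kindredvar", "gene", str(s + 1), str(e),
                                ".", t.strand, ".", attrs]))
        lines.append("\t".join([t.chrom, "kindredvar", "mRNA", str(s + 1), str(e),
                                ".", t.strand, ".",
                                f"ID={t.transcript_id};Parent=gene:{t.gene};"
                                f"gene_name={t.gene}"]))
        for i, (xs, xe) in enumerate(t.exons, 1):
            lines.append("\t".join([
                t.chrom, "kindredvar", "exon", str(xs + 1), str(xe), ".",
                t.strand, ".", f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]))
        cds_iv = t.cds_intervals()
        ordered = cds_iv if t.strand == "+" else list(reversed(cds_iv))
        acc = 0
        phased = []
        for cs, ce in ordered:
            phased.append((cs, ce, (3 - acc % 3) % 3))
            acc += ce - cs
        for cs, ce, phase in sorted(phased):
            lines.append("\t".join([
                t.chrom, "kindredvar", "CDS", str(cs + 1), str(ce), ".",
                t.strand, str(phase), f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

def _cds_genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic positions (0-based) of CDS bases in coding order."""
    pos = [p for s, e in t.cds_intervals() for p in range(s, e)]
    return pos[::-1] if t.strand == "-" else pos


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _missense_snv(rng: np.random.Generator, t: TranscriptModel,
                  genome: dict[str, str], codon_index: int) -> tuple[int, str, str]:
    """A genomic SNV changing codon ``codon_index`` to a different, non-stop residue."""
    cds = t.cds_seq
    assert cds is not None
    positions = _cds_genomic_positions(t)
    for within in (0, 1, 2):
        off = codon_index * 3 + within
        codon = cds[codon_index * 3: codon_index * 3 + 3]
        for base in "ACGT":
            if base == cds[off]:
                continue
            new = codon[:within] + base + codon[within + 1:]
            if new in _STOPS or _AA[new] == _AA[codon]:
                continue
            g = positions[off]
            ref = genome[t.chrom][g]
            alt = base if t.strand == "+" else base.translate(_COMPLEMENT)
            if alt != ref:
                return g + 1, ref, alt
    raise ConfigurationError(f"could not construct a missense SNV in {t.gene}")


def _frameshift_deletion(t: TranscriptModel, genome: dict[str, str],
                         codon_index: int) -> tuple[int, str, str]:
    """A 1-bp CDS deletion (VCF anchor style) hitting ``codon_index``."""
    positions = _cds_genomic_positions(t)
    g = positions[codon_index * 3 + 1]
    seq = genome[t.chrom]
    return g, seq[g - 1: g + 1], seq[g - 1]  # pos is 1-based == g


def _resolve_scenario_gene(scenario: PlantedScenario,
                           ref: SyntheticReference) -> TranscriptModel:
    by_gene = {t.gene.casefold(): t for t in ref.transcripts}
    if scenario.gene is not None:
        t = by_gene.get(scenario.gene.casefold())
        if t is None:
            raise ConfigurationError(
                f"planted scenario gene {scenario.gene!r} not in the reference")
        return t
    want_x = scenario.model is ModelName.X_LINKED
    for t in ref.transcripts:
        on_x = t.chrom.upper() == "X"
        if t.gene in ref.panel and on_x == want_x:
            return t
    raise ConfigurationError(
        f"no suitable panel gene for a {scenario.model.value} scenario")


def simulate_family(config: SimConfig, reference: SyntheticReference,
                    out_dir) -> SimulatedFamily:
    """Write per-member VCFs and a PED file for one synthetic family.

    Planted scenarios are injected per their model's genotype pattern
    (recessive: siblings hom-alt or compound-het with carrier parents;
    X-linked: siblings and mother het; high-impact de novo: frameshift het in
    all siblings, absent from both parents, no database record). Background
    variants are Bernoulli-shared across siblings and always transmitted by
    at least one carrier parent. Output is byte-deterministic for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    genome = reference.contigs

    member_variants: dict[str, list[VariantRecord]] = {m: [] for m in MEMBERS}
    used_positions: dict[str, set[int]] = {c: set() for c in genome}
    planted: dict[ModelName, list[VariantRecord]] = {m: [] for m in ModelName}
    taken_genes: set[str] = set()

    def emit(chrom, pos, ref, alt, genotypes: dict[str, GenotypeCall],
             gene=None, rsid=None, freqs=None,
             status=FilterStatus.PASS) -> VariantRecord:
        proto = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, filter_status=status,
            rsid=rsid, pop_freqs=dict(freqs or {}), gene=gene)
        for member, call in genotypes.items():
            rec = replace(proto, genotypes={member: call},
                          pop_freqs=dict(proto.pop_freqs))
            member_variants[member].append(rec)
        used_positions[chrom].update(range(pos - 1, pos - 1 + len(ref)))
        return replace(proto, genotypes=dict(genotypes))

    # --- planted scenarios -------------------------------------------------
    for scenario in config.planted_scenarios:
        if scenario.gene is None:
            # auto-pick: first unused suitable panel gene
            want_x = scenario.model is ModelName.X_LINKED
            t = next(
                (m for m in reference.transcripts
                 if m.gene in reference.panel
                 and (m.chrom.upper() == "X") == want_x
                 and m.gene not in taken_genes),
                None)
            if t is None:
                raise ConfigurationError(
                    f"no free panel gene for a {scenario.model.value} scenario")
        else:
            t = _resolve_scenario_gene(scenario, reference)
        taken_genes.add(t.gene)
        kind = scenario.kind or _DEFAULT_KIND[scenario.model]
        n_codons = len(t.cds_seq) // 3
        mid = n_codons // 2

        if kind == "frameshift_del":
            pos, ref, alt = _frameshift_deletion(t, genome, mid)
            rec = emit(t.chrom, pos, ref, alt,
                       {s: HET_CALL for s in SIBLINGS}, gene=t.gene)
        elif kind == "hom_snv":
            pos, ref, alt = _missense_snv(rng, t, genome, mid)
            gts = {s: HOM_ALT_CALL for s in SIBLINGS}
            gts.update({p: HET_CALL for p in PARENTS})
            rec = emit(t.chrom, pos, ref, alt, gts, gene=t.gene)
        elif kind == "compound_het":
            p1, r1, a1 = _missense_snv(rng, t, genome, max(2, mid - 5))
            p2, r2, a2 = _missense_snv(rng, t, genome, min(n_codons - 3, mid + 5))
            rec1 = emit(t.chrom, p1, r1, a1,
                        {**{s: HET_CALL for s in SIBLINGS}, "FATHER": HET_CALL},
                        gene=t.gene)
            rec2 = emit(t.chrom, p2, r2, a2,
                        {**{s: HET_CALL for s in SIBLINGS}, "MOTHER": HET_CALL},
                        gene=t.gene)
            planted[scenario.model].extend([rec1, rec2])
            continue
        elif kind == "het_snv":
            pos, ref, alt = _missense_snv(rng, t, genome, mid)
            gts = {s: HET_CALL for s in SIBLINGS}
            if scenario.model is ModelName.X_LINKED:
                gts["MOTHER"] = HET_CALL
            rec = emit(t.chrom, pos, ref, alt, gts, gene=t.gene)
        else:
            raise ConfigurationError(f"unknown planted kind {kind!r}")
        planted[scenario.model].append(rec)

    # --- background --------------------------------------------------------
    gene_index: dict[str, IntervalTree] = {}
    for t in reference.transcripts:
        s, e = t.span
        gene_index.setdefault(t.chrom, IntervalTree()).addi(s, e, t.gene)

    contig_names = sorted(genome)
    lengths = np.array([len(genome[c]) for c in contig_names], dtype=float)
    weights = lengths / lengths.sum()
    share = config.sibling_share_rate
    expected_per_slot = share + (1 - share) / 3
    n_slots = int(round(config.n_background_variants / expected_per_slot))
    lo, hi = config.background_freq_range
    threshold = 0.01
    # genes hosting planted variants count as occupied, so no background
    # rare shared het can pair with a planted allele into a spurious
    # compound heterozygote
    rare_shared_genes: set[str] = set(taken_genes)
    background: list[VariantRecord] = []

    for slot in range(n_slots):
        for _attempt in range(200):
            chrom = contig_names[int(rng.choice(len(contig_names), p=weights))]
            pos0 = int(rng.integers(1, len(genome[chrom]) - 3))
            span = 2 if rng.random() < config.indel_fraction else 1
            is_del = span == 2
            if any(p in used_positions[chrom] for p in range(pos0 - 1, pos0 + span)):
                continue
            break
        else:  # pragma: no cover - genome saturated
            raise ConfigurationError("could not place background variant; genome too small")

        seq = genome[chrom]
        if is_del:
            pos, ref, alt = pos0, seq[pos0 - 1: pos0 + 1], seq[pos0 - 1]
        else:
            ref = seq[pos0]
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref:
                alt = "ACGT"[int(rng.integers(0, 4))]
            pos = pos0 + 1

        hits = gene_index.get(chrom, IntervalTree()).overlap(pos - 1, pos - 1 + len(ref))
        gene = sorted(h.data for h in hits)[0] if hits else None

        shared = rng.random() < share
        owners = list(SIBLINGS) if shared else [SIBLINGS[int(rng.integers(0, 3))]]
        recorded = rng.random() < config.fraction_recorded
        f1 = round(float(rng.uniform(lo, hi)), 4)
        f2 = round(min(1.0, max(1e-4, f1 * float(rng.uniform(0.7, 1.3)))), 4)

        def survives() -> bool:
            return (not recorded) or max(f1, f2) <= threshold

        if shared and gene is not None and survives():
            if gene in rare_shared_genes:
                # guard: at most one rarity-surviving shared variant per gene
                recorded = True
                f1 = round(float(rng.uniform(2 * threshold, hi)), 4)
                f2 = round(min(1.0, f1 * float(rng.uniform(0.9, 1.1))), 4)
            else:
                rare_shared_genes.add(gene)

        draw = rng.random()
        trans_parents = (list(PARENTS) if draw < 0.1
                         else ["MOTHER"] if draw < 0.55 else ["FATHER"])
        sib_call = HET_CALL
        if len(trans_parents) == 2 and not survives() and rng.random() < 0.25:
            sib_call = HOM_ALT_CALL
        gts = {s: sib_call for s in owners}
        gts.update({p: HET_CALL for p in trans_parents})
        status = (FilterStatus.FAIL if rng.random() < config.fraction_fail_filter
                  else FilterStatus.PASS)
        rsid = f"rs{1000000 + slot}" if recorded else None
        freqs = {"1000G": f1, "ESP": f2} if recorded else None
        background.append(
            emit(chrom, pos, ref, alt, gts, gene=gene, rsid=rsid,
                 freqs=freqs, status=status))

    # --- write outputs -----------------------------------------------------
    contig_lengths = {c: len(genome[c]) for c in genome}
    vcf_paths: dict[str, Path] = {}
    for member in MEMBERS:
        path = out / f"{member}.vcf"
        write_vcf(member_variants[member], path, samples=[member],
                  contig_lengths=contig_lengths)
        vcf_paths[member] = path

    ped_path = out / "family.ped"
    ped_lines = [
        "FAM1\tFATHER\t0\t0\t1\t1",
        "FAM1\tMOTHER\t0\t0\t2\t1",
    ] + [f"FAM1\t{s}\tFATHER\tMOTHER\t1\t2" for s in SIBLINGS]
    ped_path.write_text("\n".join(ped_lines) + "\n")

    return SimulatedFamily(vcf_paths=vcf_paths, ped_path=ped_path,
                           planted=planted, background=background)


def simulate(config: SimConfig, out_dir) -> tuple[SyntheticReference, SimulatedFamily]:
    """Convenience wrapper: reference and family into one output directory."""
    ref = make_reference(config, out_dir)
    fam = simulate_family(config, ref, out_dir)
    return ref, fam
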