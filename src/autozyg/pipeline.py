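"""End-to-end orchestration: simulate -> QC -> linkage -> ROH ->
critical intervals -> segregation filter -> annotation -> NMD.

Two marker-QC passes are run, mirroring how family-based mapping treats
the two analyses differently: the linkage scan uses the full pruning
cascade (noninformative, sex chromosomes, missing-in-any, Mendel
errors, MAF), while homozygosity mapping keeps low-MAF and monomorphic
markers and only drops sex-chromosome, Mendel-error, and
missing-in-any-case markers.

All stage functions are importable; :func:`run_all` additionally writes
every artifact (PED/MAP, VCF, BED, TSV reports, summary JSON) to an
output directory.  A fixed config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .intervals import CriticalIntervalSet, intersect, merge_with_gaps, span_mb
from .linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    LodResult,
    linked_regions,
    scan,
    write_lod_table,
)
from .nmd import AlleleCounts, NmdResult, nmd_classify
from .qc import QcCriteria, QcReport, prune_markers, write_qc_report
from .roh import RohParams, RohSegment, compile_boundaries, detect_roh, shared_roh, write_roh_table
from .sim import (
    SimParams,
    TruthRecord,
    emit_nmd_counts,
    emit_transcript_fixture,
    emit_wgs_table,
    gene_drop,
    make_half_sib_pedigree,
    simulate_founder_haplotypes,
)
from .types import GenomeInterval, MarkerDataset, Pedigree, VariantRecord
from .varfilter import CascadeReport, SampleRoles, run_cascade, write_cascade_report

__all__ = ["PipelineConfig", "SimBundle", "PipelineResult", "simulate_inputs",
           "analyze", "run_all"]


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    qc: QcCriteria = field(default_factory=QcCriteria)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    roh: RohParams = field(default_factory=RohParams)
    max_gap_bp: float = 1.5e6
    strict_controls: bool = False
    alpha: float = 0.05
    nmd_true_fraction: float = 0.25
    nmd_depth_gdna: int = 100
    nmd_depth_cdna: int = 100
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID
    seed: int = 0
    shared_parent: str = "sire"


@dataclass
class SimBundle:
    """Everything one simulated study comprises."""

    pedigree: Pedigree
    dataset: MarkerDataset
    truth: TruthRecord
    wgs_records: list[VariantRecord]
    roles: SampleRoles
    transcript: object
    nmd_gdna: AlleleCounts
    nmd_cdna: AlleleCounts


@dataclass
class PipelineResult:
    qc_report: QcReport
    lod_results: list[LodResult]
    linked: list[GenomeInterval]
    roh_qc_report: QcReport
    roh_segments: dict[str, list[RohSegment]]
    shared: list[GenomeInterval]
    compiled: list[GenomeInterval]
    critical: CriticalIntervalSet
    cascade_report: CascadeReport
    candidates: list
    nmd_result: NmdResult
    recovered: Optional[bool] = None

    def summary(self, truth: Optional[TruthRecord] = None, seed: Optional[int] = None) -> dict:
        s = {
            "tool_version": __version__,
            "seed": seed,
            "markers_input": self.qc_report.n_input_markers,
            "markers_linkage": self.qc_report.n_surviving_markers,
            "markers_roh": self.roh_qc_report.n_surviving_markers,
            "qc_removed": dict(self.qc_report.removed),
            "n_linked_regions": len(self.linked),
            "n_roh_segments": {
                c: len(v) for c, v in sorted(self.roh_segments.items())
            },
            "n_shared_roh": len(self.shared),
            "critical_intervals": [
                {
                    "chrom": iv.chrom,
                    "start_bp": iv.start_bp,
                    "end_bp": iv.end_bp,
                    "span_mb": span_mb(iv, 1),
                }
                for iv in self.critical
            ],
            "cascade": [
                {"step": label, "n_variants": n}
                for label, n in self.cascade_report.steps
            ],
            "cascade_per_chromosome": dict(
                sorted(self.cascade_report.per_chromosome.items())
            ),
            "candidates": [
                {
                    "chrom": r.chrom,
                    "pos_bp": r.pos_bp,
                    "ref": r.ref_allele,
                    "alt": r.alt_allele,
                    "class": csq.csq_class.value,
                    "hgvs_c": csq.hgvs_c,
                    "hgvs_p": csq.hgvs_p,
                    "truncated_fraction": csq.truncated_fraction,
                }
                for r, csq in self.candidates
            ],
            "nmd": {
                "classification": self.nmd_result.classification.value,
                "gdna_alt_fraction": self.nmd_result.gdna_alt_fraction,
                "cdna_alt_fraction": self.nmd_result.cdna_alt_fraction,
                "p_gdna_vs_half": self.nmd_result.p_gdna_vs_half,
                "p_cdna_vs_half": self.nmd_result.p_cdna_vs_half,
                "p_gdna_vs_cdna": self.nmd_result.p_gdna_vs_cdna,
            },
        }
        if truth is not None:
            s["truth"] = {
                "chrom": truth.chrom,
                "pos_bp": truth.pos_bp,
                "ref": truth.ref_allele,
                "alt": truth.alt_allele,
            }
            s["recovered"] = self.recovered
        return s


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(x) for x in rng.integers(0, 2**31 - 1, size=n)]


def simulate_inputs(config: PipelineConfig) -> SimBundle:
    """Generate one complete synthetic study with known ground truth."""
    s_pool, s_drop, s_wgs, s_tx, s_nmd = _subseeds(config.seed, 5)
    params = config.sim
    pedigree = make_half_sib_pedigree(config.shared_parent)
    pool = simulate_founder_haplotypes(params, seed=s_pool)
    dataset, truth = gene_drop(pedigree, pool, params, seed=s_drop)
    transcript, planted = emit_transcript_fixture(
        chrom=params.causal_chrom,
        variant_pos_bp=params.causal_pos_bp,
        seed=s_tx,
    )
    # the causal variant is the fixture's planted stop-gain
    truth.ref_allele = planted.ref_allele
    truth.alt_allele = planted.alt_allele
    records, roles = emit_wgs_table(truth, params, seed=s_wgs)
    gdna, cdna = emit_nmd_counts(
        config.nmd_true_fraction,
        config.nmd_depth_gdna,
        config.nmd_depth_cdna,
        seed=s_nmd,
    )
    return SimBundle(
        pedigree=pedigree,
        dataset=dataset,
        truth=truth,
        wgs_records=records,
        roles=roles,
        transcript=transcript,
        nmd_gdna=gdna,
        nmd_cdna=cdna,
    )


def analyze(bundle: SimBundle, config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage on one (simulated or loaded) study."""
    from .types import Affection

    pedigree = bundle.pedigree
    dataset = bundle.dataset
    cases = [
        ind.id
        for ind in pedigree
        if ind.affection is Affection.AFFECTED and ind.id in dataset._sample_idx
    ]

    # linkage-grade pruning (full cascade)
    link_ds, qc_report = prune_markers(pedigree, dataset, config.qc)
    lod_results = scan(pedigree, link_ds, config.disease_model, config.theta_grid)
    linked = linked_regions(lod_results)

    # homozygosity-grade pruning: keep monomorphic / low-MAF markers
    roh_criteria = QcCriteria(
        min_maf=0.0,
        excluded_chroms=config.qc.excluded_chroms,
        max_missing_in_study=0,
        drop_mendel_error_markers=config.qc.drop_mendel_error_markers,
        drop_noninformative=False,
        min_sample_call_rate=config.qc.min_sample_call_rate,
    )
    roh_ds, roh_qc = prune_markers(
        pedigree, dataset, roh_criteria, study_samples=cases
    )
    segments = {c: detect_roh(roh_ds, c, config.roh) for c in cases}
    shared = shared_roh(roh_ds, cases, config.roh, segments=segments)
    compiled = compile_boundaries(shared, roh_ds, cases)

    critical = merge_with_gaps(
        intersect(
            CriticalIntervalSet(list(linked), [("linkage",)] * len(linked)),
            CriticalIntervalSet(list(compiled), [("homozygosity",)] * len(compiled)),
        ),
        config.max_gap_bp,
    )

    candidates, cascade_report = run_cascade(
        bundle.wgs_records,
        bundle.roles,
        critical.intervals,
        [bundle.transcript] if bundle.transcript is not None else [],
        strict_controls=config.strict_controls,
    )
    nmd_result = nmd_classify(bundle.nmd_gdna, bundle.nmd_cdna, config.alpha)

    recovered = None
    if bundle.truth is not None:
        recovered = (
            len(candidates) == 1
            and candidates[0][0].key() == bundle.truth.causal_key
        )
    return PipelineResult(
        qc_report=qc_report,
        lod_results=lod_results,
        linked=linked,
        roh_qc_report=roh_qc,
        roh_segments=segments,
        shared=shared,
        compiled=compiled,
        critical=critical,
        cascade_report=cascade_report,
        candidates=candidates,
        nmd_result=nmd_result,
        recovered=recovered,
    )


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Simulate one study, analyze it, and write every artifact.

    Returns the summary dict (also written as ``summary.json``).
    """
    from . import io as aio
    from .intervals import write_span_report

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_inputs(config)
    result = analyze(bundle, config)

    aio.write_ped_map(
        bundle.pedigree, bundle.dataset, out / "family.ped", out / "family.map"
    )
    aio.write_vcf(
        bundle.wgs_records,
        out / "wgs.vcf",
        samples=sorted(bundle.roles.cases)
        + sorted(bundle.roles.carriers)
        + sorted(bundle.roles.controls),
        contig_lengths={
            c: config.sim.chrom_length_bp for c in config.sim.chrom_names
        },
    )
    aio.write_exon_table(bundle.transcript, out / "exons.tsv")
    aio.write_cds_fasta(bundle.transcript, out / "cds.fa")
    aio.write_counts_tsv([bundle.nmd_gdna, bundle.nmd_cdna], out / "counts.tsv")
    write_qc_report(result.qc_report, out / "qc.tsv")
    write_lod_table(result.lod_results, out / "lod.tsv")
    aio.write_bed(result.linked, out / "linked_regions.bed")
    write_roh_table(
        [s for segs in result.roh_segments.values() for s in segs],
        out / "roh.tsv",
    )
    aio.write_bed(result.compiled, out / "shared_roh.bed")
    aio.write_bed(result.critical.intervals, out / "critical.bed")
    write_span_report(result.critical, out / "spans.tsv")
    write_cascade_report(result.cascade_report, out / "cascade.tsv")
    aio.write_vcf(
        [r for r, _ in result.candidates],
        out / "candidates.vcf",
        samples=sorted(bundle.roles.cases) + sorted(bundle.roles.carriers),
        contig_lengths={
            c: config.sim.chrom_length_bp for c in config.sim.chrom_names
        },
    )
    truth_doc = {
        "chrom": bundle.truth.chrom,
        "pos_bp": bundle.truth.pos_bp,
        "ref": bundle.truth.ref_allele,
        "alt": bundle.truth.alt_allele,
        "causal_dosage": bundle.truth.causal_dosage,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    (out / "nmd.json").write_text(
        json.dumps(
            result.summary(bundle.truth, config.seed)["nmd"], indent=2, sort_keys=True
        )
    )
    summary = result.summary(bundle.truth, config.seed)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
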