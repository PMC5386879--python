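"""Mendelian segregation filtering of multi-sample variant calls.

The cascade selects candidate variants for a fully penetrant recessive
disorder: a variant must be homozygous alternate in every case,
heterozygous in every obligate carrier, and homozygous reference (or
missing) in every population control; survivors are then restricted to
the critical intervals and finally to protein-changing consequences.
The report mirrors the familiar filtering-step/variant-count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import GenomeInterval, GenotypeCall, VariantRecord

__all__ = [
    "SampleRoles",
    "CascadeReport",
    "segregation_filter",
    "genotype_pattern_filter",
    "restrict_to_intervals",
    "run_cascade",
]


@dataclass(frozen=True)
class SampleRoles:
    cases: frozenset[str]
    carriers: frozenset[str]
    controls: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "cases", frozenset(self.cases))
        object.__setattr__(self, "carriers", frozenset(self.carriers))
        object.__setattr__(self, "controls", frozenset(self.controls))
        if not self.cases or not self.carriers:
            raise ValueError("cases and carriers must be non-empty")
        for a, b in (
            (self.cases, self.carriers),
            (self.cases, self.controls),
            (self.carriers, self.controls),
        ):
            if a & b:
                raise ValueError(f"sample roles overlap: {sorted(a & b)}")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.cases | self.carriers | self.controls


@dataclass
class CascadeReport:
    """Ordered filtering steps with surviving-variant counts."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    per_chromosome: dict[str, int] = field(default_factory=dict)

    def add(self, label: str, count: int) -> None:
        self.steps.append((label, count))

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.steps]

    def is_monotone(self) -> bool:
        c = self.counts
        return all(a >= b for a, b in zip(c, c[1:]))


def _check_roles_present(records: Sequence[VariantRecord], roles: SampleRoles) -> None:
    if not records:
        return
    present = set(records[0].genotypes)
    missing = sorted(roles.all_ids - present)
    if missing:
        raise ValueError(
            f"role sample ids absent from variant records: {missing}"
        )


def genotype_pattern_filter(
    records: Sequence[VariantRecord], roles: SampleRoles
) -> list[VariantRecord]:
    """Keep records homozygous-alternate in every case and heterozygous
    in every carrier (no control condition)."""
    _check_roles_present(records, roles)
    out = []
    for r in records:
        if all(r.genotypes[c] == GenotypeCall.HOM_ALT for c in roles.cases) and all(
            r.genotypes[c] == GenotypeCall.HET for c in roles.carriers
        ):
            out.append(r)
    return out


def segregation_filter(
    records: Sequence[VariantRecord],
    roles: SampleRoles,
    strict_controls: bool = False,
) -> list[VariantRecord]:
    """Full recessive segregation filter.

    Controls must be homozygous reference; a missing control call also
    passes unless ``strict_controls`` is set.  An empty control set makes
    the control condition vacuously true (a warning is emitted).
    """
    _check_roles_present(records, roles)
    if not roles.controls:
        warnings.warn("control set is empty; control condition is vacuous")
    ok_control = (
        {GenotypeCall.HOM_REF}
        if strict_controls
        else {GenotypeCall.HOM_REF, GenotypeCall.MISSING}
    )
    out = []
    for r in genotype_pattern_filter(records, roles):
        if all(r.genotypes[c] in ok_control for c in roles.controls):
            out.append(r)
    return out


def restrict_to_intervals(
    records: Sequence[VariantRecord], intervals: Iterable[GenomeInterval]
) -> list[VariantRecord]:
    """Keep records whose position falls inside any interval (both
    interval endpoints inclusive)."""
    ivs = list(intervals)
    return [
        r
        for r in records
        if any(iv.contains(r.chrom, r.pos_bp) for iv in ivs)
    ]


def run_cascade(
    records: Sequence[VariantRecord],
    roles: SampleRoles,
    intervals: Iterable[GenomeInterval],
    transcript_models: Sequence = (),
    strict_controls: bool = False,
):
    """Apply the full cascade and report per-step survivor counts.

    Returns ``(candidates, report)`` where ``candidates`` is a list of
    ``(record, consequence)`` pairs for the protein-changing survivors
    inside the critical intervals.  The report's main chain is
    monotone; per-chromosome interval counts are reported separately.
    """
    from .consequence import PROTEIN_CHANGING, annotate_against

    ivs = list(intervals)
    report = CascadeReport()
    s1 = genotype_pattern_filter(records, roles)
    report.add("cases hom-alt and carriers het", len(s1))
    s2 = segregation_filter(records, roles, strict_controls=strict_controls)
    report.add("segregating genome-wide (controls clear)", len(s2))
    chroms = sorted({iv.chrom for iv in ivs})
    for chrom in chroms:
        sub = [iv for iv in ivs if iv.chrom == chrom]
        report.per_chromosome[chrom] = len(restrict_to_intervals(s2, sub))
    s3 = restrict_to_intervals(s2, ivs)
    report.add("segregating in critical intervals", len(s3))
    candidates = []
    for r in s3:
        csq = annotate_against(transcript_models, r)
        if csq.csq_class in PROTEIN_CHANGING:
            candidates.append((r, csq))
    report.add("protein-changing in critical intervals", len(candidates))
    return candidates, report


def write_cascade_report(report: CascadeReport, path) -> None:
    from .io import _provenance

    with open(path, "w") as fh:
        fh.write(_provenance("segregation-filter cascade"))
        fh.write("filtering_step\tn_variants\n")
        for label, count in report.steps:
            fh.write(f"{label}\t{count}\n")
        for chrom, count in sorted(report.per_chromosome.items()):
            fh.write(f"segregating in critical interval on chr. {chrom}\t{count}\n")
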