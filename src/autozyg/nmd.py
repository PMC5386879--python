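"""Allele-balance test for nonsense-mediated decay.

In a heterozygous carrier, genomic DNA shows the two alleles at a 1:1
ratio; if the premature-stop transcript is degraded by NMD, the mutant
allele is underrepresented in cDNA.  The qualitative chromatogram
evidence is formalized here as integer allele counts (peak heights or
read counts): each source's alternate-allele fraction is tested against
0.5 with an exact two-sided binomial test, and the two sources are
compared with Fisher's exact test on the 2x2 count table.  Exact tests
are used throughout because depths may be small.

Classification (direction is decided on the alternate allele; reported
p-values stay two-sided):

* ``complete_absence`` — no mutant allele at all in cDNA while gDNA is
  consistent with 1:1;
* ``partial_nmd`` — cDNA significantly depleted below 0.5, gDNA not
  significantly off 1:1, and the two sources significantly different;
* ``no_depletion`` — no test significant;
* ``inconclusive`` — any other pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy.stats import binomtest, fisher_exact

__all__ = ["AlleleCounts", "NmdClass", "NmdResult", "nmd_classify"]


@dataclass(frozen=True)
class AlleleCounts:
    source: str  # "gdna" or "cdna"
    ref_count: int
    alt_count: int

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be >= 0")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        if self.total == 0:
            raise ValueError(f"{self.source}: zero total depth")
        return self.alt_count / self.total


class NmdClass(str, Enum):
    NO_DEPLETION = "no_depletion"
    PARTIAL_NMD = "partial_nmd"
    COMPLETE_ABSENCE = "complete_absence"
    INCONCLUSIVE = "inconclusive"


@dataclass
class NmdResult:
    gdna_alt_fraction: float
    cdna_alt_fraction: float
    p_gdna_vs_half: float
    p_cdna_vs_half: float
    p_gdna_vs_cdna: float
    classification: NmdClass


def nmd_classify(
    gdna: AlleleCounts, cdna: AlleleCounts, alpha: float = 0.05
) -> NmdResult:
    """Classify evidence for NMD from paired gDNA/cDNA allele counts."""
    if gdna.total == 0 or cdna.total == 0:
        raise ValueError("both gDNA and cDNA must have total depth > 0")
    p_g = binomtest(gdna.alt_count, gdna.total, 0.5).pvalue
    p_c = binomtest(cdna.alt_count, cdna.total, 0.5).pvalue
    _, p_gc = fisher_exact(
        [[gdna.ref_count, gdna.alt_count], [cdna.ref_count, cdna.alt_count]]
    )
    frac_g = gdna.alt_fraction
    frac_c = cdna.alt_fraction
    gdna_balanced = p_g >= alpha
    cdna_depleted = p_c < alpha and frac_c < 0.5
    sources_differ = p_gc < alpha
    if cdna.alt_count == 0 and gdna_balanced:
        cls = NmdClass.COMPLETE_ABSENCE
    elif cdna_depleted and gdna_balanced and sources_differ:
        cls = NmdClass.PARTIAL_NMD
    elif p_g >= alpha and p_c >= alpha and p_gc >= alpha:
        cls = NmdClass.NO_DEPLETION
    else:
        cls = NmdClass.INCONCLUSIVE
    return NmdResult(
        gdna_alt_fraction=frac_g,
        cdna_alt_fraction=frac_c,
        p_gdna_vs_half=float(p_g),
        p_cdna_vs_half=float(p_c),
        p_gdna_vs_cdna=float(p_gc),
        classification=cls,
    )
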