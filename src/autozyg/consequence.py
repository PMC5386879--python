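"""Transcript-aware variant consequence annotation.

Maps genomic positions into CDS coordinates (HGVS ``c.`` numbering:
nucleotide 1 is the A of the initiator ATG), translates reference and
alternate codons with the standard nuclear code, classifies the change,
and emits HGVS ``c.``/``p.`` strings.  For stop-gains the truncated
fraction of the open reading frame is reported: a premature stop at
codon *k* in a protein of *L* codons removes ``(L - (k - 1)) / L`` of
the ORF (the stop codon's own position counts as lost).

Codon and protein numbering is 1-based with the initiator methionine as
residue 1.  Splice annotation is restricted to the canonical +/-2 bp
intronic dinucleotides.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .types import GenomeInterval, VariantRecord

__all__ = [
    "ConsequenceClass",
    "PROTEIN_CHANGING",
    "TranscriptModel",
    "Consequence",
    "genomic_to_cds",
    "codon_of",
    "annotate",
    "annotate_against",
    "truncated_fraction",
    "parse_hgvs_c",
]


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    NONCODING = "noncoding"


PROTEIN_CHANGING = {
    ConsequenceClass.MISSENSE,
    ConsequenceClass.NONSENSE,
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.INFRAME_INDEL,
    ConsequenceClass.SPLICE,
}

_STOPS = set(standard_dna_table.stop_codons)


class ReferenceMismatchError(ValueError):
    """The variant's reference allele disagrees with the CDS sequence."""


@dataclass
class TranscriptModel:
    """A single-transcript gene model with its spliced CDS sequence.

    ``cds_sequence`` is on the coding strand, starts with ATG, has
    length divisible by 3, and contains no internal stop codon (a
    terminal stop codon may be present or absent; the protein length in
    codons is simply ``len(cds_sequence) // 3``).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.cds_sequence = self.cds_sequence.upper()
        exons = sorted(self.exons, key=lambda iv: iv.start_bp)
        for a, b in zip(exons, exons[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError("exons overlap")
        self.exons = exons
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not self.cds_sequence.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        n_codons = len(self.cds_sequence) // 3
        for k in range(n_codons - 1):
            if self.cds_sequence[3 * k : 3 * k + 3] in _STOPS:
                raise ValueError(f"internal stop codon at codon {k + 1}")
        coding_len = sum(
            seg.end_bp - seg.start_bp + 1 for seg in self.coding_segments
        )
        if coding_len != len(self.cds_sequence):
            raise ValueError(
                f"coding exon span ({coding_len} bp) does not match CDS "
                f"length ({len(self.cds_sequence)} bp)"
            )

    @cached_property
    def coding_segments(self) -> list[GenomeInterval]:
        """Exon pieces inside [cds_start, cds_end], in genomic order."""
        cds_iv = GenomeInterval(self.chrom, self.cds_start, self.cds_end)
        segs = [
            seg
            for ex in self.exons
            if (seg := ex.intersection(cds_iv)) is not None
        ]
        return segs

    @property
    def protein_length_codons(self) -> int:
        return len(self.cds_sequence) // 3


@dataclass
class Consequence:
    csq_class: ConsequenceClass
    hgvs_c: str
    hgvs_p: Optional[str] = None
    codon_index: Optional[int] = None
    truncated_fraction: Optional[float] = None
    transcript_id: Optional[str] = None
    splice_distance: Optional[int] = None


def genomic_to_cds(model: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """1-based CDS coordinate of a genomic position, or ``None`` for
    intronic/UTR/intergenic positions.  Strand-aware: on the minus
    strand CDS coordinates count from the 3' genomic side."""
    segs = model.coding_segments
    if model.strand == "-":
        segs = list(reversed(segs))
    offset = 0
    for seg in segs:
        if seg.start_bp <= genomic_pos <= seg.end_bp:
            if model.strand == "+":
                return offset + (genomic_pos - seg.start_bp) + 1
            return offset + (seg.end_bp - genomic_pos) + 1
        offset += seg.end_bp - seg.start_bp + 1
    return None


def splice_context(
    model: TranscriptModel, genomic_pos: int
) -> Optional[tuple[int, int]]:
    """For an intronic position: (distance into the intron, nearest
    flanking CDS coordinate signed by HGVS convention) -> returns
    (distance, anchor_cds_pos, sign) packed as (distance, signed_anchor);
    ``None`` when the position is not intronic.

    The signed anchor is positive offset from the upstream exon's last
    coding base (``c.N+d``) or negative offset to the downstream exon's
    first coding base (``c.N-d``), in transcript orientation.
    """
    exons = model.exons
    for a, b in zip(exons, exons[1:]):
        if a.end_bp < genomic_pos < b.start_bp:
            dist_left = genomic_pos - a.end_bp  # bases into intron from left exon
            dist_right = b.start_bp - genomic_pos
            if model.strand == "+":
                if dist_left <= dist_right:
                    anchor = genomic_to_cds(model, a.end_bp)
                    return (dist_left, anchor or 0, +1)
                anchor = genomic_to_cds(model, b.start_bp)
                return (dist_right, anchor or 0, -1)
            else:
                # transcript reads right-to-left: left exon is downstream
                if dist_right <= dist_left:
                    anchor = genomic_to_cds(model, b.start_bp)
                    return (dist_right, anchor or 0, +1)
                anchor = genomic_to_cds(model, a.end_bp)
                return (dist_left, anchor or 0, -1)
    return None


def codon_of(cds_pos: int) -> tuple[int, int]:
    """(codon_index, offset_in_codon), both 1-based: codon = ceil(p/3),
    offset = ((p - 1) mod 3) + 1."""
    if cds_pos < 1:
        raise ValueError("CDS position must be >= 1")
    return math.ceil(cds_pos / 3), ((cds_pos - 1) % 3) + 1


def truncated_fraction(codon_index: int, protein_length_codons: int) -> float:
    """Fraction of ORF codons at or after a premature stop."""
    if not 1 <= codon_index <= protein_length_codons:
        raise ValueError(
            f"codon_index {codon_index} outside 1..{protein_length_codons}"
        )
    return (protein_length_codons - (codon_index - 1)) / protein_length_codons


_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL)[::-1]


def _aa3(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return seq3(str(Seq(codon).translate()))


def annotate(model: TranscriptModel, variant: VariantRecord) -> Consequence:
    """Annotate one biallelic variant against one transcript model."""
    if variant.chrom != model.chrom:
        return Consequence(
            ConsequenceClass.NONCODING,
            hgvs_c=f"g.{variant.pos_bp}{variant.ref_allele}>{variant.alt_allele}",
            transcript_id=model.transcript_id,
        )
    if variant.is_snv:
        return _annotate_snv(model, variant)
    return _annotate_indel(model, variant)


def _annotate_snv(model: TranscriptModel, variant: VariantRecord) -> Consequence:
    pos = variant.pos_bp
    cds_pos = genomic_to_cds(model, pos)
    if cds_pos is None:
        ctx = splice_context(model, pos)
        if ctx is not None:
            dist, anchor, sign = ctx
            ref, alt = variant.ref_allele, variant.alt_allele
            if model.strand == "-":
                ref, alt = _revcomp(ref), _revcomp(alt)
            hgvs = f"c.{anchor}{'+' if sign > 0 else '-'}{dist}{ref}>{alt}"
            if dist <= 2:
                return Consequence(
                    ConsequenceClass.SPLICE,
                    hgvs_c=hgvs,
                    transcript_id=model.transcript_id,
                    splice_distance=dist,
                )
            return Consequence(
                ConsequenceClass.NONCODING,
                hgvs_c=hgvs,
                transcript_id=model.transcript_id,
                splice_distance=dist,
            )
        return Consequence(
            ConsequenceClass.NONCODING,
            hgvs_c=f"g.{pos}{variant.ref_allele}>{variant.alt_allele}",
            transcript_id=model.transcript_id,
        )
    ref = variant.ref_allele
    alt = variant.alt_allele
    if model.strand == "-":
        ref, alt = _revcomp(ref), _revcomp(alt)
    expected = model.cds_sequence[cds_pos - 1]
    if ref != expected:
        raise ReferenceMismatchError(
            f"{model.transcript_id}: reference allele {variant.ref_allele!r} at "
            f"{variant.chrom}:{variant.pos_bp} maps to CDS position {cds_pos} "
            f"whose base is {expected!r}"
        )
    codon_idx, offset = codon_of(cds_pos)
    codon_start = 3 * (codon_idx - 1)
    ref_codon = model.cds_sequence[codon_start : codon_start + 3]
    alt_codon = ref_codon[: offset - 1] + alt + ref_codon[offset:]
    ref_aa = _aa3(ref_codon)
    alt_aa = _aa3(alt_codon)
    hgvs_c = f"c.{cds_pos}{ref}>{alt}"
    if alt_aa == "*" and ref_aa != "*":
        return Consequence(
            ConsequenceClass.NONSENSE,
            hgvs_c=hgvs_c,
            hgvs_p=f"p.{ref_aa}{codon_idx}*",
            codon_index=codon_idx,
            truncated_fraction=truncated_fraction(
                codon_idx, model.protein_length_codons
            ),
            transcript_id=model.transcript_id,
        )
    if alt_aa == ref_aa:
        return Consequence(
            ConsequenceClass.SYNONYMOUS,
            hgvs_c=hgvs_c,
            hgvs_p=f"p.{ref_aa}{codon_idx}=",
            codon_index=codon_idx,
            transcript_id=model.transcript_id,
        )
    return Consequence(
        ConsequenceClass.MISSENSE,
        hgvs_c=hgvs_c,
        hgvs_p=f"p.{ref_aa}{codon_idx}{alt_aa}",
        codon_index=codon_idx,
        transcript_id=model.transcript_id,
    )


def _annotate_indel(model: TranscriptModel, variant: VariantRecord) -> Consequence:
    """Length-changing alleles (VCF anchored-base convention)."""
    ref, alt = variant.ref_allele, variant.alt_allele
    delta = len(alt) - len(ref)
    # genomic footprint of the changed bases (after the shared anchor base)
    if delta < 0:  # deletion of bases pos+1 .. pos+len(ref)-1
        g_lo, g_hi = variant.pos_bp + 1, variant.pos_bp + len(ref) - 1
    elif delta > 0:  # insertion between pos and pos+1
        g_lo = g_hi = variant.pos_bp
    else:  # same-length multi-base substitution
        g_lo, g_hi = variant.pos_bp, variant.pos_bp + len(ref) - 1
    footprint = GenomeInterval(model.chrom, g_lo, g_hi)
    if not any(seg.overlaps(footprint) for seg in model.coding_segments):
        return Consequence(
            ConsequenceClass.NONCODING,
            hgvs_c=f"g.{variant.pos_bp}{ref}>{alt}",
            transcript_id=model.transcript_id,
        )
    cds_positions = sorted(
        p
        for p in (genomic_to_cds(model, g_lo), genomic_to_cds(model, g_hi))
        if p is not None
    ) or [
        genomic_to_cds(model, seg.start_bp)
        for seg in model.coding_segments
        if seg.overlaps(footprint)
    ][:1]
    cds_lo = cds_positions[0]
    cds_hi = cds_positions[-1]
    codon_idx, _ = codon_of(cds_lo)
    codon_start = 3 * (codon_idx - 1)
    ref_aa = _aa3(model.cds_sequence[codon_start : codon_start + 3])
    if delta < 0:
        hgvs_c = f"c.{cds_lo}_{cds_hi}del" if cds_hi > cds_lo else f"c.{cds_lo}del"
    elif delta > 0:
        ins = alt[1:]
        if model.strand == "-":
            ins = _revcomp(ins)
        hgvs_c = f"c.{cds_lo}_{cds_lo + 1}ins{ins}"
    else:
        hgvs_c = f"c.{cds_lo}_{cds_hi}delins{alt}"
    if delta % 3 != 0:
        return Consequence(
            ConsequenceClass.FRAMESHIFT,
            hgvs_c=hgvs_c,
            hgvs_p=f"p.({ref_aa}{codon_idx}fs)",
            codon_index=codon_idx,
            transcript_id=model.transcript_id,
        )
    return Consequence(
        ConsequenceClass.INFRAME_INDEL,
        hgvs_c=hgvs_c,
        codon_index=codon_idx,
        transcript_id=model.transcript_id,
    )


def annotate_against(
    models: Sequence[TranscriptModel], variant: VariantRecord
) -> Consequence:
    """Annotate against a transcript set: the most severe consequence
    wins (protein-changing > synonymous > noncoding)."""
    if not models:
        return Consequence(
            ConsequenceClass.NONCODING,
            hgvs_c=f"g.{variant.pos_bp}{variant.ref_allele}>{variant.alt_allele}",
        )
    severity = {
        ConsequenceClass.NONSENSE: 6,
        ConsequenceClass.FRAMESHIFT: 5,
        ConsequenceClass.SPLICE: 4,
        ConsequenceClass.MISSENSE: 3,
        ConsequenceClass.INFRAME_INDEL: 3,
        ConsequenceClass.SYNONYMOUS: 2,
        ConsequenceClass.NONCODING: 1,
    }
    best = None
    for m in models:
        csq = annotate(m, variant)
        if best is None or severity[csq.csq_class] > severity[best.csq_class]:
            best = csq
    return best


_HGVS_SNV = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del$")
_HGVS_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_hgvs_c(s: str) -> dict:
    """Parse the subset of HGVS ``c.`` strings this package emits."""
    m = _HGVS_SNV.match(s)
    if m:
        return {
            "kind": "snv",
            "cds_pos": int(m.group(1)),
            "ref": m.group(2),
            "alt": m.group(3),
        }
    m = _HGVS_DEL.match(s)
    if m:
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        return {"kind": "del", "cds_lo": lo, "cds_hi": hi}
    m = _HGVS_INS.match(s)
    if m:
        return {
            "kind": "ins",
            "cds_lo": int(m.group(1)),
            "cds_hi": int(m.group(2)),
            "seq": m.group(3),
        }
    raise ValueError(f"unsupported HGVS c. string: {s!r}")
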