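"""Consequence annotation: CDS mapping, codon arithmetic, HGVS naming,
and agreement with a naive mutate-and-translate oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from autozyg.consequence import (
    ConsequenceClass,
    ReferenceMismatchError,
    annotate,
    codon_of,
    genomic_to_cds,
    parse_hgvs_c,
    truncated_fraction,
)
from autozyg.sim import emit_transcript_fixture
from autozyg.types import VariantRecord


def _cds_to_genomic(model, cds_pos):
    """Test-side inverse of genomic_to_cds (linear scan)."""
    segs = model.coding_segments
    if model.strand == "-":
        segs = list(reversed(segs))
    off = 0
    for seg in segs:
        size = seg.end_bp - seg.start_bp + 1
        if off < cds_pos <= off + size:
            if model.strand == "+":
                return seg.start_bp + (cds_pos - off - 1)
            return seg.end_bp - (cds_pos - off - 1)
        off += size
    raise AssertionError("cds position outside CDS")


class TestCodonOf:
    @pytest.mark.parametrize(
        "cds_pos,expected",
        [(388, (130, 1)), (3, (1, 3)), (4, (2, 1)), (1, (1, 1)), (6, (2, 3))],
    )
    def test_examples(self, cds_pos, expected):
        assert codon_of(cds_pos) == expected

    def test_inverse_identity_over_range(self):
        for p in range(1, 400):
            codon, off = codon_of(p)
            assert 3 * (codon - 1) + off == p

    def test_position_below_one_rejected(self):
        with pytest.raises(ValueError):
            codon_of(0)


class TestGenomicToCds:
    def test_first_cds_base_maps_to_one(self):
        model, _ = emit_transcript_fixture(100, 40, "+")
        assert genomic_to_cds(model, model.coding_segments[0].start_bp) == 1

    def test_fixture_variant_maps_to_planted_offset(self):
        model, var = emit_transcript_fixture(650, 130, "+")
        assert genomic_to_cds(model, var.pos_bp) == 388
        model, var = emit_transcript_fixture(650, 130, "-")
        assert genomic_to_cds(model, var.pos_bp) == 388

    def test_intronic_position_is_none(self):
        model, _ = emit_transcript_fixture(100, 40, "+", intron_bp=500)
        intronic = model.exons[0].end_bp + 10
        assert genomic_to_cds(model, intronic) is None

    def test_roundtrip_with_inverse(self):
        for strand in ("+", "-"):
            model, _ = emit_transcript_fixture(80, 30, strand, seed=4)
            for p in (1, 2, 77, 120, 239, 240):
                assert genomic_to_cds(model, _cds_to_genomic(model, p)) == p


class TestAnnotate:
    def test_planted_stop_gain(self):
        model, var = emit_transcript_fixture(650, 130, "+")
        csq = annotate(model, var)
        assert csq.csq_class is ConsequenceClass.NONSENSE
        assert csq.hgvs_c == "c.388G>T"
        assert csq.hgvs_p == "p.Glu130*"
        assert csq.codon_index == 130
        assert csq.truncated_fraction == pytest.approx(521 / 650)

    def test_synonymous_third_base(self):
        # GAG -> GAA is still Glu
        model, _ = emit_transcript_fixture(650, 130, "+")
        g = _cds_to_genomic(model, 390)
        csq = annotate(model, VariantRecord(model.chrom, g, "G", "A"))
        assert csq.csq_class is ConsequenceClass.SYNONYMOUS
        assert csq.hgvs_c == "c.390G>A"
        assert csq.hgvs_p == "p.Glu130="

    def test_missense(self):
        # GAG -> CAG: Glu -> Gln
        model, _ = emit_transcript_fixture(650, 130, "+")
        g = _cds_to_genomic(model, 388)
        csq = annotate(model, VariantRecord(model.chrom, g, "G", "C"))
        assert csq.csq_class is ConsequenceClass.MISSENSE
        assert csq.hgvs_p == "p.Glu130Gln"

    def test_two_bp_deletion_is_frameshift(self):
        model, _ = emit_transcript_fixture(100, 40, "+")
        g = _cds_to_genomic(model, 10)
        ref = model.cds_sequence[9:12]  # anchored 3-base ref, 2 deleted
        csq = annotate(model, VariantRecord(model.chrom, g, ref, ref[0]))
        assert csq.csq_class is ConsequenceClass.FRAMESHIFT
        assert "fs" in (csq.hgvs_p or "")

    def test_three_bp_deletion_is_inframe(self):
        model, _ = emit_transcript_fixture(100, 40, "+")
        g = _cds_to_genomic(model, 10)
        ref = model.cds_sequence[9:13]
        csq = annotate(model, VariantRecord(model.chrom, g, ref, ref[0]))
        assert csq.csq_class is ConsequenceClass.INFRAME_INDEL

    def test_reference_mismatch_is_error(self):
        model, var = emit_transcript_fixture(650, 130, "+")
        wrong = VariantRecord(model.chrom, var.pos_bp, "A", "T")
        with pytest.raises(ReferenceMismatchError):
            annotate(model, wrong)

    def test_other_chromosome_is_noncoding(self):
        model, _ = emit_transcript_fixture(100, 40, "+")
        csq = annotate(model, VariantRecord("99", 1000, "A", "T"))
        assert csq.csq_class is ConsequenceClass.NONCODING

    def test_canonical_splice_dinucleotides(self):
        model, _ = emit_transcript_fixture(100, 40, "+", intron_bp=500)
        donor = model.exons[0].end_bp
        for offset, expected in [
            (1, ConsequenceClass.SPLICE),
            (2, ConsequenceClass.SPLICE),
            (3, ConsequenceClass.NONCODING),
        ]:
            csq = annotate(
                model, VariantRecord(model.chrom, donor + offset, "A", "T")
            )
            assert csq.csq_class is expected, offset

    def test_strand_symmetry_on_random_coding_snvs(self):
        rng = np.random.default_rng(8)
        plus, _ = emit_transcript_fixture(120, 50, "+", seed=6)
        minus, _ = emit_transcript_fixture(120, 50, "-", seed=6)
        compl = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(40):
            p = int(rng.integers(1, 361))
            ref = plus.cds_sequence[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            a = annotate(
                plus, VariantRecord(plus.chrom, _cds_to_genomic(plus, p), ref, str(alt))
            )
            b = annotate(
                minus,
                VariantRecord(
                    minus.chrom, _cds_to_genomic(minus, p), compl[ref], compl[str(alt)]
                ),
            )
            assert (a.csq_class, a.hgvs_c, a.hgvs_p) == (b.csq_class, b.hgvs_c, b.hgvs_p)

    def test_agrees_with_mutate_and_translate_oracle(self):
        rng = np.random.default_rng(11)
        for seed in range(4):
            model, _ = emit_transcript_fixture(
                int(rng.integers(50, 200)), int(rng.integers(2, 40)),
                rng.choice(["+", "-"]), seed=seed,
            )
            cds = model.cds_sequence
            ref_protein = str(Seq(cds).translate())
            for _ in range(30):
                p = int(rng.integers(1, len(cds) + 1))
                ref_c = cds[p - 1]
                alt_c = str(rng.choice([b for b in "ACGT" if b != ref_c]))
                g = _cds_to_genomic(model, p)
                compl = {"A": "T", "C": "G", "G": "C", "T": "A"}
                if model.strand == "+":
                    var = VariantRecord(model.chrom, g, ref_c, alt_c)
                else:
                    var = VariantRecord(model.chrom, g, compl[ref_c], compl[alt_c])
                csq = annotate(model, var)
                mutant = cds[: p - 1] + alt_c + cds[p:]
                alt_protein = str(Seq(mutant).translate())
                if "*" in alt_protein and "*" not in ref_protein:
                    expected = ConsequenceClass.NONSENSE
                elif alt_protein == ref_protein:
                    expected = ConsequenceClass.SYNONYMOUS
                else:
                    expected = ConsequenceClass.MISSENSE
                assert csq.csq_class is expected


class TestTruncatedFraction:
    def test_examples(self):
        assert truncated_fraction(130, 650) == pytest.approx(521 / 650)
        assert truncated_fraction(1, 650) == 1.0
        assert truncated_fraction(650, 650) == pytest.approx(1 / 650)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            truncated_fraction(0, 650)
        with pytest.raises(ValueError):
            truncated_fraction(651, 650)


class TestHgvsRoundtrip:
    def test_snv_parse_format_identity(self):
        model, _ = emit_transcript_fixture(120, 50, "+", seed=2)
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = int(rng.integers(1, 361))
            ref = model.cds_sequence[p - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            csq = annotate(
                model, VariantRecord(model.chrom, _cds_to_genomic(model, p), ref, alt)
            )
            parsed = parse_hgvs_c(csq.hgvs_c)
            assert parsed == {"kind": "snv", "cds_pos": p, "ref": ref, "alt": alt}

    def test_del_and_ins_forms(self):
        assert parse_hgvs_c("c.10_12del") == {"kind": "del", "cds_lo": 10, "cds_hi": 12}
        assert parse_hgvs_c("c.10del") == {"kind": "del", "cds_lo": 10, "cds_hi": 10}
        assert parse_hgvs_c("c.10_11insACG") == {
            "kind": "ins", "cds_lo": 10, "cds_hi": 11, "seq": "ACG",
        }
        with pytest.raises(ValueError):
            parse_hgvs_c("c.banana")
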