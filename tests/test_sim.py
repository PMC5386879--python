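"""Gene-dropping simulator: determinism, Mendelian consistency, and the
statistical properties of the generated study."""

import numpy as np
import pytest

from autozyg import io as aio
from autozyg.consequence import annotate
from autozyg.qc import detect_mendel_errors
from autozyg.sim import (
    SimParams,
    emit_nmd_counts,
    emit_transcript_fixture,
    emit_wgs_table,
    gene_drop,
    make_half_sib_pedigree,
    simulate_founder_haplotypes,
)
from autozyg.types import Affection, GenotypeCall
from autozyg.varfilter import segregation_filter

SMALL = SimParams(n_chromosomes=2, n_markers_per_chrom=300,
                  chrom_length_bp=20_000_000, causal_pos_bp=10_000_000,
                  n_background_variants=50)


class TestFounderHaplotypes:
    def test_same_seed_identical_pool(self):
        a = simulate_founder_haplotypes(SMALL, seed=11)
        b = simulate_founder_haplotypes(SMALL, seed=11)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.markers == b.markers
        c = simulate_founder_haplotypes(SMALL, seed=12)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_folded_beta_maf_mean(self):
        # Beta(1,1) allele frequencies: E[min(p, 1-p)] = 1/4 exactly
        params = SimParams(
            n_chromosomes=4, n_markers_per_chrom=2000,
            founder_maf_beta=(1.0, 1.0),
        )
        pool = simulate_founder_haplotypes(params, seed=5)
        maf = np.minimum(pool.allele_freqs, 1 - pool.allele_freqs)
        se = maf.std(ddof=1) / np.sqrt(maf.size)
        assert abs(maf.mean() - 0.25) < 3 * se

    def test_causal_on_exactly_one_pool_haplotype(self):
        pool = simulate_founder_haplotypes(SMALL, seed=3)
        assert 0 <= pool.causal_hap_index < pool.pool_size


class TestGeneDrop:
    def test_no_recombination_gametes_are_intact_parental_haplotypes(self, half_sib):
        params = SimParams(
            n_chromosomes=2, n_markers_per_chrom=200,
            chrom_length_bp=20_000_000, causal_pos_bp=10_000_000,
            recomb_rate_cM_per_Mb=0.0, missing_rate=0.0,
            genotype_error_rate=0.0,
        )
        pool = simulate_founder_haplotypes(params, seed=2)
        ds, truth = gene_drop(half_sib, pool, params, seed=2)
        slices = ds.chrom_slices().values()
        for child in ("CH1", "CH2", "CH3"):
            ind = half_sib[child]
            for gam, parent in zip(truth.phased[child], (ind.sire_id, ind.dam_id)):
                pa, pb = truth.phased[parent]
                for sl in slices:  # chromosomes assort independently
                    assert np.array_equal(gam[sl], pa[sl]) or np.array_equal(
                        gam[sl], pb[sl]
                    )

    def test_affected_are_homozygous_causal_and_parents_carry(self, half_sib):
        pool = simulate_founder_haplotypes(SMALL, seed=4)
        _, truth = gene_drop(half_sib, pool, SMALL, seed=4)
        for iid in truth.affected_ids:
            assert truth.causal_dosage[iid] == 2
        for ind in half_sib.nonfounders:
            if ind.affection is Affection.AFFECTED:
                assert truth.causal_dosage[ind.sire_id] >= 1
                assert truth.causal_dosage[ind.dam_id] >= 1

    def test_mendel_error_counts_track_error_rate(self, half_sib):
        clean = SimParams(
            n_chromosomes=4, n_markers_per_chrom=3000,
            genotype_error_rate=0.0, missing_rate=0.0,
        )
        pool = simulate_founder_haplotypes(clean, seed=6)
        ds, _ = gene_drop(half_sib, pool, clean, seed=6)
        assert detect_mendel_errors(half_sib, ds) == []
        noisy = SimParams(
            n_chromosomes=4, n_markers_per_chrom=3000,
            genotype_error_rate=0.01, missing_rate=0.0,
        )
        pool = simulate_founder_haplotypes(noisy, seed=6)
        ds, _ = gene_drop(half_sib, pool, noisy, seed=6)
        assert len(detect_mendel_errors(half_sib, ds)) > 0

    def test_same_seed_identical_dataset(self, half_sib):
        pool = simulate_founder_haplotypes(SMALL, seed=9)
        a, _ = gene_drop(half_sib, pool, SMALL, seed=9)
        b, _ = gene_drop(half_sib, pool, SMALL, seed=9)
        assert a == b

    def test_shared_dam_family_also_realizable(self, half_sib_shared_dam):
        pool = simulate_founder_haplotypes(SMALL, seed=10)
        _, truth = gene_drop(half_sib_shared_dam, pool, SMALL, seed=10)
        assert all(truth.causal_dosage[i] == 2 for i in truth.affected_ids)


class TestWgsTable:
    def test_causal_record_passes_segregation_filter(self, half_sib):
        pool = simulate_founder_haplotypes(SMALL, seed=1)
        _, truth = gene_drop(half_sib, pool, SMALL, seed=1)
        records, roles = emit_wgs_table(truth, SMALL, seed=1)
        surv = segregation_filter(records, roles)
        assert truth.causal_key in {r.key() for r in surv}

    def test_background_frequencies_match_generating_distribution(self, half_sib):
        params = SimParams(
            n_chromosomes=2, n_markers_per_chrom=100,
            chrom_length_bp=20_000_000, causal_pos_bp=10_000_000,
            n_background_variants=2000, cosegregating_fraction=0.0,
        )
        pool = simulate_founder_haplotypes(params, seed=8)
        _, truth = gene_drop(half_sib, pool, params, seed=8)
        records, _ = emit_wgs_table(truth, params, seed=8)
        freqs = []
        for r in records:
            if r.key() == truth.causal_key:
                continue
            alts = [int(g) for g in r.genotypes.values() if g != GenotypeCall.MISSING]
            freqs.append(sum(alts) / (2 * len(alts)))
        freqs = np.array(freqs)
        # generating distribution is Beta(1, 3): mean 0.25
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - 0.25) < 4 * se

    def test_same_seed_identical_vcf_body(self, half_sib, tmp_path):
        pool = simulate_founder_haplotypes(SMALL, seed=2)
        _, truth = gene_drop(half_sib, pool, SMALL, seed=2)
        bodies = []
        for name in ("a.vcf", "b.vcf"):
            records, roles = emit_wgs_table(truth, SMALL, seed=7)
            aio.write_vcf(records, tmp_path / name,
                          samples=sorted(roles.all_ids))
            body = [
                l for l in (tmp_path / name).read_text().splitlines()
                if not l.startswith("##")
            ]
            bodies.append(body)
        assert bodies[0] == bodies[1]

    def test_requires_two_cases_and_two_carriers(self, half_sib):
        pool = simulate_founder_haplotypes(SMALL, seed=2)
        _, truth = gene_drop(half_sib, pool, SMALL, seed=2)
        truth.affected_ids = truth.affected_ids[:1]
        with pytest.raises(ValueError, match="affected"):
            emit_wgs_table(truth, SMALL, seed=2)


class TestTranscriptFixture:
    def test_planted_variant_is_the_expected_stop_gain(self):
        model, var = emit_transcript_fixture(650, 130, "+")
        csq = annotate(model, var)
        assert csq.csq_class.value == "nonsense"
        assert csq.hgvs_c == "c.388G>T"
        assert csq.hgvs_p == "p.Glu130*"

    def test_reverse_strand_gives_same_protein_annotation(self):
        plus, v_plus = emit_transcript_fixture(650, 130, "+", seed=5)
        minus, v_minus = emit_transcript_fixture(650, 130, "-", seed=5)
        a = annotate(plus, v_plus)
        b = annotate(minus, v_minus)
        assert (a.hgvs_c, a.hgvs_p, a.csq_class) == (b.hgvs_c, b.hgvs_p, b.csq_class)

    def test_truncation_fraction_exceeds_80_percent(self):
        model, var = emit_transcript_fixture(650, 130)
        csq = annotate(model, var)
        assert csq.truncated_fraction == pytest.approx((650 - 129) / 650)
        assert csq.truncated_fraction > 0.80

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            emit_transcript_fixture(650, 1)  # codon 1 is the initiator
        with pytest.raises(ValueError):
            emit_transcript_fixture(650, 651)

    def test_exon_table_fasta_roundtrip(self, tmp_path):
        model, _ = emit_transcript_fixture(100, 40, "-", seed=3)
        aio.write_exon_table(model, tmp_path / "exons.tsv")
        aio.write_cds_fasta(model, tmp_path / "cds.fa")
        back, = aio.read_exon_table(tmp_path / "exons.tsv", tmp_path / "cds.fa")
        assert back.exons == model.exons
        assert back.cds_sequence == model.cds_sequence
        assert back.strand == model.strand


class TestNmdCounts:
    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            emit_nmd_counts(0.5, 0, 100)
        with pytest.raises(ValueError):
            emit_nmd_counts(1.5, 10, 10)

    def test_counts_are_binomial_draws_at_the_stated_fractions(self):
        g, c = emit_nmd_counts(0.2, 10_000, 10_000, seed=1)
        assert abs(g.alt_fraction - 0.5) < 0.02
        assert abs(c.alt_fraction - 0.2) < 0.02
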