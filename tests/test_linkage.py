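"""Parametric linkage: peeling likelihood vs exhaustive oracle, LOD
properties, and linked-region assembly."""

import numpy as np
import pytest

from _oracles import enum_log10_likelihood, random_pedigree
from autozyg.linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    linked_regions,
    lod_score,
    pedigree_log_likelihood,
    scan,
    LodResult,
)
from autozyg.types import (
    Affection,
    GenomeInterval,
    Individual,
    Marker,
    MarkerDataset,
    Pedigree,
)

MODEL = DiseaseModel()  # q = 0.7, fully penetrant recessive

NUCLEAR = Pedigree([
    Individual("F", affection=Affection.UNAFFECTED),
    Individual("M", affection=Affection.UNAFFECTED),
    Individual("C", sire_id="F", dam_id="M", affection=Affection.AFFECTED),
])


def _cmp_oracle(pedigree, calls, freq, theta, model=MODEL):
    mine = pedigree_log_likelihood(pedigree, calls, freq, model, theta)
    ref = enum_log10_likelihood(
        pedigree, calls, freq,
        model.disease_allele_freq, model.penetrances, theta,
    )
    if np.isinf(ref):
        assert np.isinf(mine)
    else:
        assert mine == pytest.approx(ref, abs=1e-9)


class TestLikelihood:
    def test_half_sib_cosegregating_marker_matches_enumeration(self, half_sib):
        # fully informative marker: parents het, affected children hom-alt
        calls = {"SIRE": 1, "DAM1": 1, "DAM2": 1, "DAM3": 1,
                 "CH1": 2, "CH2": 2, "CH3": 2}
        for theta in (0.0, 0.1, 0.3, 0.5):
            _cmp_oracle(half_sib, calls, 0.4, theta)

    def test_nuclear_family_matches_enumeration(self):
        calls = {"F": 1, "M": 1, "C": 2}
        for theta in (0.0, 0.05, 0.2, 0.5):
            _cmp_oracle(NUCLEAR, calls, 0.3, theta)

    def test_impossible_data_gives_neg_inf_not_exception(self):
        # affected child of two genotyped parents is fine, but a child
        # het at a marker both parents are hom-ref for is impossible
        calls = {"F": 0, "M": 0, "C": 1}
        ll = pedigree_log_likelihood(NUCLEAR, calls, 0.3, MODEL, 0.1)
        assert ll == float("-inf")

    def test_monomorphic_marker_is_theta_independent(self, half_sib):
        calls = {iid: 2 for iid in half_sib.ids}
        lls = [
            pedigree_log_likelihood(half_sib, calls, 0.999, MODEL, t)
            for t in (0.0, 0.2, 0.5)
        ]
        assert max(lls) - min(lls) < 1e-12

    def test_peeling_equals_enumeration_on_random_pedigrees(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            ped = random_pedigree(rng, int(rng.integers(3, 7)))
            calls = {
                ind.id: int(rng.integers(-1, 3)) for ind in ped
            }
            freq = float(rng.uniform(0.05, 0.95))
            theta = float(rng.choice([0.0, 0.1, 0.3, 0.5]))
            _cmp_oracle(ped, calls, freq, theta)


class TestLod:
    def test_lod_is_zero_at_half_everywhere(self, half_sib):
        rng = np.random.default_rng(3)
        markers = [Marker(f"m{j}", "1", 1000 * (j + 1)) for j in range(25)]
        g = rng.integers(-1, 3, size=(7, 25)).astype(np.int8)
        ds = MarkerDataset(markers, half_sib.ids, g)
        for r in scan(half_sib, ds, MODEL):
            assert abs(r.lod_at_theta[0.5]) < 1e-9

    def test_single_affected_child_matches_oracle_and_is_uninformative(self):
        """One transmission per parent fixes no phase: the LOD curve of a
        carrier x carrier family with a single affected child is exactly
        flat, and the maximum (at theta 0) equals the enumeration oracle."""
        from autozyg.linkage import founder_allele_freq

        ds = MarkerDataset(
            [Marker("m1", "1", 1000)], ["F", "M", "C"],
            np.array([[1], [1], [2]], dtype=np.int8),
        )
        r = lod_score(NUCLEAR, 0, ds, MODEL)
        freq = founder_allele_freq(NUCLEAR, ds, 0)
        calls = {"F": 1, "M": 1, "C": 2}
        ref0 = enum_log10_likelihood(NUCLEAR, calls, freq, 0.7, (0, 0, 1), 0.0)
        ref5 = enum_log10_likelihood(NUCLEAR, calls, freq, 0.7, (0, 0, 1), 0.5)
        assert r.max_lod == pytest.approx(ref0 - ref5, abs=1e-9)
        assert max(abs(v) for v in r.lod_at_theta.values()) < 1e-9

    def test_two_affected_children_peak_at_theta_zero(self):
        """A second affected child makes the parents' phases informative
        and the cosegregating marker peaks at theta = 0."""
        ped = Pedigree([
            Individual("F", affection=Affection.UNAFFECTED),
            Individual("M", affection=Affection.UNAFFECTED),
            Individual("C1", "F", "M", affection=Affection.AFFECTED),
            Individual("C2", "F", "M", affection=Affection.AFFECTED),
        ])
        ds = MarkerDataset(
            [Marker("m1", "1", 1000)], ped.ids,
            np.array([[1], [1], [2], [2]], dtype=np.int8),
        )
        r = lod_score(ped, 0, ds, MODEL)
        assert r.theta_hat == 0.0
        assert r.max_lod > 0
        from autozyg.linkage import founder_allele_freq

        freq = founder_allele_freq(ped, ds, 0)
        calls = {"F": 1, "M": 1, "C1": 2, "C2": 2}
        ref0 = enum_log10_likelihood(ped, calls, freq, 0.7, (0, 0, 1), 0.0)
        ref5 = enum_log10_likelihood(ped, calls, freq, 0.7, (0, 0, 1), 0.5)
        assert r.max_lod == pytest.approx(ref0 - ref5, abs=1e-9)

    def test_obligate_recombinant_neg_inf_at_zero_interior_max(self):
        ped = Pedigree([
            Individual("F", affection=Affection.UNAFFECTED),
            Individual("M", affection=Affection.UNAFFECTED),
            Individual("C1", "F", "M", affection=Affection.AFFECTED),
            Individual("C2", "F", "M", affection=Affection.AFFECTED),
            Individual("C3", "F", "M", affection=Affection.AFFECTED),
        ])
        ds = MarkerDataset(
            [Marker("m1", "1", 1000)], ped.ids,
            np.array([[1], [1], [2], [2], [1]], dtype=np.int8),
        )
        r = lod_score(ped, 0, ds, MODEL)
        assert r.lod_at_theta[0.0] == float("-inf")
        assert 0.0 < r.theta_hat < 0.5
        assert r.max_lod > 0

    def test_all_missing_marker_is_flagged_zero(self, half_sib):
        ds = MarkerDataset(
            [Marker("m1", "1", 1000)], half_sib.ids,
            np.full((7, 1), -1, dtype=np.int8),
        )
        r = lod_score(half_sib, 0, ds, MODEL)
        assert r.flagged and r.max_lod == 0.0

    def test_empty_dataset_scan(self, half_sib):
        ds = MarkerDataset([], half_sib.ids, np.empty((7, 0), dtype=np.int8))
        assert scan(half_sib, ds, MODEL) == []

    def test_theta_grid_must_include_half(self, half_sib):
        ds = MarkerDataset(
            [Marker("m1", "1", 1000)], half_sib.ids,
            np.ones((7, 1), dtype=np.int8),
        )
        with pytest.raises(ValueError, match="0.5"):
            lod_score(half_sib, 0, ds, MODEL, theta_grid=[0.0, 0.1])


def _result(chrom, pos, max_lod, curve=None):
    grid = DEFAULT_THETA_GRID
    if curve is None:
        curve = {t: max_lod if t < 0.5 else 0.0 for t in grid}
    return LodResult(
        marker=Marker(f"m_{chrom}_{pos}", chrom, pos),
        lod_at_theta=curve,
        max_lod=max_lod,
        theta_hat=0.0 if max_lod > 0 else 0.5,
    )


class TestLinkedRegions:
    def test_no_positive_markers_gives_empty(self):
        res = [_result("1", p, 0.0, {0.0: -2.0, 0.5: 0.0}) for p in
               (10**6, 2 * 10**6, 3 * 10**6)]
        assert linked_regions(res) == []

    def test_two_mb_run_flanked_by_negatives(self):
        res = (
            [_result("1", 10**6, 0.0, {0.0: -3.0, 0.5: 0.0})]
            + [_result("1", 2 * 10**6 + k * 10**6, 0.9) for k in range(3)]
            + [_result("1", 6 * 10**6, 0.0, {0.0: -3.0, 0.5: 0.0})]
        )
        assert linked_regions(res) == [GenomeInterval("1", 2 * 10**6, 4 * 10**6)]

    def test_short_run_discarded(self):
        res = [
            _result("1", 10**6, 0.9),
            _result("1", 10**6 + 500_000, 0.9),
        ]
        assert linked_regions(res) == []

    def test_flat_uninformative_marker_does_not_break_a_run(self):
        res = [
            _result("1", 1_000_000, 0.9),
            _result("1", 2_000_000, 0.0),  # flat curve: no information
            _result("1", 3_000_000, 0.9),
        ]
        assert linked_regions(res) == [GenomeInterval("1", 1_000_000, 3_000_000)]

    def test_negative_marker_breaks_a_run(self):
        res = [
            _result("1", 1_000_000, 0.9),
            _result("1", 2_500_000, 0.9),
            _result("1", 3_000_000, 0.0, {0.0: -2.5, 0.5: 0.0}),
            _result("1", 3_500_000, 0.9),
            _result("1", 5_000_000, 0.9),
        ]
        assert linked_regions(res) == [
            GenomeInterval("1", 1_000_000, 2_500_000),
            GenomeInterval("1", 3_500_000, 5_000_000),
        ]

    def test_chromosome_change_closes_runs(self):
        res = [
            _result("1", 1_000_000, 0.9),
            _result("1", 3_000_000, 0.9),
            _result("2", 1_000_000, 0.9),
            _result("2", 4_000_000, 0.9),
        ]
        assert linked_regions(res) == [
            GenomeInterval("1", 1_000_000, 3_000_000),
            GenomeInterval("2", 1_000_000, 4_000_000),
        ]
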