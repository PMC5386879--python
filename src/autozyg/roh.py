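"""Run-of-homozygosity detection and cross-case allele sharing.

The detector follows the windowed algorithm popularized by PLINK's
``--homozyg``: a window of ``window_snps`` consecutive markers slides
along each chromosome; a window is called homozygous when it contains at
most ``max_het_in_window`` heterozygous and ``max_missing_in_window``
missing calls; a SNP is *in-ROH* when the fraction of homozygous windows
covering it reaches ``min_window_hit_fraction``; maximal in-ROH runs
passing the length and SNP-count thresholds become segments whose
boundaries are the first and last in-ROH marker positions.

``shared_roh`` mirrors ``--homozyg-group`` at the strictness needed for
autozygosity mapping: segments of all cases are intersected and the
overlap is kept only when the cases carry *identical* homozygous
genotypes at (nearly) every mutually typed marker — identity by descent
rather than mere co-located homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GenomeInterval, GenotypeCall, MarkerDataset

__all__ = [
    "RohParams",
    "RohSegment",
    "detect_roh",
    "shared_roh",
    "compile_boundaries",
]


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 5
    min_window_hit_fraction: float = 0.05
    min_run_length_bp: float = 1e6
    min_run_snps: int = 100
    allele_match_fraction: float = 0.99

    def __post_init__(self):
        if min(self.window_snps, self.max_het_in_window,
               self.max_missing_in_window, self.min_run_snps) < 0:
            raise ValueError("ROH counts must be >= 0")
        for f in (self.min_window_hit_fraction, self.allele_match_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("ROH fractions must lie in [0, 1]")


@dataclass
class RohSegment:
    sample: str
    interval: GenomeInterval
    n_snps: int
    n_het: int
    n_missing: int


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def detect_roh(
    dataset: MarkerDataset, sample: str, params: RohParams = RohParams()
) -> list[RohSegment]:
    """Windowed ROH detection for one sample on a map-sorted dataset.

    Chromosomes with fewer SNPs than ``window_snps`` are scanned with a
    single window spanning all their SNPs.
    """
    row = dataset.genotypes[dataset.sample_index(sample)]
    segments: list[RohSegment] = []
    for chrom, sl in dataset.chrom_slices().items():
        g = row[sl]
        pos = np.array([m.pos_bp for m in dataset.markers[sl]])
        n = len(g)
        if n == 0:
            continue
        w = min(params.window_snps, n)
        het = (g == GenotypeCall.HET).astype(np.int64)
        miss = (g == GenotypeCall.MISSING).astype(np.int64)
        win_het = _moving_sum(het, w)
        win_miss = _moving_sum(miss, w)
        win_ok = (
            (win_het <= params.max_het_in_window)
            & (win_miss <= params.max_missing_in_window)
        ).astype(np.int64)
        idx = np.arange(n)
        lo = np.maximum(0, idx - w + 1)
        hi = np.minimum(idx, n - w)
        cum_ok = np.concatenate([[0], np.cumsum(win_ok)])
        n_ok = cum_ok[hi + 1] - cum_ok[lo]
        n_cov = hi - lo + 1
        in_roh = n_ok / n_cov >= params.min_window_hit_fraction
        # maximal in-ROH runs
        boundaries = np.flatnonzero(np.diff(in_roh.astype(np.int8)) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        for s, e in zip(starts, ends):
            if not in_roh[s]:
                continue
            n_snps = e - s
            length = int(pos[e - 1] - pos[s])
            if n_snps < params.min_run_snps or length < params.min_run_length_bp:
                continue
            segments.append(
                RohSegment(
                    sample=sample,
                    interval=GenomeInterval(chrom, int(pos[s]), int(pos[e - 1])),
                    n_snps=int(n_snps),
                    n_het=int(het[s:e].sum()),
                    n_missing=int(miss[s:e].sum()),
                )
            )
    return segments


def _intersect_lists(
    a: list[GenomeInterval], b: list[GenomeInterval]
) -> list[GenomeInterval]:
    out = []
    for x in a:
        for y in b:
            z = x.intersection(y)
            if z is not None:
                out.append(z)
    return sorted(out)


def _identity_fraction(
    dataset: MarkerDataset, case_rows: list[int], lo: int, hi: int
) -> tuple[int, int]:
    """(n_matching, n_mutually_typed) over marker index range [lo, hi]."""
    g = dataset.genotypes[case_rows, lo : hi + 1]
    typed = (g != GenotypeCall.MISSING).all(axis=0)
    hom = ((g == GenotypeCall.HOM_REF) | (g == GenotypeCall.HOM_ALT)).all(axis=0)
    same = (g == g[0]).all(axis=0)
    match = typed & hom & same
    return int(match.sum()), int(typed.sum())


def _marker_range(dataset: MarkerDataset, iv: GenomeInterval) -> tuple[int, int] | None:
    sl = dataset.chrom_slices().get(iv.chrom)
    if sl is None:
        return None
    pos = np.array([m.pos_bp for m in dataset.markers[sl]])
    lo = int(np.searchsorted(pos, iv.start_bp, side="left"))
    hi = int(np.searchsorted(pos, iv.end_bp, side="right")) - 1
    if hi < lo:
        return None
    return sl.start + lo, sl.start + hi


def shared_roh(
    dataset: MarkerDataset,
    case_ids: list[str],
    params: RohParams = RohParams(),
    segments: dict[str, list[RohSegment]] | None = None,
) -> list[GenomeInterval]:
    """ROH intervals shared by all cases with identical homozygous alleles.

    Per-case segments are intersected pairwise across all cases; an
    overlap survives when, over its mutually typed markers, every case
    is homozygous for the same allele at >= ``allele_match_fraction``
    of them, and when it still clears ``min_run_length_bp``.  A single
    case degenerates to its own segments.
    """
    if segments is None:
        segments = {c: detect_roh(dataset, c, params) for c in case_ids}
    per_case = [sorted(seg.interval for seg in segments[c]) for c in case_ids]
    if len(case_ids) == 1:
        return per_case[0]
    overlaps = per_case[0]
    for other in per_case[1:]:
        overlaps = _intersect_lists(overlaps, other)
    case_rows = [dataset.sample_index(c) for c in case_ids]
    out: list[GenomeInterval] = []
    for iv in overlaps:
        rng = _marker_range(dataset, iv)
        if rng is None:
            continue
        n_match, n_typed = _identity_fraction(dataset, case_rows, *rng)
        if n_typed == 0:
            continue  # sharing cannot be confirmed
        if n_match / n_typed < params.allele_match_fraction:
            continue
        if iv.length_bp < params.min_run_length_bp:
            continue
        out.append(iv)
    return sorted(out)


def compile_boundaries(
    shared: list[GenomeInterval],
    dataset: MarkerDataset,
    case_ids: list[str],
) -> list[GenomeInterval]:
    """Deterministic boundary refinement of shared-ROH intervals.

    Each boundary is walked marker-by-marker outward for as long as
    every case stays homozygous for the same allele; the first marker at
    which any case is heterozygous, missing, or discordant stops the
    extension (a missing call does not confirm sharing).  This replaces
    by-eye inspection of raw genotypes with a reproducible rule.
    """
    case_rows = [dataset.sample_index(c) for c in case_ids]
    g = dataset.genotypes[case_rows, :]
    typed = (g != GenotypeCall.MISSING).all(axis=0)
    hom = ((g == GenotypeCall.HOM_REF) | (g == GenotypeCall.HOM_ALT)).all(axis=0)
    same = (g == g[0]).all(axis=0)
    confirm = typed & hom & same
    slices = dataset.chrom_slices()
    out = []
    for iv in shared:
        rng = _marker_range(dataset, iv)
        if rng is None:
            out.append(iv)
            continue
        lo, hi = rng
        sl = slices[iv.chrom]
        while lo - 1 >= sl.start and confirm[lo - 1]:
            lo -= 1
        while hi + 1 < sl.stop and confirm[hi + 1]:
            hi += 1
        out.append(
            GenomeInterval(
                iv.chrom,
                dataset.markers[lo].pos_bp,
                dataset.markers[hi].pos_bp,
            )
        )
    return out


def write_roh_table(segments: list[RohSegment], path) -> None:
    from .io import _provenance

    with open(path, "w") as fh:
        fh.write(_provenance("ROH segments"))
        fh.write("sample\tchrom\tstart\tend\tn_snps\tn_het\tn_missing\n")
        for s in segments:
            fh.write(
                f"{s.sample}\t{s.interval.chrom}\t{s.interval.start_bp}\t"
                f"{s.interval.end_bp}\t{s.n_snps}\t{s.n_het}\t{s.n_missing}\n"
            )
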