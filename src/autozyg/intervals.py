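"""Critical-interval arithmetic: intersection, gap-tolerant merging, spans.

Intervals are 1-based inclusive; spans are plain coordinate differences
(``end - start``) so that published boundary coordinates reproduce the
published megabase spans literally.  Merging unions consecutive
same-chromosome intervals whose separating gap is strictly smaller than
``max_gap_bp`` — the rule used to treat a run of homozygous segments
interrupted only by sub-threshold non-homozygous stretches as one
critical interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence, Union

from .types import GenomeInterval

__all__ = ["CriticalIntervalSet", "intersect", "merge_with_gaps", "span_mb"]


@dataclass
class CriticalIntervalSet:
    """Sorted intervals with per-interval provenance tags."""

    intervals: list[GenomeInterval] = field(default_factory=list)
    provenance: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self):
        if not self.provenance:
            self.provenance = [()] * len(self.intervals)
        if len(self.provenance) != len(self.intervals):
            raise ValueError("provenance must parallel intervals")
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i])
        self.intervals = [self.intervals[i] for i in order]
        self.provenance = [self.provenance[i] for i in order]

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


IntervalsLike = Union[CriticalIntervalSet, Sequence[GenomeInterval]]


def _coerce(x: IntervalsLike, tag: str) -> CriticalIntervalSet:
    if isinstance(x, CriticalIntervalSet):
        return x
    return CriticalIntervalSet(list(x), [(tag,)] * len(list(x)))


def intersect(set_a: IntervalsLike, set_b: IntervalsLike) -> CriticalIntervalSet:
    """All pairwise overlaps between the two sets (same chromosome only)."""
    a = _coerce(set_a, "a")
    b = _coerce(set_b, "b")
    ivs: list[GenomeInterval] = []
    prov: list[tuple[str, ...]] = []
    for x, px in zip(a.intervals, a.provenance):
        for y, py in zip(b.intervals, b.provenance):
            z = x.intersection(y)
            if z is not None:
                ivs.append(z)
                prov.append(tuple(px) + tuple(py))
    return CriticalIntervalSet(ivs, prov)


def merge_with_gaps(
    s: IntervalsLike, max_gap_bp: float = 1.5e6
) -> CriticalIntervalSet:
    """Union consecutive same-chromosome intervals separated by a gap
    strictly smaller than ``max_gap_bp`` (gap = next.start - prev.end)."""
    cs = _coerce(s, "input")
    out_iv: list[GenomeInterval] = []
    out_pv: list[tuple[str, ...]] = []
    for iv, pv in zip(cs.intervals, cs.provenance):
        if (
            out_iv
            and iv.chrom == out_iv[-1].chrom
            and iv.start_bp - out_iv[-1].end_bp < max_gap_bp
        ):
            prev = out_iv[-1]
            out_iv[-1] = GenomeInterval(
                iv.chrom, prev.start_bp, max(prev.end_bp, iv.end_bp)
            )
            out_pv[-1] = ("merged-from",) + tuple(
                t for t in out_pv[-1] if t != "merged-from"
            ) + tuple(pv)
        else:
            out_iv.append(iv)
            out_pv.append(tuple(pv))
    return CriticalIntervalSet(out_iv, out_pv)


def span_mb(interval: GenomeInterval, decimals: int = 1) -> float:
    """(end - start) / 1e6, rounded half-up to ``decimals`` places."""
    mb = Decimal(interval.end_bp - interval.start_bp) / Decimal(1_000_000)
    quantum = Decimal(1).scaleb(-decimals)
    return float(mb.quantize(quantum, rounding=ROUND_HALF_UP))


def write_span_report(cs: CriticalIntervalSet, path, decimals: int = 1) -> None:
    from .io import _provenance

    with open(path, "w") as fh:
        fh.write(_provenance("critical interval spans"))
        fh.write("chrom\tstart\tend\tspan_mb\tprovenance\n")
        for iv, pv in zip(cs.intervals, cs.provenance):
            fh.write(
                f"{iv.chrom}\t{iv.start_bp}\t{iv.end_bp}\t"
                f"{span_mb(iv, decimals)}\t{','.join(pv) or '.'}\n"
            )
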