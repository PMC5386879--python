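#!/usr/bin/env python
"""Intersect linkage and homozygosity evidence into critical intervals.

Overlaps the positive-LOD regions with the shared identical-allele ROH
and merges consecutive segments separated by gaps under 1.5 Mb into
single conservative critical intervals, reporting their spans.
"""

from pathlib import Path

from autozyg import io as aio
from autozyg.intervals import (
    CriticalIntervalSet,
    intersect,
    merge_with_gaps,
    span_mb,
    write_span_report,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    linked = aio.read_bed(BASE / "linkage" / "regions.bed")
    shared = aio.read_bed(BASE / "roh" / "shared.bed")
    critical = merge_with_gaps(
        intersect(
            CriticalIntervalSet(linked, [("linkage",)] * len(linked)),
            CriticalIntervalSet(shared, [("homozygosity",)] * len(shared)),
        ),
        1.5e6,
    )
    out = BASE / "intervals"
    out.mkdir(parents=True, exist_ok=True)
    aio.write_bed(critical.intervals, out / "critical.bed")
    write_span_report(critical, out / "spans.tsv")
    print(f"critical intervals: {len(critical)}")
    for iv in critical:
        print(f"  {iv.chrom}:{iv.start_bp}-{iv.end_bp}  ({span_mb(iv, 1)} Mb)")


if __name__ == "__main__":
    main()
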