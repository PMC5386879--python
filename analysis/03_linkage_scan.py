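#!/usr/bin/env python
"""Genome-wide single-point parametric linkage scan.

Applies a fully penetrant autosomal recessive model with disease allele
frequency 0.7 to every pruned marker, then assembles runs of
positive-LOD markers (>1 Mb) into candidate linked regions.
"""

from pathlib import Path

from autozyg import io as aio
from autozyg.linkage import DiseaseModel, linked_regions, scan, write_lod_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pedigree, dataset = aio.read_ped_map(
        BASE / "qc" / "pruned.ped", BASE / "qc" / "pruned.map"
    )
    results = scan(pedigree, dataset.sort_by_position(), DiseaseModel())
    regions = linked_regions(results)
    out = BASE / "linkage"
    out.mkdir(parents=True, exist_ok=True)
    write_lod_table(results, out / "lod.tsv")
    aio.write_bed(regions, out / "regions.bed")
    best = max(results, key=lambda r: r.max_lod)
    print(f"scanned {len(results)} markers")
    print(f"top marker: {best.marker.name} ({best.marker.chrom}:"
          f"{best.marker.pos_bp}) maxLOD={best.max_lod:.3f} at "
          f"theta={best.theta_hat}")
    print(f"linked regions >1 Mb with positive LOD: {len(regions)}")
    for iv in regions:
        print(f"  {iv.chrom}:{iv.start_bp}-{iv.end_bp}")


if __name__ == "__main__":
    main()
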