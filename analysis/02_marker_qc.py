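#!/usr/bin/env python
"""Prune the array markers ahead of linkage analysis.

Removes markers that are noninformative, on the sex chromosomes,
missing in any of the seven family members, Mendel-inconsistent, or
below 20% minor allele frequency, after excluding any sample with a
call rate under 95%.  Writes the pruned PED/MAP and the per-criterion
removal report.
"""

from pathlib import Path

from autozyg import io as aio
from autozyg.qc import QcCriteria, prune_markers, write_qc_report

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pedigree, dataset = aio.read_ped_map(
        BASE / "study" / "family.ped", BASE / "study" / "family.map"
    )
    pruned, report = prune_markers(pedigree, dataset.sort_by_position(), QcCriteria())
    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    aio.write_ped_map(pedigree, pruned, out / "pruned.ped", out / "pruned.map")
    write_qc_report(report, out / "qc.tsv")
    print(f"input markers: {report.n_input_markers}")
    for crit, n in report.removed.items():
        print(f"  removed ({crit}): {n}")
    print(f"surviving markers for linkage: {report.n_surviving_markers}")


if __name__ == "__main__":
    main()
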