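#!/usr/bin/env python
"""Allele-balance evidence for nonsense-mediated decay.

Compares the mutant-allele fraction between a heterozygous carrier's
gDNA and cDNA with exact binomial and Fisher tests, classifying the
transcript-level depletion of the premature-stop allele.
"""

import json
from pathlib import Path

from autozyg import io as aio
from autozyg.nmd import nmd_classify

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = {c.source: c for c in aio.read_counts_tsv(BASE / "study" / "counts.tsv")}
    res = nmd_classify(counts["gdna"], counts["cdna"], alpha=0.05)
    out = BASE / "nmd"
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "classification": res.classification.value,
        "gdna_alt_fraction": res.gdna_alt_fraction,
        "cdna_alt_fraction": res.cdna_alt_fraction,
        "p_gdna_vs_half": res.p_gdna_vs_half,
        "p_cdna_vs_half": res.p_cdna_vs_half,
        "p_gdna_vs_cdna": res.p_gdna_vs_cdna,
    }
    (out / "nmd.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    print(f"gDNA mutant fraction: {res.gdna_alt_fraction:.3f} "
          f"(p vs 0.5 = {res.p_gdna_vs_half:.3g})")
    print(f"cDNA mutant fraction: {res.cdna_alt_fraction:.3f} "
          f"(p vs 0.5 = {res.p_cdna_vs_half:.3g})")
    print(f"gDNA vs cDNA: p = {res.p_gdna_vs_cdna:.3g}")
    print(f"classification: {res.classification.value}")


if __name__ == "__main__":
    main()
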