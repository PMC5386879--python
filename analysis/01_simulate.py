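#!/usr/bin/env python
"""Generate the synthetic study.

Simulates a half-sib mapping family (3 affected offspring, 4 carrier
parents) genotyped at dense biallelic markers, a WGS-tier genotype
table (2 cases, 2 obligate carriers, 75 controls) containing a planted
fully penetrant recessive stop-gain among background variants, the
transcript model the stop-gain lands in, and gDNA/cDNA allele counts
showing transcript-level depletion of the mutant allele.

Writes everything under results/study/ in the standard text formats,
plus the ground truth as JSON.
"""

import json
from pathlib import Path

from autozyg import io as aio
from autozyg.pipeline import PipelineConfig, simulate_inputs

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    bundle = simulate_inputs(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    aio.write_ped_map(bundle.pedigree, bundle.dataset,
                      OUT / "family.ped", OUT / "family.map")
    aio.write_vcf(
        bundle.wgs_records, OUT / "wgs.vcf",
        samples=sorted(bundle.roles.cases) + sorted(bundle.roles.carriers)
        + sorted(bundle.roles.controls),
        contig_lengths={c: cfg.sim.chrom_length_bp for c in cfg.sim.chrom_names},
    )
    aio.write_exon_table(bundle.transcript, OUT / "exons.tsv")
    aio.write_cds_fasta(bundle.transcript, OUT / "cds.fa")
    aio.write_counts_tsv([bundle.nmd_gdna, bundle.nmd_cdna], OUT / "counts.tsv")
    truth = {
        "chrom": bundle.truth.chrom,
        "pos_bp": bundle.truth.pos_bp,
        "ref": bundle.truth.ref_allele,
        "alt": bundle.truth.alt_allele,
        "causal_dosage": bundle.truth.causal_dosage,
        "cases": sorted(bundle.roles.cases),
        "carriers": sorted(bundle.roles.carriers),
        "seed": SEED,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    print(f"family: {bundle.dataset.n_samples} individuals x "
          f"{bundle.dataset.n_markers} markers")
    print(f"WGS tier: {len(bundle.wgs_records)} variants, "
          f"{len(bundle.roles.all_ids)} samples")
    print(f"planted variant: {bundle.truth.chrom}:{bundle.truth.pos_bp} "
          f"{bundle.truth.ref_allele}>{bundle.truth.alt_allele}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
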