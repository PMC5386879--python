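"""Gene-dropping simulator with known ground truth.

Produces every input the mapping pipeline consumes: dense SNP-array
genotypes for a family segregating a fully penetrant recessive variant,
a case/carrier/control WGS-style genotype table containing the planted
causal variant among background variants, a transcript fixture in which
the causal variant is a stop-gain, and gDNA/cDNA allele counts with
transcript-level depletion of the mutant allele.

The population model is deliberately simple: a pool of ancestral
haplotypes with per-marker allele frequencies drawn from a Beta
distribution, exactly one pool haplotype carrying the causal allele.
Founders draw haplotypes from the pool *with replacement* — the inbred-
population assumption that lets several founders carry identical-by-
descent copies of the causal haplotype.  Founders who are obligate
carriers (parents of affected individuals) are assigned one copy of the
causal haplotype outright, and each offspring's gametes are resampled
until its genotype at the causal locus matches its recorded affection
status (bounded retries); this conditions the drop on the observed
affection pattern without importance weighting.

Meioses use a Poisson crossover count (rate = genetic length in
Morgans, linear map function) with uniformly placed crossovers and no
interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nmd import AlleleCounts
from .types import (
    Affection,
    GenotypeCall,
    Individual,
    Marker,
    MarkerDataset,
    Pedigree,
    Sex,
    VariantRecord,
)

__all__ = [
    "SimParams",
    "HaplotypePool",
    "TruthRecord",
    "make_half_sib_pedigree",
    "simulate_founder_haplotypes",
    "gene_drop",
    "emit_wgs_table",
    "emit_transcript_fixture",
    "emit_nmd_counts",
]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic datasets.

    The defaults emulate the shapes of the real study at desk scale:
    a half-sib mapping family (3 affected offspring, 4 parents) typed
    at dense evenly spaced biallelic markers on a few chromosomes, and
    a WGS tier of 2 cases, 2 obligate carriers, and 75 controls.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 40_000_000
    n_markers_per_chrom: int = 1200
    founder_maf_beta: tuple[float, float] = (2.0, 2.0)
    recomb_rate_cM_per_Mb: float = 1.0
    causal_chrom: str = "2"
    causal_pos_bp: int = 20_000_000
    causal_ref: str = "G"
    causal_alt: str = "T"
    missing_rate: float = 0.005
    genotype_error_rate: float = 0.001
    n_controls: int = 75
    n_background_variants: int = 2000
    cosegregating_fraction: float = 0.02
    control_missing_rate: float = 0.05
    haplotype_pool_size: int = 20
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.genotype_error_rate,
                  self.cosegregating_fraction, self.control_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 1 <= self.causal_pos_bp <= self.chrom_length_bp:
            raise ValueError("causal position outside chromosome")
        if self.causal_chrom not in self.chrom_names:
            raise ValueError(
                f"causal_chrom {self.causal_chrom!r} not in {self.chrom_names}"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_bp / 1e6 * self.recomb_rate_cM_per_Mb / 100.0


@dataclass
class HaplotypePool:
    """Ancestral haplotypes over the simulated marker map."""

    markers: list[Marker]
    haplotypes: np.ndarray  # (pool_size, n_markers) int8, second-allele indicator
    allele_freqs: np.ndarray  # per-marker frequency of the second allele
    causal_hap_index: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def pool_size(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class TruthRecord:
    """Ground truth of one gene drop."""

    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    causal_dosage: dict[str, int]
    affected_ids: list[str]
    carrier_ids: list[str]
    causal_hap_index: int
    phased: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    phased_causal: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    @property
    def causal_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos_bp, self.ref_allele, self.alt_allele)


def make_half_sib_pedigree(shared_parent: str = "sire") -> Pedigree:
    """Three affected half-siblings sharing one parent, plus the four
    parents (all unaffected founders)."""
    if shared_parent not in ("sire", "dam"):
        raise ValueError("shared_parent must be 'sire' or 'dam'")
    inds = []
    if shared_parent == "sire":
        inds.append(Individual("SIRE", sex=Sex.MALE, affection=Affection.UNAFFECTED))
        for k in (1, 2, 3):
            inds.append(
                Individual(f"DAM{k}", sex=Sex.FEMALE, affection=Affection.UNAFFECTED)
            )
        for k in (1, 2, 3):
            inds.append(
                Individual(
                    f"CH{k}",
                    sire_id="SIRE",
                    dam_id=f"DAM{k}",
                    sex=Sex.UNKNOWN,
                    affection=Affection.AFFECTED,
                )
            )
    else:
        inds.append(Individual("DAM", sex=Sex.FEMALE, affection=Affection.UNAFFECTED))
        for k in (1, 2, 3):
            inds.append(
                Individual(f"SIRE{k}", sex=Sex.MALE, affection=Affection.UNAFFECTED)
            )
        for k in (1, 2, 3):
            inds.append(
                Individual(
                    f"CH{k}",
                    sire_id=f"SIRE{k}",
                    dam_id="DAM",
                    sex=Sex.UNKNOWN,
                    affection=Affection.AFFECTED,
                )
            )
    return Pedigree(inds)


def _marker_map(params: SimParams, rng: np.random.Generator) -> list[Marker]:
    markers: list[Marker] = []
    n = params.n_markers_per_chrom
    spacing = params.chrom_length_bp // (n + 1)
    if spacing < 3:
        raise ValueError("chromosome too short for the requested marker count")
    for chrom in params.chrom_names:
        jitter = rng.integers(-(spacing // 3), spacing // 3 + 1, size=n)
        pos = spacing * np.arange(1, n + 1) + jitter
        for j, p in enumerate(pos):
            markers.append(
                Marker(name=f"snp{chrom}_{j + 1}", chrom=chrom, pos_bp=int(p))
            )
    return markers


def simulate_founder_haplotypes(
    params: SimParams, seed: int | None = None
) -> HaplotypePool:
    """Draw the ancestral haplotype pool.

    Per-marker second-allele frequencies come from the configured Beta
    distribution; each pool haplotype is an independent Bernoulli draw
    per marker.  Exactly one pool haplotype (index 0) is designated the
    carrier of the causal allele; its marker background is a random
    haplotype like any other, which over hundreds of markers is unique
    in the pool with overwhelming probability, so autozygosity for it
    is detectable as allele-identical homozygosity.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    markers = _marker_map(params, rng)
    a, b = params.founder_maf_beta
    freqs = rng.beta(a, b, size=len(markers))
    pool = (
        rng.random((params.haplotype_pool_size, len(markers))) < freqs
    ).astype(np.int8)
    return HaplotypePool(
        markers=markers,
        haplotypes=pool,
        allele_freqs=freqs,
        causal_hap_index=0,
    )


def _chrom_layout(markers: list[Marker]) -> list[tuple[str, slice, np.ndarray]]:
    out = []
    start = 0
    for i, m in enumerate(markers):
        if i and m.chrom != markers[i - 1].chrom:
            sl = slice(start, i)
            out.append(
                (markers[start].chrom, sl, np.array([x.pos_bp for x in markers[sl]]))
            )
            start = i
    if markers:
        sl = slice(start, len(markers))
        out.append(
            (markers[start].chrom, sl, np.array([x.pos_bp for x in markers[sl]]))
        )
    return out


def _gamete(
    rng: np.random.Generator,
    haps: tuple[tuple[np.ndarray, bool], tuple[np.ndarray, bool]],
    layout,
    params: SimParams,
) -> tuple[np.ndarray, bool]:
    """One meiosis: Poisson crossovers, uniform placement, no interference."""
    (alleles_a, causal_a), (alleles_b, causal_b) = haps
    out = np.empty_like(alleles_a)
    causal = False
    for chrom, sl, pos in layout:
        k = rng.poisson(params.morgans_per_chrom)
        xpos = np.sort(rng.uniform(0, params.chrom_length_bp, size=k))
        start = int(rng.integers(2))
        src = (start + np.searchsorted(xpos, pos)) % 2
        out[sl] = np.where(src == 0, alleles_a[sl], alleles_b[sl])
        if chrom == params.causal_chrom:
            s = (start + int(np.searchsorted(xpos, params.causal_pos_bp))) % 2
            causal = causal_a if s == 0 else causal_b
    return out, causal


def gene_drop(
    pedigree: Pedigree,
    pool: HaplotypePool,
    params: SimParams,
    seed: int | None = None,
) -> tuple[MarkerDataset, TruthRecord]:
    """Drop the pool haplotypes through the pedigree.

    Founders draw from the pool with replacement; founders who are
    parents of affected individuals receive one copy of the causal
    haplotype (obligate carriers), affected founders two.  Offspring
    gametes are resampled (bounded by ``params.max_retries``) until the
    causal-locus genotype matches the recorded affection status under
    full penetrance.  Genotyping errors and missingness are applied
    independently at the configured rates afterwards.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    layout = _chrom_layout(pool.markers)
    causal_row = pool.haplotypes[pool.causal_hap_index]
    n_pool = pool.pool_size

    def random_noncausal_row() -> np.ndarray:
        idx = int(rng.integers(n_pool - 1))
        if idx >= pool.causal_hap_index:
            idx += 1
        return pool.haplotypes[idx]

    obligate = {
        ind.id
        for ind in pedigree.founders
        if any(
            ch.affection is Affection.AFFECTED
            for ch in pedigree.children_of(ind.id)
        )
    }
    haps: dict[str, tuple[tuple[np.ndarray, bool], tuple[np.ndarray, bool]]] = {}
    for ind in pedigree.topological_order():
        if ind.is_founder:
            if ind.affection is Affection.AFFECTED:
                haps[ind.id] = ((causal_row.copy(), True), (causal_row.copy(), True))
            elif ind.id in obligate:
                haps[ind.id] = (
                    (causal_row.copy(), True),
                    (random_noncausal_row().copy(), False),
                )
            else:
                pair = []
                for _ in range(2):
                    idx = int(rng.integers(n_pool))
                    pair.append(
                        (pool.haplotypes[idx].copy(), idx == pool.causal_hap_index)
                    )
                haps[ind.id] = (pair[0], pair[1])
            continue
        sire, dam = haps[ind.sire_id], haps[ind.dam_id]
        for _attempt in range(params.max_retries):
            gp = _gamete(rng, sire, layout, params)
            gm = _gamete(rng, dam, layout, params)
            dosage = int(gp[1]) + int(gm[1])
            if ind.affection is Affection.AFFECTED and dosage != 2:
                continue
            if ind.affection is Affection.UNAFFECTED and dosage == 2:
                continue
            haps[ind.id] = (gp, gm)
            break
        else:
            raise RuntimeError(
                f"could not realize affection status of {ind.id!r} within "
                f"{params.max_retries} retries (no carrier x carrier mating?)"
            )

    samples = pedigree.ids
    geno = np.empty((len(samples), pool.n_markers), dtype=np.int8)
    for i, iid in enumerate(samples):
        (ha, _), (hb, _) = haps[iid]
        geno[i] = ha + hb
    if params.genotype_error_rate > 0:
        err = rng.random(geno.shape) < params.genotype_error_rate
        shift = rng.integers(1, 3, size=geno.shape)
        geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random(geno.shape) < params.missing_rate
        geno = np.where(miss, np.int8(-1), geno)

    dosage = {
        iid: int(haps[iid][0][1]) + int(haps[iid][1][1]) for iid in samples
    }
    truth = TruthRecord(
        chrom=params.causal_chrom,
        pos_bp=params.causal_pos_bp,
        ref_allele=params.causal_ref,
        alt_allele=params.causal_alt,
        causal_dosage=dosage,
        affected_ids=[
            ind.id for ind in pedigree if ind.affection is Affection.AFFECTED
        ],
        carrier_ids=[iid for iid, d in dosage.items() if d == 1],
        causal_hap_index=pool.causal_hap_index,
        phased={iid: (haps[iid][0][0], haps[iid][1][0]) for iid in samples},
        phased_causal={iid: (haps[iid][0][1], haps[iid][1][1]) for iid in samples},
    )
    dataset = MarkerDataset(pool.markers, samples, geno)
    return dataset, truth


_BASES = np.array(list("ACGT"))


def emit_wgs_table(
    truth: TruthRecord, params: SimParams, seed: int | None = None
):
    """WGS-tier genotype table: the causal variant plus background.

    Returns ``(records, roles)``.  Cases (2) are affected individuals,
    carriers (2) are causal-allele heterozygotes from the family, and
    controls are unrelated samples.  Background variants draw
    Hardy-Weinberg genotypes from population frequencies for every
    sample; a configurable fraction mimics partial cosegregation (the
    case/carrier pattern with at least one carrier-like control), to
    exercise the cascade's intermediate counts.
    """
    from .varfilter import SampleRoles

    rng = np.random.default_rng(params.seed if seed is None else seed)
    affected = sorted(truth.affected_ids)
    carriers_all = sorted(truth.carrier_ids)
    if len(affected) < 2 or len(carriers_all) < 2:
        raise ValueError("need >= 2 affected and >= 2 carrier individuals")
    cases = affected[:2]
    carriers = carriers_all[:2]
    controls = [f"CTRL{i:03d}" for i in range(1, params.n_controls + 1)]
    samples = cases + carriers + controls

    records: list[VariantRecord] = []
    causal_calls: dict[str, GenotypeCall] = {}
    for s in cases:
        causal_calls[s] = GenotypeCall.HOM_ALT
    for s in carriers:
        causal_calls[s] = GenotypeCall.HET
    for s in controls:
        causal_calls[s] = (
            GenotypeCall.MISSING
            if rng.random() < params.control_missing_rate
            else GenotypeCall.HOM_REF
        )
    records.append(
        VariantRecord(
            chrom=truth.chrom,
            pos_bp=truth.pos_bp,
            ref_allele=truth.ref_allele,
            alt_allele=truth.alt_allele,
            genotypes=causal_calls,
        )
    )

    used = {(truth.chrom, truth.pos_bp)}
    n = params.n_background_variants
    n_coseg = int(round(n * params.cosegregating_fraction))
    for v in range(n):
        while True:
            chrom = params.chrom_names[int(rng.integers(params.n_chromosomes))]
            pos = int(rng.integers(1, params.chrom_length_bp + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
        p = float(rng.beta(1.0, 3.0))
        calls = {
            s: GenotypeCall(int(g))
            for s, g in zip(samples, rng.binomial(2, p, size=len(samples)))
        }
        if v < n_coseg:  # near-miss: fails only on the controls
            for s in cases:
                calls[s] = GenotypeCall.HOM_ALT
            for s in carriers:
                calls[s] = GenotypeCall.HET
            for s in controls:
                calls[s] = GenotypeCall.HOM_REF
            k = 1 + int(rng.integers(3))
            for s in rng.choice(controls, size=k, replace=False):
                calls[str(s)] = GenotypeCall.HET
        records.append(
            VariantRecord(
                chrom=chrom,
                pos_bp=pos,
                ref_allele=str(_BASES[ref_i]),
                alt_allele=str(_BASES[alt_i]),
                genotypes=calls,
            )
        )
    records.sort(key=lambda r: (int(r.chrom), r.pos_bp))
    roles = SampleRoles(
        cases=frozenset(cases),
        carriers=frozenset(carriers),
        controls=frozenset(controls),
    )
    return records, roles


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


def emit_transcript_fixture(
    protein_length_codons: int = 650,
    stop_codon_index: int = 130,
    strand: str = "+",
    chrom: str = "2",
    variant_pos_bp: int = 20_000_000,
    n_exons: int = 4,
    intron_bp: int = 2_000,
    seed: int = 0,
    transcript_id: str = "TX1",
):
    """Transcript fixture with a planted stop-gain.

    The CDS codon at ``stop_codon_index`` is GAG (Glu); the planted
    genomic variant substitutes its first base G>T on the coding strand,
    creating a TAG stop.  Returns ``(TranscriptModel, VariantRecord)``
    where the record carries no genotypes (site only).
    """
    from .consequence import TranscriptModel

    if not 2 <= stop_codon_index <= protein_length_codons:
        raise ValueError(
            "stop_codon_index must lie in 2..protein_length_codons "
            "(codon 1 is the initiator ATG)"
        )
    if n_exons < 1 or intron_bp < 1:
        raise ValueError("need n_exons >= 1 and intron_bp >= 1")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _CODONS[int(i)]
        for i in rng.integers(len(_CODONS), size=protein_length_codons - 1)
    ]
    codons[stop_codon_index - 1] = "GAG"
    cds = "".join(codons)
    cds_len = len(cds)
    v_cds = 3 * (stop_codon_index - 1) + 1  # first base of the GAG codon

    sizes = [
        cds_len // n_exons + (1 if i < cds_len % n_exons else 0)
        for i in range(n_exons)
    ]
    # plus-strand layout anchored at 1, then shifted
    exon_bounds = []
    g = 1
    for s in sizes:
        exon_bounds.append((g, g + s - 1))
        g += s + intron_bp
    # genomic position of CDS coordinate v on the anchored layout
    off = 0
    g_v = None
    for (lo, hi) in exon_bounds:
        size = hi - lo + 1
        if off < v_cds <= off + size:
            g_v = lo + (v_cds - off - 1)
            break
        off += size
    assert g_v is not None

    from .types import GenomeInterval

    if strand == "+":
        shift = variant_pos_bp - g_v
        exons = [
            GenomeInterval(chrom, lo + shift, hi + shift) for lo, hi in exon_bounds
        ]
        ref, alt = "G", "T"
    elif strand == "-":
        mirror = variant_pos_bp + g_v
        exons = sorted(
            GenomeInterval(chrom, mirror - hi, mirror - lo)
            for lo, hi in exon_bounds
        )
        ref, alt = "C", "A"  # genomic complement of the coding-strand change
    else:
        raise ValueError("strand must be '+' or '-'")
    if exons[0].start_bp < 1:
        raise ValueError(
            "impossible geometry: transcript extends below position 1; "
            "increase variant_pos_bp or shrink the transcript"
        )
    model = TranscriptModel(
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=exons[0].start_bp,
        cds_end=exons[-1].end_bp,
        cds_sequence=cds,
    )
    variant = VariantRecord(
        chrom=chrom, pos_bp=variant_pos_bp, ref_allele=ref, alt_allele=alt
    )
    return model, variant


def emit_nmd_counts(
    true_cdna_mutant_fraction: float,
    depth_gdna: int,
    depth_cdna: int,
    seed: int = 0,
) -> tuple[AlleleCounts, AlleleCounts]:
    """Paired allele counts: gDNA binomial at 0.5, cDNA at the supplied
    mutant fraction."""
    if not 0.0 <= true_cdna_mutant_fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if depth_gdna <= 0 or depth_cdna <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    g_alt = int(rng.binomial(depth_gdna, 0.5))
    c_alt = int(rng.binomial(depth_cdna, true_cdna_mutant_fraction))
    return (
        AlleleCounts("gdna", depth_gdna - g_alt, g_alt),
        AlleleCounts("cdna", depth_cdna - c_alt, c_alt),
    )
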