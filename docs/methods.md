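# Methods

## Study design emulated

The pipeline targets the mapping design of a rare fully penetrant
autosomal recessive disorder in a closed, inbred population: three
affected half-siblings and their four parents genotyped on a dense
biallelic SNP array; two affected and two obligate-carrier individuals
whole-genome sequenced together with a panel of 75 unrelated controls;
and Sanger-style allele counts from one carrier's gDNA and cDNA. All
coordinates are 1-based inclusive internally (VCF convention); BED's
0-based half-open coordinates appear only at file boundaries. Interval
*length* is defined as `end − start` (a plain coordinate difference),
because published interval spans are differences of the printed
boundary coordinates; with that convention every printed number stays
literal.

## Synthetic data generator

`autozyg.sim` produces every input with known ground truth.

**Population model.** A pool of ancestral haplotypes (default 20) over
an evenly spaced, jittered marker map. Per-marker second-allele
frequencies are drawn from Beta(2, 2) — a unimodal spread around 0.5
chosen to mimic the common-variant ascertainment of commercial arrays;
haplotypes are independent Bernoulli draws per marker (no background
LD). Exactly one pool haplotype carries the causal allele; with
hundreds of markers its marker background is unique in the pool with
overwhelming probability, so autozygosity for it is detectable as
allele-identical homozygosity.

**Gene drop.** Founders draw haplotypes from the pool *with
replacement* — the inbreeding assumption that lets all four parents
carry identical-by-descent copies of the causal haplotype. Founders who
are parents of affected offspring (obligate carriers) are assigned one
copy of the causal haplotype outright; affected founders two. Each
meiosis draws a Poisson crossover count (rate = genetic length in
Morgans; genetic distance = physical distance × 1 cM/Mb, linear map, no
interference) with uniformly placed crossovers. Each offspring's pair
of gametes is resampled until its causal genotype matches its recorded
affection status (bounded at 10,000 retries). Because affection depends
only on the individual's own genotype given its parents, per-offspring
resampling in topological order is exact conditional sampling of the
drop given the affection pattern — equivalent to, but enormously
cheaper than, whole-pedigree rejection.

**Default study conditions.** 4 chromosomes × 40 Mb × 1200 markers
(4800 markers, ~30 per Mb — a desk-scale stand-in for a 670k genome-wide
array), causal locus mid-chromosome 2; genotype missingness 0.005 and
error rate 0.001 per call (array-typical placeholders, configurable,
as real per-call rates are rarely published); WGS tier of 2 cases, 2
carriers, 75 controls with 2000 background variants at Beta(1, 3)
population frequencies under Hardy–Weinberg, 2% of which mimic partial
cosegregation (case/carrier pattern but carrier-like controls) to
exercise the cascade's intermediate counts; 5% of control calls at the
causal site are missing. The transcript fixture is a 650-codon CDS
split over 4 exons whose codon 130 is GAG; the planted variant is the
first-base G>T creating a TAG stop (c.388G>T, p.Glu130*), placed at the
causal position. cDNA mutant fraction for the NMD counts defaults to
0.25 at depth 100 — a moderate depletion consistent with partial decay.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: background linkage disequilibrium and
haplotype-block structure, marker ascertainment bias, batch/plate
effects, relatedness between the WGS samples at background variants
(all samples draw Hardy–Weinberg genotypes independently there),
sequencing depth/quality variation, and multi-generation pedigree
complexity beyond the half-sib design.

## Marker QC

Criteria are applied in a fixed order — noninformative, sex chromosome,
missing-in-any-study-individual, Mendel error, minor allele frequency —
and each removed marker is attributed to the *first* failing criterion,
making the report a deterministic partition. "Noninformative" means
all non-missing study genotypes identical (this subsumes monomorphic
and also drops all-heterozygous columns). MAF is computed within the
study individuals, since family-based pruning is what the design calls
for; the folded frequency uses non-missing calls only. The Mendelian
check is single-locus and only fires when child and both parents are
typed. Samples under 95% call rate are excluded before any marker
statistic. Two QC profiles are used: the full cascade ahead of linkage,
and a homozygosity-mapping profile that keeps low-MAF and monomorphic
markers (an ROH is evidence regardless of frequency) and drops only
sex-chromosome, Mendel-error, and missing-in-any-case markers.

## Parametric linkage

Single-point, two-locus likelihood: each individual's latent state is
an ordered diplotype over four haplotypes (disease allele × marker
allele), 16 states. Founder priors factorize as products of the disease
allele frequency q (default 0.7 — the frequency is a property of the
breed's carrier pool, not of the disorder) and the per-marker allele
frequency, i.e. linkage equilibrium. Penetrances default to (0, 0, 1):
fully penetrant recessive. Marker allele frequencies are estimated from
typed founders with one pseudo-observation per allele (0.5 when no
founder is typed); transmissions recombine with probability θ.

The likelihood is evaluated by peeling, implemented as exact variable
elimination on the pedigree's factor graph with a static min-degree
order and per-individual support pruning; all θ grid points (0 to 0.5,
step 0.01) are evaluated in one vectorized pass. Elimination handles
looped (inbred) pedigrees natively, so no loop-breaking transformation
is needed. Impossible data yield a likelihood of zero, represented as
−∞ log-likelihood that propagates through LOD arithmetic (−∞ compares
below any finite value); ties in the LOD maximum resolve to the
smallest θ.

**Region assembly.** Single-point scans differ from multipoint ones in
one important way: a marker at which the phase-informative parent is
homozygous carries *no* linkage information — its LOD curve is exactly
flat — rather than evidence against linkage. (In the half-sib design
nearly all information flows through the shared parent: each other
parent has a single offspring, and one transmission cannot fix a
phase.) Candidate regions are therefore maximal runs of positive-LOD
markers (max LOD > 10⁻⁹) that tolerate interspersed flat (neutral)
markers and are broken by markers whose curve dips negative at tight
linkage (evidence against) or by chromosome changes; the interval spans
the outermost positive markers, and runs spanning ≤ 1 Mb are discarded.
Breaking runs at flat markers would fragment support regions wherever
the shared parent happens to be homozygous, which is the single-point
artifact the tolerance removes.

Single-point LOD with region assembly is this package's deliberate
replacement for a multipoint (Lander–Green/Elston–Stewart multipoint)
computation: it is self-contained, exactly testable against an
enumeration oracle, and over dense maps its positive-run regions
approximate multipoint support regions.

## Runs of homozygosity

The windowed algorithm popularized by PLINK, with its documented
defaults exposed as parameters: 50-SNP windows, ≤1 heterozygote and ≤5
missing calls per window, per-SNP window-hit fraction ≥ 0.05, minimum
run of 1 Mb and 100 SNPs. Chromosomes shorter than the window fall back
to a single window. Shared ROH across cases is the pairwise
intersection of all cases' segments, kept only where the cases carry
identical homozygous genotypes at ≥ 99% of mutually typed markers (the
1% slack absorbs genotyping error; missing calls are excluded from the
denominator — they neither confirm nor break sharing) and where the
overlap still clears the minimum length. Boundary compilation then
extends each shared interval marker-by-marker outward while every case
stays homozygous-identical — a deterministic, reproducible replacement
for by-eye inspection of raw genotypes.

## Critical intervals

Linkage regions ∩ shared ROH, then merging of consecutive
same-chromosome intervals whose gap (`next.start − prev.end`) is
strictly below 1.5 Mb — the conservative rule for treating a run of
autozygous segments interrupted only by small non-homozygous stretches
as one interval. Spans are `(end − start)/10⁶`, rounded half-up.

## Segregation filter

The cascade keeps records that are homozygous-alternate in every case
and heterozygous in every carrier (a homozygous-alternate "carrier"
contradicts obligate-carrier status under full penetrance and
disqualifies the record); controls must be homozygous reference, with
missing calls also accepted unless strict mode is set. Indels are
treated exactly like SNVs. The main report chain — pattern, +controls,
in-intervals, protein-changing — is monotone non-increasing by
construction; per-chromosome interval counts are reported alongside.
"Protein-changing" covers missense, nonsense, frameshift, in-frame
indels, and canonical splice — the complement of synonymous/noncoding.

## Consequence annotation

CDS coordinates follow HGVS `c.` numbering (nucleotide 1 = A of the
initiator ATG), codons and residues are 1-based with Met1, and on the
minus strand CDS coordinates count from the 3′ genomic side with
alleles complemented. The reference allele is checked against the CDS
sequence and a mismatch is an error, not a silent skip. Splice
annotation is limited to the canonical ±2 bp intronic dinucleotides.
A premature stop at codon k of an L-codon ORF truncates
`(L − (k − 1))/L` of it — the stop codon's own position counts as
lost. The terminal stop codon is included in L only when the supplied
CDS includes it; the fixture generator excludes it.

## NMD allele-balance test

Chromatogram peak heights are abstracted as integer allele counts. Each
source's alternate fraction is tested against 0.5 with an exact
two-sided binomial test and the two sources are compared with Fisher's
exact test on the 2×2 table; exact tests because depths may be small.
Classification is directional on the alternate allele while reported
p-values stay two-sided: `complete_absence` (no alternate reads in
cDNA, gDNA consistent with 1:1), `partial_nmd` (cDNA significantly
below 0.5, gDNA not off 1:1, sources significantly different),
`no_depletion` (nothing significant), `inconclusive` otherwise. At
depth 100 and α = 0.05 the partial-NMD false-call rate is well below α
(the call requires two significant tests jointly) and power at a true
cDNA fraction of 0.2 is above 0.9.

## Numerical and implementation choices

- θ grid {0, 0.01, …, 0.5}; positivity tolerance 10⁻⁹ on LOD values;
  −∞ propagation instead of exceptions for impossible configurations.
- Multi-allelic VCF sites are decomposed per alternate allele;
  genotypes referencing another alternate become missing for that
  record; half-calls and non-diploid genotypes are missing with a
  warning.
- PED/MAP allele pairs are inferred per marker as the sorted observed
  symbols; monomorphic markers carry `"0"` as the unobserved second
  symbol.
- All randomness flows through numpy Generators seeded from a single
  run seed; fixed config + seed reproduces byte-identical outputs.
- Rounding of Mb spans is decimal half-up (not banker's).

## Problem sizes

The default simulated study uses 4 chromosomes × 40 Mb × 1200 markers
and a 2000-variant WGS tier; one full simulate-and-analyze cycle takes
under a second on a laptop core, and the 20-replicate recovery study a
few seconds. These sizes were chosen so that the complete analysis,
its oracle cross-checks (exhaustive pedigree enumeration up to 8
members, naive ROH scans up to 500 SNPs), and the calibration studies
are routine to re-run while leaving all mapping signals comfortably
detectable.

## Known limitations

- Single-point linkage cannot use flanking-marker information;
  uninformative markers are bridged at the region-assembly stage rather
  than through the likelihood.
- The likelihood assumes marker–disease linkage equilibrium in
  founders; in a truly inbred pool the causal haplotype's marker
  background violates this, which inflates neither the type-I rate nor
  the recovery criterion here but would bias fine-scale θ estimates.
- `shared_roh` requires every case to contribute a detected segment; a
  case whose ROH is shattered below the run thresholds removes the
  region entirely rather than degrading it gracefully.
- The annotation model is single-transcript per gene, without
  NMD-escape (last-exon) rules or protein-domain context.
- The WGS background ignores relatedness between family samples, so
  background variants never mimic true identity-by-descent sharing
  beyond the configured cosegregation fraction.
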