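"""Single-point parametric linkage analysis under a recessive disease model.

For each marker the pedigree likelihood is computed over the joint
two-locus (disease locus + marker) genotype space.  Every individual's
latent state is an *ordered* diplotype: a paternal and a maternal
haplotype, each haplotype one of four (disease allele x marker allele),
giving 16 states.  Founder haplotype frequencies factorize as the
product of the disease- and marker-allele frequencies (linkage
equilibrium); transmissions recombine with probability theta; affection
status enters through the penetrance vector and marker genotypes
through a consistency indicator.

The likelihood is evaluated by peeling: the factor graph over
individuals (founder priors, penetrance/observation terms, one
transmission factor per non-founder) is contracted by variable
elimination, with states incompatible with the observed data pruned
from each individual's support first.  The elimination handles looped
(inbred) pedigrees natively, so no loop-breaking is required.  All
values are evaluated on the whole theta grid at once.

LOD(theta) = log10 L(theta) - log10 L(0.5).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import GenomeInterval, GenotypeCall, MarkerDataset, Marker, Pedigree

__all__ = [
    "DiseaseModel",
    "LodResult",
    "pedigree_log_likelihood",
    "lod_score",
    "scan",
    "linked_regions",
    "founder_allele_freq",
    "DEFAULT_THETA_GRID",
]

DEFAULT_THETA_GRID: tuple[float, ...] = tuple(
    float(np.round(0.01 * i, 2)) for i in range(51)
)

# haplotype index h = 2*d + m: d = disease allele (1 = disease), m = marker allele
_HAP_D = np.array([0, 0, 1, 1])
_HAP_M = np.array([0, 1, 0, 1])
# ordered diplotype state s = 4*paternal_hap + maternal_hap
_STATE_PAT = np.repeat(np.arange(4), 4)
_STATE_MAT = np.tile(np.arange(4), 4)
_N_DISEASE = _HAP_D[_STATE_PAT] + _HAP_D[_STATE_MAT]  # disease-allele dosage
_MARKER_DOSE = _HAP_M[_STATE_PAT] + _HAP_M[_STATE_MAT]  # marker alt dosage

# observation masks per genotype call (missing -> all ones)
_OBS_MASK = {
    c: (_MARKER_DOSE == c).astype(float) for c in (0, 1, 2)
}
_OBS_MASK[-1] = np.ones(16)


@dataclass(frozen=True)
class DiseaseModel:
    """Fully parameterized single-locus disease model.

    ``penetrances`` are P(affected | 0, 1, 2 disease alleles); the
    default (0, 0, 1) is a fully penetrant autosomal recessive model.
    """

    disease_allele_freq: float = 0.7
    penetrances: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must lie in (0, 1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")


@dataclass
class LodResult:
    marker: Marker
    lod_at_theta: dict[float, float]
    max_lod: float
    theta_hat: float
    flagged: bool = False  # all-missing or degenerate marker


def _gamete_probs(thetas: np.ndarray) -> np.ndarray:
    """P(gamete haplotype | parent state) -> array (n_theta, 4, 16)."""
    nT = len(thetas)
    out = np.zeros((nT, 4, 16))
    half_same = (1.0 - thetas) / 2.0
    half_diff = thetas / 2.0
    for parent in range(16):
        haps = (int(_STATE_PAT[parent]), int(_STATE_MAT[parent]))
        for g in range(4):
            dg, mg = int(_HAP_D[g]), int(_HAP_M[g])
            for i in (0, 1):
                for j in (0, 1):
                    if _HAP_D[haps[i]] == dg and _HAP_M[haps[j]] == mg:
                        out[:, g, parent] += half_same if i == j else half_diff
    return out


def _transmission_tensor(thetas: np.ndarray) -> np.ndarray:
    """P(child state | father state, mother state): (n_theta, 16, 16, 16)."""
    G = _gamete_probs(thetas)
    pat = G[:, _STATE_PAT, :]  # (nT, child, father)
    mat = G[:, _STATE_MAT, :]  # (nT, child, mother)
    return pat[:, :, :, None] * mat[:, :, None, :]


def _penetrance_vector(affection, model: DiseaseModel) -> np.ndarray:
    from .types import Affection

    pen = np.asarray(model.penetrances)
    if affection is Affection.AFFECTED:
        return pen[_N_DISEASE].astype(float)
    if affection is Affection.UNAFFECTED:
        return (1.0 - pen[_N_DISEASE]).astype(float)
    return np.ones(16)


def _founder_prior(marker_freq: float, model: DiseaseModel) -> np.ndarray:
    q = model.disease_allele_freq
    pd = np.array([1.0 - q, q])
    pm = np.array([1.0 - marker_freq, marker_freq])
    hap = pd[_HAP_D] * pm[_HAP_M]
    return hap[_STATE_PAT] * hap[_STATE_MAT]


def _contract(touching, elim_var):
    """Multiply factors sharing ``elim_var`` and sum it out (theta axis
    broadcasts through the einsum ellipsis)."""
    vars_union: list[str] = []
    for vs, _ in touching:
        for v in vs:
            if v not in vars_union:
                vars_union.append(v)
    letters = {v: string.ascii_letters[i] for i, v in enumerate(vars_union)}
    lhs = ",".join(
        "..." + "".join(letters[v] for v in vs) for vs, _ in touching
    )
    out_vars = tuple(v for v in vars_union if v != elim_var)
    rhs = "..." + "".join(letters[v] for v in out_vars)
    arr = np.einsum(lhs + "->" + rhs, *[a for _, a in touching])
    return (out_vars, arr)


def _elimination_order(pedigree: Pedigree) -> list[str]:
    """Static greedy (min-fill-ish) elimination order on the pedigree's
    moral graph; computed once per pedigree and reused for every marker."""
    neighbors: dict[str, set[str]] = {ind.id: set() for ind in pedigree}
    for ind in pedigree.nonfounders:
        trio = [ind.id]
        if ind.sire_id:
            trio.append(ind.sire_id)
        if ind.dam_id:
            trio.append(ind.dam_id)
        for a in trio:
            for b in trio:
                if a != b:
                    neighbors[a].add(b)
    order = []
    remaining = set(neighbors)
    while remaining:
        v = min(remaining, key=lambda x: (len(neighbors[x] & remaining), x))
        order.append(v)
        nb = neighbors[v] & remaining
        for a in nb:
            neighbors[a].update(nb - {a})
        remaining.discard(v)
    return order


class _Peeler:
    """Reusable peeling machinery for one pedigree and one theta grid."""

    def __init__(self, pedigree: Pedigree, model: DiseaseModel,
                 thetas: Sequence[float]):
        self.pedigree = pedigree
        self.model = model
        self.thetas = np.asarray(thetas, dtype=float)
        if np.any((self.thetas < 0) | (self.thetas > 0.5)):
            raise ValueError("theta must lie in [0, 0.5]")
        for ind in pedigree.nonfounders:
            if (ind.sire_id is None) != (ind.dam_id is None):
                raise ValueError(
                    f"individual {ind.id!r} has exactly one parent; the "
                    "likelihood requires both parents or none"
                )
        self.trans = _transmission_tensor(self.thetas)
        self.pen = {
            ind.id: _penetrance_vector(ind.affection, model)
            for ind in pedigree
        }
        self.order = _elimination_order(pedigree)

    def loglik(self, calls: dict[str, int], marker_freq: float) -> np.ndarray:
        """log10 likelihood on the theta grid; -inf where the data are
        impossible under the model."""
        ped = self.pedigree
        prior = _founder_prior(marker_freq, self.model)
        unary: dict[str, np.ndarray] = {}
        support: dict[str, np.ndarray] = {}
        for ind in ped:
            u = self.pen[ind.id] * _OBS_MASK[int(calls.get(ind.id, -1))]
            if ind.is_founder:
                u = u * prior
            sup = np.nonzero(u > 0)[0]
            if sup.size == 0:
                return np.full(len(self.thetas), -np.inf)
            unary[ind.id] = u[sup]
            support[ind.id] = sup

        factors = []
        folded: set[str] = set()
        for ind in ped.nonfounders:
            arr = self.trans[
                np.ix_(
                    np.arange(len(self.thetas)),
                    support[ind.id],
                    support[ind.sire_id],
                    support[ind.dam_id],
                )
            ]
            arr = arr * unary[ind.id][None, :, None, None]
            folded.add(ind.id)
            factors.append(((ind.id, ind.sire_id, ind.dam_id), arr))
        for ind in ped:
            if ind.id not in folded:
                factors.append(((ind.id,), unary[ind.id][None, :]))

        for v in self.order:
            touching = [f for f in factors if v in f[0]]
            if not touching:
                continue
            rest = [f for f in factors if v not in f[0]]
            factors = rest + [_contract(touching, v)]

        result = np.ones(len(self.thetas))
        for vs, arr in factors:
            assert not vs
            result = result * arr.reshape(-1) if arr.shape[0] > 1 else result * arr.reshape(-1)[0]
        with np.errstate(divide="ignore"):
            return np.log10(result)


def pedigree_log_likelihood(
    pedigree: Pedigree,
    genotypes: dict[str, GenotypeCall],
    marker_allele_freq: float,
    disease_model: DiseaseModel = DiseaseModel(),
    theta: float = 0.0,
) -> float:
    """log10 P(marker genotypes, affection | theta, model).

    Returns ``-inf`` (not an exception) when the data are impossible
    under the model, e.g. an affected child of two genotype-proven
    non-carriers under full penetrance.
    """
    peeler = _Peeler(pedigree, disease_model, [theta])
    calls = {s: int(c) for s, c in genotypes.items()}
    return float(peeler.loglik(calls, marker_allele_freq)[0])


def founder_allele_freq(
    pedigree: Pedigree, dataset: MarkerDataset, marker_idx: int,
    pseudocount: float = 1.0,
) -> float:
    """Second-allele frequency estimated from typed founders with one
    pseudo-observation per allele; 0.5 when no founder is typed."""
    alt = 0.0
    n = 0
    for ind in pedigree.founders:
        if ind.id not in dataset._sample_idx:
            continue
        g = int(dataset.genotypes[dataset.sample_index(ind.id), marker_idx])
        if g >= 0:
            alt += g
            n += 2
    if n == 0:
        return 0.5
    return (alt + pseudocount) / (n + 2 * pseudocount)


def _lod_from_loglik(ll: np.ndarray, thetas: np.ndarray, marker: Marker,
                     flagged: bool = False) -> LodResult:
    i05 = int(np.argmin(np.abs(thetas - 0.5)))
    if abs(thetas[i05] - 0.5) > 1e-12:
        raise ValueError("theta grid must include 0.5")
    ll05 = ll[i05]
    if not np.isfinite(ll05):
        # data impossible even under free recombination: no linkage evidence
        lod = np.zeros_like(ll)
        flagged = True
    else:
        lod = ll - ll05
    max_lod = float(np.max(lod))
    theta_hat = float(thetas[int(np.argmax(lod == max_lod))])
    return LodResult(
        marker=marker,
        lod_at_theta={float(t): float(v) for t, v in zip(thetas, lod)},
        max_lod=max_lod,
        theta_hat=theta_hat,
        flagged=flagged,
    )


def lod_score(
    pedigree: Pedigree,
    marker_idx: int,
    dataset: MarkerDataset,
    disease_model: DiseaseModel = DiseaseModel(),
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> LodResult:
    """LOD curve for one marker; allele frequency from typed founders."""
    peeler = _Peeler(pedigree, disease_model, theta_grid)
    return _scan_one(pedigree, marker_idx, dataset, peeler)


def _scan_one(pedigree, j, dataset, peeler) -> LodResult:
    marker = dataset.markers[j]
    calls = {}
    any_typed = False
    for ind in pedigree:
        if ind.id in dataset._sample_idx:
            c = int(dataset.genotypes[dataset.sample_index(ind.id), j])
            calls[ind.id] = c
            any_typed = any_typed or c >= 0
    if not any_typed:
        thetas = peeler.thetas
        return LodResult(
            marker=marker,
            lod_at_theta={float(t): 0.0 for t in thetas},
            max_lod=0.0,
            theta_hat=0.5,
            flagged=True,
        )
    freq = founder_allele_freq(pedigree, dataset, j)
    ll = peeler.loglik(calls, freq)
    return _lod_from_loglik(ll, peeler.thetas, marker)


def scan(
    pedigree: Pedigree,
    dataset: MarkerDataset,
    disease_model: DiseaseModel = DiseaseModel(),
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> list[LodResult]:
    """Genome-wide single-point LOD scan (one result per marker)."""
    peeler = _Peeler(pedigree, disease_model, theta_grid)
    return [
        _scan_one(pedigree, j, dataset, peeler)
        for j in range(dataset.n_markers)
    ]


def linked_regions(
    results: list[LodResult],
    min_length_bp: float = 1e6,
    lod_tol: float = 1e-9,
) -> list[GenomeInterval]:
    """Assemble positive-LOD marker runs into candidate linked regions.

    Markers are classified by their LOD curve: *positive* when
    ``max_lod > lod_tol``; *negative* when the maximum is zero but the
    curve dips below ``-lod_tol`` at tight linkage (evidence against);
    *neutral* when the curve is flat (an uninformative marker, e.g. one
    where the phase-informative parent is homozygous — such markers
    carry no linkage information in a single-point scan and must not
    break a support region, the way they would not in a multipoint
    scan).  A region is a maximal run of positive markers, tolerant of
    interspersed neutral markers and broken by negative markers or
    chromosome changes; its interval spans the first to last *positive*
    marker.  Regions whose span (end - start) is <= ``min_length_bp``
    are discarded.
    """
    out: list[GenomeInterval] = []
    run: list[LodResult] = []

    def close_run():
        if run:
            span = run[-1].marker.pos_bp - run[0].marker.pos_bp
            if span > min_length_bp:
                out.append(
                    GenomeInterval(
                        run[0].marker.chrom,
                        run[0].marker.pos_bp,
                        run[-1].marker.pos_bp,
                    )
                )
            run.clear()

    prev_chrom: Optional[str] = None
    for r in results:
        if r.marker.chrom != prev_chrom:
            close_run()
            prev_chrom = r.marker.chrom
        if r.max_lod > lod_tol:
            run.append(r)  # positive: extends (and may start) a run
        elif min(r.lod_at_theta.values()) < -lod_tol:
            close_run()  # negative evidence at some theta: break
        # else neutral: flat curve, neither breaks nor extends
    close_run()
    return out


def write_lod_table(results: list[LodResult], path) -> None:
    from .io import _provenance

    with open(path, "w") as fh:
        fh.write(_provenance("single-point LOD scan"))
        fh.write("marker\tchrom\tpos\tmaxLOD\ttheta_hat\n")
        for r in results:
            fh.write(
                f"{r.marker.name}\t{r.marker.chrom}\t{r.marker.pos_bp}\t"
                f"{r.max_lod:.6f}\t{r.theta_hat:.2f}\n"
            )
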