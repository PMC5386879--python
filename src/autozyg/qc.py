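"""Marker and sample quality control for family-based mapping.

The pruning mirrors the standard pre-linkage cleanup of a dense SNP-array
dataset: drop markers that are noninformative (monomorphic across the
study individuals), on the sex chromosomes, missing in any study
individual, inconsistent with Mendelian transmission, or below a minor
allele frequency threshold.  Samples whose call rate falls below a
threshold are excluded before any marker statistics are computed.

Each removed marker is attributed to the *first* failing criterion in
the order listed above, which makes the removal report a deterministic
partition of the input markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeCall, MarkerDataset, Pedigree

__all__ = [
    "QcCriteria",
    "QcReport",
    "sample_call_rate",
    "minor_allele_frequency",
    "detect_mendel_errors",
    "prune_markers",
]

# Attribution order for removal counts (first failing criterion wins).
CRITERIA_ORDER = (
    "noninformative",
    "sex_chromosome",
    "missing_in_study",
    "mendel_error",
    "low_maf",
)


@dataclass(frozen=True)
class QcCriteria:
    min_maf: float = 0.2
    excluded_chroms: frozenset[str] = frozenset({"X", "Y"})
    max_missing_in_study: int = 0
    drop_mendel_error_markers: bool = True
    drop_noninformative: bool = True
    min_sample_call_rate: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass
class QcReport:
    removed: dict[str, int] = field(default_factory=dict)
    n_input_markers: int = 0
    n_surviving_markers: int = 0
    sample_call_rates: dict[str, float] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)

    def check_partition(self) -> bool:
        return sum(self.removed.values()) + self.n_surviving_markers == self.n_input_markers


def sample_call_rate(dataset: MarkerDataset, sample: str) -> float:
    """Fraction of non-missing calls for one sample."""
    row = dataset.genotypes[dataset.sample_index(sample)]
    if dataset.n_markers == 0:
        return 1.0
    return float(np.mean(row != GenotypeCall.MISSING))


def minor_allele_frequency(dataset: MarkerDataset, marker_idx: int,
                           samples: list[str] | None = None) -> float:
    """Folded allele frequency in [0, 0.5] over non-missing study calls.

    Raises ``ValueError`` when every call is missing (such a marker is
    flagged noninformative by :func:`prune_markers` instead).
    """
    rows = (
        slice(None)
        if samples is None
        else [dataset.sample_index(s) for s in samples]
    )
    col = dataset.genotypes[rows, marker_idx]
    typed = col[col != GenotypeCall.MISSING]
    if typed.size == 0:
        raise ValueError(f"marker index {marker_idx}: all calls missing")
    f = float(typed.sum()) / (2 * typed.size)
    return min(f, 1.0 - f)


# child alt-dosage sets compatible with (sire, dam) dosages
_ALLOWED = {}
for gf in (0, 1, 2):
    for gm in (0, 1, 2):
        pat = {0, 1} if gf == 1 else {gf // 2}
        mat = {0, 1} if gm == 1 else {gm // 2}
        _ALLOWED[(gf, gm)] = {p + m for p in pat for m in mat}


def detect_mendel_errors(
    pedigree: Pedigree, dataset: MarkerDataset
) -> list[tuple[int, str]]:
    """Single-locus Mendelian-consistency check.

    Returns (marker_index, offspring_id) pairs where the offspring
    genotype is impossible given both parents' non-missing genotypes.
    Any missing call in the trio exempts the marker for that trio.
    """
    errors: list[tuple[int, str]] = []
    g = dataset.genotypes
    for ind in pedigree.nonfounders:
        if ind.sire_id is None or ind.dam_id is None:
            continue
        if not all(p in dataset._sample_idx for p in (ind.sire_id, ind.dam_id, ind.id)):
            continue
        gc = g[dataset.sample_index(ind.id)]
        gf = g[dataset.sample_index(ind.sire_id)]
        gm = g[dataset.sample_index(ind.dam_id)]
        typed = (gc >= 0) & (gf >= 0) & (gm >= 0)
        idx = np.nonzero(typed)[0]
        for j in idx:
            if int(gc[j]) not in _ALLOWED[(int(gf[j]), int(gm[j]))]:
                errors.append((int(j), ind.id))
    return errors


def prune_markers(
    pedigree: Pedigree,
    dataset: MarkerDataset,
    criteria: QcCriteria = QcCriteria(),
    study_samples: list[str] | None = None,
) -> tuple[MarkerDataset, QcReport]:
    """Apply the full marker-pruning cascade.

    ``study_samples`` restricts the missingness/MAF/informativeness
    statistics to a subset (default: every pedigree member present in
    the dataset).  Low-call-rate samples are excluded from the dataset
    (and the study set) before any marker statistic is computed.
    """
    report = QcReport(n_input_markers=dataset.n_markers)
    report.sample_call_rates = {
        s: sample_call_rate(dataset, s) for s in dataset.samples
    }
    report.excluded_samples = [
        s
        for s, r in report.sample_call_rates.items()
        if r < criteria.min_sample_call_rate
    ]
    if report.excluded_samples:
        keep = [s for s in dataset.samples if s not in report.excluded_samples]
        dataset = dataset.subset(samples=keep)

    if study_samples is None:
        study = [s for s in dataset.samples if s in pedigree]
    else:
        study = [s for s in study_samples if s in dataset._sample_idx]
    if not study:
        study = list(dataset.samples)
    rows = [dataset.sample_index(s) for s in study]
    g = dataset.genotypes[rows, :]
    typed = g != GenotypeCall.MISSING
    n_typed = typed.sum(axis=0)
    n_missing = len(study) - n_typed

    # noninformative: all non-missing study calls identical (or none typed)
    gmask = np.where(typed, g, np.int8(-2))
    col_min = np.where(typed, g, np.int8(3)).min(axis=0)
    col_max = gmask.max(axis=0)
    noninformative = (n_typed == 0) | (col_min == col_max)

    chroms = np.array([m.chrom for m in dataset.markers])
    sexchrom = np.isin(chroms, list(criteria.excluded_chroms))

    too_missing = n_missing > criteria.max_missing_in_study

    mendel = np.zeros(dataset.n_markers, dtype=bool)
    if criteria.drop_mendel_error_markers:
        for j, _iid in detect_mendel_errors(pedigree, dataset):
            mendel[j] = True

    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_typed > 0, g.clip(min=0).sum(axis=0) / (2 * np.maximum(n_typed, 1)), 0.0)
    maf = np.minimum(f, 1.0 - f)
    low_maf = (maf < criteria.min_maf) & (n_typed > 0)

    fail = {
        "noninformative": noninformative if criteria.drop_noninformative else np.zeros_like(noninformative),
        "sex_chromosome": sexchrom,
        "missing_in_study": too_missing,
        "mendel_error": mendel,
        "low_maf": low_maf,
    }
    removed_by = np.full(dataset.n_markers, -1, dtype=int)
    for rank, name in enumerate(CRITERIA_ORDER):
        newly = fail[name] & (removed_by < 0)
        removed_by[newly] = rank
        report.removed[name] = int(newly.sum())

    keep_mask = removed_by < 0
    report.n_surviving_markers = int(keep_mask.sum())
    if report.n_surviving_markers == 0:
        raise ValueError(
            "marker pruning removed every marker; review QC criteria "
            f"(removals: {report.removed})"
        )
    pruned = dataset.subset(marker_mask=keep_mask)
    return pruned, report


def write_qc_report(report: QcReport, path) -> None:
    from .io import _provenance

    with open(path, "w") as fh:
        fh.write(_provenance("marker QC report"))
        fh.write("criterion\tremoved\n")
        for name in CRITERIA_ORDER:
            fh.write(f"{name}\t{report.removed.get(name, 0)}\n")
        fh.write(f"surviving\t{report.n_surviving_markers}\n")
        fh.write(f"input\t{report.n_input_markers}\n")
        for s, r in report.sample_call_rates.items():
            fh.write(f"call_rate:{s}\t{r:.6f}\n")
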