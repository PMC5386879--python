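"""Shared domain types and genome-coordinate conventions.

All genomic coordinates in this package are 1-based with inclusive
endpoints (the convention of VCF and of published interval boundaries).
Conversion to BED's 0-based half-open coordinates happens only at the
file boundary (see :mod:`autozyg.io`).

Interval *length* is defined as ``end_bp - start_bp`` (a plain coordinate
difference, not the inclusive base count).  Published autozygosity spans
are coordinate differences, so this keeps every printed number literal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Sex",
    "Affection",
    "GenotypeCall",
    "Individual",
    "Pedigree",
    "Marker",
    "MarkerDataset",
    "GenomeInterval",
    "VariantRecord",
    "PedigreeError",
    "FormatError",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


class FormatError(ValueError):
    """Raised for malformed input files (carries a line-number context)."""


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class GenotypeCall(IntEnum):
    """Biallelic genotype as an ordered alternate-allele count.

    The integer values are the codes used in genotype matrices
    (``-1`` marks a missing call), so ``GenotypeCall`` compares equal
    to raw matrix entries.
    """

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1

    @property
    def is_hom(self) -> bool:
        return self in (GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT)

    @property
    def alt_count(self) -> Optional[int]:
        return None if self is GenotypeCall.MISSING else int(self)


@dataclass(frozen=True)
class Individual:
    """A pedigree member.

    An individual is a founder iff *both* parent ids are ``None``.
    """

    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """An ordered collection of individuals with resolved parent links.

    Invariants enforced at construction: ids are unique, parent ids
    (when present) resolve within the pedigree, and no individual is
    its own ancestor.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if iid in (ind.sire_id, ind.dam_id)
        ]

    def topological_order(self) -> list[Individual]:
        """Parents before offspring."""
        order: list[Individual] = []
        done: set[str] = set()

        def visit(ind: Individual) -> None:
            if ind.id in done:
                return
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    visit(self._by_id[pid])
            done.add(ind.id)
            order.append(ind)

        for ind in self.individuals:
            visit(ind)
        return order


@dataclass(frozen=True)
class Marker:
    """A biallelic array marker; ``alleles`` is (first, second) and
    genotype codes count copies of the *second* allele."""

    name: str
    chrom: str
    pos_bp: int
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.name}: pos_bp must be >= 1")


class MarkerDataset:
    """Marker map plus a sample x marker genotype matrix.

    The matrix holds int8 codes 0/1/2 (second-allele count) with -1 for
    missing; :class:`GenotypeCall` members compare equal to the codes.
    """

    def __init__(self, markers: list[Marker], samples: list[str], genotypes):
        self.markers = list(markers)
        self.samples = list(samples)
        g = np.asarray(genotypes, dtype=np.int8)
        if g.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.genotypes = g
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_idx[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in dataset") from None

    def call(self, sample: str, marker_idx: int) -> GenotypeCall:
        return GenotypeCall(int(self.genotypes[self.sample_index(sample), marker_idx]))

    def sort_by_position(self) -> "MarkerDataset":
        """Return a copy with markers sorted by (chrom, pos); positions
        must then be strictly increasing within each chromosome."""
        order = sorted(
            range(self.n_markers),
            key=lambda i: (self.markers[i].chrom, self.markers[i].pos_bp, self.markers[i].name),
        )
        markers = [self.markers[i] for i in order]
        for a, b in zip(markers, markers[1:]):
            if a.chrom == b.chrom and b.pos_bp <= a.pos_bp:
                raise ValueError(
                    f"markers {a.name} and {b.name} share or invert position "
                    f"on {a.chrom}"
                )
        return MarkerDataset(markers, self.samples, self.genotypes[:, order])

    def subset(self, samples=None, marker_mask=None) -> "MarkerDataset":
        g = self.genotypes
        markers = self.markers
        smp = self.samples
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask, dtype=bool)
            markers = [m for m, keep in zip(self.markers, marker_mask) if keep]
            g = g[:, marker_mask]
        if samples is not None:
            rows = [self.sample_index(s) for s in samples]
            smp = list(samples)
            g = g[rows, :]
        return MarkerDataset(markers, smp, g)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker index ranges per chromosome (map-sorted input)."""
        out: dict[str, slice] = {}
        start = 0
        for i, m in enumerate(self.markers):
            if i and m.chrom != self.markers[i - 1].chrom:
                out[self.markers[start].chrom] = slice(start, i)
                start = i
        if self.markers:
            out[self.markers[start].chrom] = slice(start, self.n_markers)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MarkerDataset)
            and self.markers == other.markers
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """1-based, inclusive-ends genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"interval start {self.start_bp} > end {self.end_bp} on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def intersection(self, other: "GenomeInterval") -> Optional["GenomeInterval"]:
        if not self.overlaps(other):
            return None
        return GenomeInterval(
            self.chrom,
            max(self.start_bp, other.start_bp),
            min(self.end_bp, other.end_bp),
        )


@dataclass
class VariantRecord:
    """A biallelic variant site with per-sample genotype calls."""

    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    id: Optional[str] = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 == len(self.alt_allele)

    def call(self, sample: str) -> GenotypeCall:
        try:
            return self.genotypes[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not genotyped at "
                           f"{self.chrom}:{self.pos_bp}") from None

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos_bp, self.ref_allele, self.alt_allele)
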