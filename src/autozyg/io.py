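"""Readers and writers for the standard text formats.

PED/MAP follow the PLINK text dialect (single family per file, two
allele columns per marker, ``0`` = missing allele).  VCF is read and
written through :mod:`pysam`; multi-allelic sites are decomposed into
one biallelic record per alternate allele, with genotypes that reference
a different alternate set to missing for that record.  BED output is
0-based half-open, converted from the package's 1-based inclusive
intervals only here, at the file boundary.

Tabular writers prepend a provenance comment (tool version and
parameters); readers skip ``#`` comment lines.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .types import (
    Affection,
    FormatError,
    GenomeInterval,
    GenotypeCall,
    Individual,
    Marker,
    MarkerDataset,
    Pedigree,
    Sex,
)

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}
_AFF_TO_PED = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}


def _provenance(params: str = "") -> str:
    line = f"# autozyg v{__version__}"
    if params:
        line += f" {params}"
    return line + "\n"


# ---------------------------------------------------------------------------
# PED / MAP


def read_map(map_path) -> list[tuple[str, str, float, int]]:
    """Read a PLINK MAP file -> list of (chrom, name, cM, bp) in file order."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}: line {lineno}: expected 4 MAP columns, "
                    f"got {len(fields)}"
                )
            chrom, name, cm, bp = fields
            rows.append((chrom, name, float(cm), int(bp)))
    return rows


def read_ped_map(ped_path, map_path) -> tuple[Pedigree, MarkerDataset]:
    """Read a PLINK text PED/MAP pair.

    Genotype codes count copies of each marker's second allele; allele
    pairs are assigned per marker as the lexicographically sorted pair
    of observed allele symbols (monomorphic markers get ``"0"`` as the
    unobserved second symbol).  ``0 0`` allele pairs map to missing;
    half-missing pairs are treated as missing with a warning.
    """
    map_rows = read_map(map_path)
    n_markers = len(map_rows)

    individuals: list[Individual] = []
    sample_ids: list[str] = []
    raw_alleles: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            expected = 6 + 2 * n_markers
            if len(fields) != expected:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {expected} columns "
                    f"(6 + 2 per marker), got {len(fields)}"
                )
            _fam, iid, sire, dam, sex, pheno = fields[:6]
            if iid in sample_ids:
                raise FormatError(
                    f"{ped_path}: line {lineno}: duplicate sample id {iid!r}"
                )
            individuals.append(
                Individual(
                    id=iid,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=_SEX_FROM_PED.get(sex, Sex.UNKNOWN),
                    affection=_AFF_FROM_PED.get(pheno, Affection.UNKNOWN),
                )
            )
            sample_ids.append(iid)
            alleles = fields[6:]
            raw_alleles.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_markers)]
            )

    markers: list[Marker] = []
    geno = np.full((len(sample_ids), n_markers), -1, dtype=np.int8)
    for j, (chrom, name, _cm, bp) in enumerate(map_rows):
        observed = sorted(
            {a for row in raw_alleles for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise FormatError(
                f"marker {name}: more than two alleles observed: {observed}"
            )
        if len(observed) == 2:
            pair = (observed[0], observed[1])
        elif len(observed) == 1:
            pair = (observed[0], "0")
        else:
            pair = ("0", "0")
        markers.append(Marker(name=name, chrom=chrom, pos_bp=bp, alleles=pair))
        for i, row in enumerate(raw_alleles):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                if (a1 == "0") != (a2 == "0"):
                    warnings.warn(
                        f"marker {name}, sample {sample_ids[i]}: half-missing "
                        "genotype treated as missing"
                    )
                continue
            geno[i, j] = (a1 == pair[1]) + (a2 == pair[1])

    return Pedigree(individuals), MarkerDataset(markers, sample_ids, geno)


def write_ped_map(
    pedigree: Pedigree,
    dataset: MarkerDataset,
    ped_path,
    map_path,
    family_id: str = "FAM1",
) -> None:
    """Write a PLINK text PED/MAP pair (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chrom}\t{m.name}\t0\t{m.pos_bp}\n")
    code_to_pair = []
    for m in dataset.markers:
        a, b = m.alleles
        code_to_pair.append({0: (a, a), 1: (a, b), 2: (b, b), -1: ("0", "0")})
    with open(ped_path, "w") as fh:
        for iid in dataset.samples:
            ind = pedigree[iid] if iid in pedigree else Individual(id=iid)
            row = [
                family_id,
                iid,
                ind.sire_id or "0",
                ind.dam_id or "0",
                _SEX_TO_PED[ind.sex],
                _AFF_TO_PED[ind.affection],
            ]
            g = dataset.genotypes[dataset.sample_index(iid)]
            for j in range(dataset.n_markers):
                row.extend(code_to_pair[j][int(g[j])])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF

from .types import VariantRecord  # noqa: E402  (grouped with VCF code)


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF 4.x file into biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per alternate
    allele; a genotype referencing a different alternate becomes missing
    for that record.  Half-calls and non-diploid genotypes are treated
    as missing with a warning.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vf.header.samples)
    out: list[VariantRecord] = []
    for rec in vf:
        alts = rec.alts or ()
        for k, alt in enumerate(alts):
            calls: dict[str, GenotypeCall] = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    if gt is not None and gt != (None,) and gt != (None, None):
                        warnings.warn(
                            f"{rec.chrom}:{rec.pos}: sample {s}: non-diploid "
                            f"or half call {gt} treated as missing"
                        )
                    calls[s] = GenotypeCall.MISSING
                    continue
                mapped = []
                ok = True
                for a in gt:
                    if a == 0:
                        mapped.append(0)
                    elif a == k + 1:
                        mapped.append(1)
                    else:  # references another alternate allele
                        ok = False
                        break
                calls[s] = (
                    GenotypeCall(sum(mapped)) if ok else GenotypeCall.MISSING
                )
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos_bp=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    genotypes=calls,
                    id=rec.id,
                )
            )
    vf.close()
    return out


def write_vcf(
    records: Sequence[VariantRecord],
    path,
    samples: Optional[Sequence[str]] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic records as an uncompressed VCF 4.2 text file."""
    if samples is None:
        seen: list[str] = []
        for r in records:
            for s in r.genotypes:
                if s not in seen:
                    seen.append(s)
        samples = seen
    header = pysam.VariantHeader()
    header.add_meta("source", f"autozyg v{__version__}")
    contigs: dict[str, int] = dict(contig_lengths or {})
    for r in records:
        need = r.pos_bp + max(len(r.ref_allele), 1)
        if contigs.get(r.chrom, 0) < need:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), need)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for s in samples:
        header.add_sample(s)
    gt_tuple = {
        GenotypeCall.HOM_REF: (0, 0),
        GenotypeCall.HET: (0, 1),
        GenotypeCall.HOM_ALT: (1, 1),
        GenotypeCall.MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos_bp, r.alt_allele)):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos_bp - 1,
                stop=r.pos_bp - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, r.alt_allele),
                id=r.id,
            )
            for s in samples:
                rec.samples[s]["GT"] = gt_tuple[
                    r.genotypes.get(s, GenotypeCall.MISSING)
                ]
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[GenomeInterval], path) -> None:
    """Write BED3: 0-based half-open, i.e. (start_bp - 1, end_bp)."""
    with open(path, "w") as fh:
        fh.write(_provenance("bed3 0-based half-open"))
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\n")


def read_bed(path) -> list[GenomeInterval]:
    """Read BED3 back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            out.append(GenomeInterval(chrom, start + 1, end))
    return out


# ---------------------------------------------------------------------------
# Transcript exon table + CDS FASTA


def write_exon_table(model, path) -> None:
    """TSV: transcript, chrom, strand, exon_start, exon_end, cds_start, cds_end."""
    with open(path, "w") as fh:
        fh.write(_provenance("exon table, 1-based inclusive coordinates"))
        fh.write(
            "transcript\tchrom\tstrand\texon_start\texon_end\tcds_start\tcds_end\n"
        )
        for ex in model.exons:
            fh.write(
                f"{model.transcript_id}\t{model.chrom}\t{model.strand}\t"
                f"{ex.start_bp}\t{ex.end_bp}\t{model.cds_start}\t{model.cds_end}\n"
            )


def read_exon_table(path, cds_fasta) -> list:
    """Read transcript models from an exon TSV plus a CDS FASTA."""
    from .consequence import TranscriptModel

    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("transcript\t"):
                continue
            tx, chrom, strand, es, ee, cs, ce = line.split("\t")
            entry = rows.setdefault(
                tx,
                {"chrom": chrom, "strand": strand, "cds_start": int(cs),
                 "cds_end": int(ce), "exons": []},
            )
            entry["exons"].append(GenomeInterval(chrom, int(es), int(ee)))
    models = []
    for tx, entry in rows.items():
        if tx not in cds_seqs:
            raise FormatError(f"transcript {tx}: no CDS sequence in FASTA")
        models.append(
            TranscriptModel(
                transcript_id=tx,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=sorted(entry["exons"], key=lambda iv: iv.start_bp),
                cds_start=entry["cds_start"],
                cds_end=entry["cds_end"],
                cds_sequence=cds_seqs[tx],
            )
        )
    return models


def write_cds_fasta(model, path) -> None:
    rec = SeqRecord(Seq(model.cds_sequence), id=model.transcript_id, description="CDS")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# Allele-count TSV (gDNA/cDNA)


def write_counts_tsv(counts: Iterable, path) -> None:
    """TSV: source, ref_count, alt_count."""
    with open(path, "w") as fh:
        fh.write(_provenance("allele counts"))
        fh.write("source\tref_count\talt_count\n")
        for c in counts:
            fh.write(f"{c.source}\t{c.ref_count}\t{c.alt_count}\n")


def read_counts_tsv(path) -> list:
    from .nmd import AlleleCounts

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            source, ref, alt = line.split("\t")
            out.append(AlleleCounts(source=source, ref_count=int(ref), alt_count=int(alt)))
    return out
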