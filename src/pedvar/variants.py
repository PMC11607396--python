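"""Variant records, canonical keys, and VCF input/output via pysam.

All coordinates are 1-based inclusive (VCF convention).  Multi-allelic sites
are decomposed at load into one biallelic record per alternate allele, so
every downstream predicate (shared-heterozygosity, segregation, phasing) is
well defined.  Phase separators in input genotypes are ignored: phasing is
recomputed by this package, never trusted from the caller's VCF.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam


class Genotype(enum.IntEnum):
    """Unphased diploid genotype with respect to one alternate allele."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


VariantKey = str  # canonical "chrom:pos:ref:alt"


def normalize_chrom(chrom: str, style: str = "plain") -> str:
    """Normalize chromosome-name dialects ("chr12" vs "12").

    ``style='plain'`` (default) strips a leading ``chr``; ``style='chr'``
    prepends it; ``style='as-is'`` leaves names untouched.  A single
    convention makes VCF/BED/annotation joins robust.
    """
    if style == "as-is":
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if style == "plain":
        return bare
    if style == "chr":
        return f"chr{bare}"
    raise ValueError(f"unknown chromosome-name style {style!r}")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with per-sample unphased genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return variant_key(self)


def variant_key(v: VariantRecord) -> VariantKey:
    """Canonical string key ``chrom:pos:ref:alt`` (bijective with the fields)."""
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def parse_variant_key(key: VariantKey) -> tuple[str, int, str, str]:
    """Inverse of :func:`variant_key`; raises ``ValueError`` on malformed keys."""
    parts = key.split(":")
    if len(parts) != 4:
        raise ValueError(f"malformed variant key {key!r} (want chrom:pos:ref:alt)")
    chrom, pos_s, ref, alt = parts
    if not chrom or not ref or not alt:
        raise ValueError(f"malformed variant key {key!r}")
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise ValueError(f"malformed position in key {key!r}") from exc
    if pos < 1:
        raise ValueError(f"position must be >= 1 in key {key!r}")
    return chrom, pos, ref, alt


def _decompose_gt(
    alleles: tuple[Optional[int], ...], alt_index: int
) -> Genotype:
    """Map one sample's GT allele tuple onto biallelic state for alt ``alt_index``.

    Any missing allele makes the whole call MISSING; otherwise the state is
    the count of the focal alternate allele.
    """
    if len(alleles) == 0 or any(a is None for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == 1 and len(alleles) > 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def read_vcf(
    path: Union[str, Path], chrom_style: str = "plain"
) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF (v4.x, GT required) into biallelic :class:`VariantRecord` s.

    Sample order is preserved from the header.  Multi-allelic records are
    decomposed into one record per alternate allele.  Raises ``ValueError``
    naming the record if GT is absent or unparseable.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            if samples and "GT" not in rec.format:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} has no GT field"
                )
            chrom = normalize_chrom(rec.chrom, chrom_style)
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt in (".", "*", "<NON_REF>"):
                    continue
                genotypes = {}
                for s in samples:
                    alleles = rec.samples[s].get("GT", (None,))
                    if alleles is None:
                        alleles = (None,)
                    genotypes[s] = _decompose_gt(tuple(alleles), alt_index)
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                    )
                )
    return samples, records


_GT_TUPLE = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_vcf(
    path: Union[str, Path],
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    source: str = "pedvar",
) -> None:
    """Write biallelic records to an uncompressed VCF v4.2 with GT only."""
    records = list(records)
    header = pysam.VariantHeader()
    header.add_meta("source", source)
    header.formats.add("GT", 1, "String", "Genotype")
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    for chrom in contigs:
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)

    ordered = sorted(records, key=lambda r: (contigs.index(r.chrom), r.pos, r.ref, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in ordered:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for s in samples:
                gt = rec.genotypes.get(s, Genotype.MISSING)
                vrec.samples[s]["GT"] = _GT_TUPLE[Genotype(gt)]
                vrec.samples[s].phased = False
            out.write(vrec)
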