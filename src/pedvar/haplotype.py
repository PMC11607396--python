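"""Pedigree- and read-backed phasing of SNP markers, and haplotype-sharing
locus exclusion.

Three phasing rules are implemented:

* **parent-shared** — an alternate allele carried by a parent and by every
  listed child is attributed to that parent's haplotype in the children;
* **sib-only** — an alternate allele carried by every listed sib but absent
  from one genotyped parent is attributed to the *other* parent's haplotype;
* **read links** — sequencing reads spanning two heterozygous markers fix
  their relative phase; links are combined by transitive closure into phase
  sets (union-find with a parity bit).

Every origin label carries a confidence class.  ``certain`` labels are forced
by Mendelian logic: the parent is homozygous, the child is homozygous, or the
other parent's genotype excludes alternative descent.  ``assumed`` labels are
the literal shared-allele heuristic, which can be wrong whenever the allele
could also descend from the other (untyped or carrier) parent.  Heuristic
labels are reported, but only ``certain`` labels orient read-backed phase
sets and enter the final haplotype strings — a single wrong heuristic label
must not poison a whole phase set, and a locus-exclusion verdict should rest
only on confidently phased evidence.

The sharing test asks whether one haplotype can be chosen per individual so
that the choices agree wherever all of them are known; markers that are
unphased (or phased only by heuristic) act as wildcards.  This is
identity-by-state consistency used as identity-by-descent evidence, not a
probabilistic IBD computation.
"""

from __future__ import annotations

import enum
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .intervals import GenomicInterval
from .pedigree import Pedigree
from .variants import Genotype, VariantKey, VariantRecord, parse_variant_key

logger = logging.getLogger(__name__)

CERTAIN = "certain"
ASSUMED = "assumed"
RELATIVE = "relative"  # phase known within a set; paternal/maternal arbitrary

DEFAULT_MIN_INFORMATIVE = 3


class Origin(enum.Enum):
    """Origin of the alternate allele at one heterozygous marker."""

    PATERNAL = "paternal"
    MATERNAL = "maternal"
    UNPHASED = "unphased"
    CONFLICT = "conflict"


@dataclass
class MarkerGenotypes:
    """Genotypes of SNP markers across one genomic interval.

    Markers are strictly position-sorted biallelic SNPs; ``genotypes`` maps
    each individual to a per-marker genotype list.
    """

    interval: GenomicInterval
    keys: list[VariantKey]
    genotypes: dict[str, list[Genotype]]

    def __post_init__(self) -> None:
        parsed = [parse_variant_key(k) for k in self.keys]
        self.positions = [p[1] for p in parsed]
        self.refs = [p[2] for p in parsed]
        self.alts = [p[3] for p in parsed]
        for pos, ref, alt in zip(self.positions, self.refs, self.alts):
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError("markers must be biallelic SNPs")
            if not (self.interval.start <= pos <= self.interval.end):
                raise ValueError(f"marker position {pos} outside {self.interval}")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("markers must be strictly sorted by position")
        for iid, gts in self.genotypes.items():
            if len(gts) != len(self.keys):
                raise ValueError(f"genotype vector length mismatch for {iid!r}")

    @property
    def n_markers(self) -> int:
        return len(self.keys)

    def genotype(self, individual_id: str, marker: int) -> Genotype:
        return self.genotypes[individual_id][marker]

    def het_markers(self, individual_id: str) -> list[int]:
        return [
            m
            for m, gt in enumerate(self.genotypes[individual_id])
            if gt is Genotype.HET
        ]

    @classmethod
    def from_variants(
        cls,
        variants: Iterable[VariantRecord],
        interval: GenomicInterval,
        sample_ids: Optional[Sequence[str]] = None,
    ) -> "MarkerGenotypes":
        """Restrict variant records to SNPs inside ``interval``."""
        inside = sorted(
            (
                v
                for v in variants
                if len(v.ref) == 1
                and len(v.alt) == 1
                and interval.contains(v.chrom, v.pos)
            ),
            key=lambda v: v.pos,
        )
        if sample_ids is None:
            ids: list[str] = []
            for v in inside:
                for s in v.genotypes:
                    if s not in ids:
                        ids.append(s)
            sample_ids = ids
        genotypes = {
            s: [v.genotypes.get(s, Genotype.MISSING) for v in inside]
            for s in sample_ids
        }
        return cls(interval=interval, keys=[v.key for v in inside], genotypes=genotypes)


@dataclass(frozen=True)
class PhaseLink:
    """Two marker alleles observed on one sequencing read of one individual."""

    individual_id: str
    marker_a: int
    marker_b: int
    allele_a: int  # 0 = ref, 1 = alt
    allele_b: int

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ValueError("a phase link must join two distinct markers")
        for a in (self.allele_a, self.allele_b):
            if a not in (0, 1):
                raise ValueError("link alleles must be 0 (ref) or 1 (alt)")

    @property
    def parity(self) -> int:
        """0 if the two alternate alleles are cis, 1 if trans."""
        return self.allele_a ^ self.allele_b


@dataclass(frozen=True)
class OriginAssignment:
    """One rule-derived origin label for one allele of one individual/marker."""

    individual_id: str
    marker: int
    allele: int  # the labelled allele (1 = alt)
    origin: Origin  # PATERNAL or MATERNAL
    confidence: str  # CERTAIN or ASSUMED
    rule: str
    parent_hom: bool = False  # parent homozygous: uninformative for the
    # parent's own haplotype distinction (still certain for the child)


class _ParityUnionFind:
    """Union-find where each node stores its phase parity to the root."""

    def __init__(self, nodes: Iterable[int]) -> None:
        self.parent = {n: n for n in nodes}
        self.parity = {n: 0 for n in self.parent}

    def find(self, n: int) -> tuple[int, int]:
        """Return (root, parity of n relative to root), compressing the path."""
        start = n
        path = []
        while self.parent[n] != n:
            path.append(n)
            n = self.parent[n]
        root = n
        acc = 0
        for node in reversed(path):  # nearest-to-root first
            acc ^= self.parity[node]
            self.parent[node] = root
            self.parity[node] = acc
        return root, (self.parity[start] if path else 0)

    def union(self, a: int, b: int, rel: int) -> bool:
        """Merge under the constraint parity(a) ^ parity(b) == rel.

        Returns False on contradiction (already joined with the other
        parity), True otherwise.
        """
        root_a, par_a = self.find(a)
        root_b, par_b = self.find(b)
        if root_a == root_b:
            return (par_a ^ par_b) == rel
        self.parent[root_b] = root_a
        self.parity[root_b] = par_a ^ rel ^ par_b
        return True


@dataclass
class PhaseSetPartition:
    """Phase sets of one individual: marker -> (root, parity), plus conflicts."""

    component: dict[int, tuple[int, int]]  # marker -> (root, parity to root)
    conflicted: set[int]
    events: list[str] = field(default_factory=list)

    def sets(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for m, (root, _) in self.component.items():
            groups.setdefault(root, []).append(m)
        return [sorted(g) for g in sorted(groups.values(), key=min)]


def phase_rule_read_links(
    markers: MarkerGenotypes, links: Iterable[PhaseLink]
) -> dict[str, PhaseSetPartition]:
    """Partition each individual's heterozygous markers into phase sets.

    Links referencing a marker that is not heterozygous in that individual
    are ignored with a warning.  A link contradicting an established pairing
    marks both endpoint markers as conflicted and logs the event.
    """
    partitions: dict[str, PhaseSetPartition] = {}
    ufs: dict[str, _ParityUnionFind] = {}
    for iid in markers.genotypes:
        het = markers.het_markers(iid)
        ufs[iid] = _ParityUnionFind(het)
        partitions[iid] = PhaseSetPartition(component={}, conflicted=set())

    for link in links:
        iid = link.individual_id
        if iid not in ufs:
            logger.warning("phase link for unknown individual %r ignored", iid)
            continue
        part = partitions[iid]
        uf = ufs[iid]
        if link.marker_a not in uf.parent or link.marker_b not in uf.parent:
            msg = (
                f"link {link.marker_a}-{link.marker_b} for {iid} names a "
                f"non-heterozygous marker; ignored"
            )
            logger.warning(msg)
            part.events.append(msg)
            continue
        if not uf.union(link.marker_a, link.marker_b, link.parity):
            part.conflicted.update((link.marker_a, link.marker_b))
            msg = (
                f"contradictory link {link.marker_a}-{link.marker_b} for {iid}; "
                f"both markers marked conflict"
            )
            logger.warning(msg)
            part.events.append(msg)

    for iid, uf in ufs.items():
        comp = {}
        for m in uf.parent:
            root, parity = uf.find(m)
            comp[m] = (root, parity)
        partitions[iid].component = comp
    return partitions


def _other_parent_id(ped: Pedigree, child_id: str, parent_id: str) -> Optional[str]:
    child = ped.get(child_id)
    if child.father_id == parent_id:
        return child.mother_id
    if child.mother_id == parent_id:
        return child.father_id
    raise ValueError(f"{parent_id!r} is not a parent of {child_id!r}")


def _side(ped: Pedigree, child_id: str, parent_id: str) -> Origin:
    child = ped.get(child_id)
    if child.father_id == parent_id:
        return Origin.PATERNAL
    if child.mother_id == parent_id:
        return Origin.MATERNAL
    raise ValueError(f"{parent_id!r} is not a parent of {child_id!r}")


def phase_rule_parent_shared(
    ped: Pedigree,
    markers: MarkerGenotypes,
    parent_id: str,
    child_ids: Sequence[str],
    mode: str = "literal",
) -> list[OriginAssignment]:
    """Shared-allele rule: parent and every child carry the alternate allele.

    The allele in each child is labelled with that parent's side.  The label
    is ``certain`` when descent is forced (parent homozygous-alt, child
    homozygous-alt, or the other parent genotyped homozygous-ref), otherwise
    ``assumed`` — the literal heuristic.  ``mode='strict'`` withholds the
    assumed labels.
    """
    if mode not in ("literal", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    if parent_id not in markers.genotypes:
        raise ValueError(f"parent {parent_id!r} has no marker genotypes")
    for cid in child_ids:
        _side(ped, cid, parent_id)  # raises if relationship absent

    out: list[OriginAssignment] = []
    for m in range(markers.n_markers):
        pg = markers.genotype(parent_id, m)
        if not pg.carries_alt():
            continue
        if not all(
            markers.genotype(cid, m).carries_alt()
            for cid in child_ids
            if cid in markers.genotypes
        ):
            continue
        for cid in child_ids:
            if cid not in markers.genotypes:
                continue
            cg = markers.genotype(cid, m)
            if not cg.carries_alt():
                continue
            other = _other_parent_id(ped, cid, parent_id)
            other_gt = (
                markers.genotype(other, m)
                if other is not None and other in markers.genotypes
                else None
            )
            certain = (
                pg is Genotype.HOM_ALT
                or cg is Genotype.HOM_ALT
                or other_gt is Genotype.HOM_REF
            )
            if not certain and mode == "strict":
                continue
            out.append(
                OriginAssignment(
                    individual_id=cid,
                    marker=m,
                    allele=1,
                    origin=_side(ped, cid, parent_id),
                    confidence=CERTAIN if certain else ASSUMED,
                    rule="parent_shared",
                    parent_hom=pg is Genotype.HOM_ALT,
                )
            )
    return out


def phase_rule_sib_only(
    ped: Pedigree,
    markers: MarkerGenotypes,
    excluded_parent_id: str,
    sib_ids: Sequence[str],
) -> list[OriginAssignment]:
    """Exclusion rule: every sib carries the alternate allele, the genotyped
    excluded parent does not — the allele must come from the other parent.

    These labels are ``certain`` (barring de novo mutation).  A sib that is
    homozygous-alt while the excluded parent carries no alternate allele is a
    Mendelian inconsistency and is skipped with a warning.
    """
    if excluded_parent_id not in markers.genotypes:
        raise ValueError(f"excluded parent {excluded_parent_id!r} has no marker genotypes")
    sides = {cid: _side(ped, cid, excluded_parent_id) for cid in sib_ids}
    if len({(ped.get(c).father_id, ped.get(c).mother_id) for c in sib_ids}) > 1:
        raise ValueError("sibs must share both parents")

    out: list[OriginAssignment] = []
    for m in range(markers.n_markers):
        eg = markers.genotype(excluded_parent_id, m)
        if eg is Genotype.MISSING or eg.carries_alt():
            continue
        typed_sibs = [c for c in sib_ids if c in markers.genotypes]
        if not typed_sibs or not all(
            markers.genotype(c, m).carries_alt() for c in typed_sibs
        ):
            continue
        for cid in typed_sibs:
            cg = markers.genotype(cid, m)
            if cg is Genotype.HOM_ALT:
                logger.warning(
                    "Mendelian inconsistency at marker %d: %s hom-alt but "
                    "excluded parent %s carries no alt; skipped",
                    m,
                    cid,
                    excluded_parent_id,
                )
                continue
            other_side = (
                Origin.MATERNAL if sides[cid] is Origin.PATERNAL else Origin.PATERNAL
            )
            out.append(
                OriginAssignment(
                    individual_id=cid,
                    marker=m,
                    allele=1,
                    origin=other_side,
                    confidence=CERTAIN,
                    rule="sib_only",
                )
            )
    return out


@dataclass
class IndividualPhasing:
    """Assembled phase of one individual.

    ``hap1``/``hap2`` are allele strings over ``{'0','1','?'}``; when the
    parental origin is known hap1 is paternal.  ``origin[m]`` labels the
    alternate allele at heterozygous markers; ``confidence[m]`` is
    ``certain``/``assumed``/``relative`` or ``None``.
    """

    hap1: str
    hap2: str
    origin: list[Origin]
    confidence: list[Optional[str]]

    def known_markers(self) -> list[int]:
        return [m for m, c in enumerate(self.hap1) if c != "?" and self.hap2[m] != "?"]


@dataclass
class PhasedHaplotypes:
    markers: MarkerGenotypes
    phasing: dict[str, IndividualPhasing]
    phase_sets: dict[str, list[list[int]]]
    events: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for iid, ph in self.phasing.items():
            for m, key in enumerate(self.markers.keys):
                rows.append(
                    {
                        "individual": iid,
                        "marker": key,
                        "genotype": self.markers.genotype(iid, m).name.lower(),
                        "hap1": ph.hap1[m],
                        "hap2": ph.hap2[m],
                        "alt_origin": ph.origin[m].value,
                        "confidence": ph.confidence[m] or "",
                    }
                )
        return pd.DataFrame(rows)


def _merge_direct_labels(
    assignments: Sequence[OriginAssignment],
    gts: Sequence[Genotype],
    events: list[str],
    iid: str,
) -> tuple[dict[int, tuple[int, str]], set[int]]:
    """Merge per-marker rule labels into (paternal allele, confidence).

    Returns (merged, conflicted).  Certain labels outrank assumed ones;
    contradictions within a confidence class mark the marker as conflict.
    """
    by_marker: dict[int, list[OriginAssignment]] = {}
    for a in assignments:
        if gts[a.marker] is Genotype.HET:
            by_marker.setdefault(a.marker, []).append(a)

    merged: dict[int, tuple[int, str]] = {}
    conflicted: set[int] = set()
    for m, labels in by_marker.items():
        certain_pa = set()
        assumed_pa = set()
        for a in labels:
            pat_allele = a.allele if a.origin is Origin.PATERNAL else 1 - a.allele
            (certain_pa if a.confidence == CERTAIN else assumed_pa).add(pat_allele)
        if len(certain_pa) > 1:
            conflicted.add(m)
            events.append(f"{iid}: contradictory certain labels at marker {m}")
        elif certain_pa:
            pa = next(iter(certain_pa))
            if assumed_pa - certain_pa:
                events.append(
                    f"{iid}: heuristic label at marker {m} contradicted by "
                    f"certain evidence; certain label kept"
                )
            merged[m] = (pa, CERTAIN)
        elif len(assumed_pa) > 1:
            # Opposing heuristic labels (e.g. both parents carry the allele):
            # the heuristic carries no information here; the marker is left
            # unlabelled so read links may still phase it.
            events.append(
                f"{iid}: ambiguous heuristic labels at marker {m}; none kept"
            )
        elif assumed_pa:
            merged[m] = (next(iter(assumed_pa)), ASSUMED)
    return merged, conflicted


def assemble_haplotypes(
    markers: MarkerGenotypes,
    assignments: Iterable[OriginAssignment],
    phase_sets: Optional[Mapping[str, PhaseSetPartition]] = None,
    ped: Optional[Pedigree] = None,
) -> PhasedHaplotypes:
    """Integrate pedigree-rule labels and read-link phase sets.

    Certain labels are seeded first and propagate through their phase set;
    a set whose certain anchors disagree becomes conflict throughout.
    Heuristic (assumed) labels are reported per marker but neither orient
    phase sets nor enter the haplotype strings.  For an individual with no
    certain label at all, the largest read-backed phase set is emitted with
    an arbitrary (but deterministic) orientation, confidence ``relative``.
    """
    assignments = list(assignments)
    events: list[str] = []
    phasing: dict[str, IndividualPhasing] = {}
    set_summary: dict[str, list[list[int]]] = {}

    for iid, gts in markers.genotypes.items():
        my_assignments = [a for a in assignments if a.individual_id == iid]
        merged, conflicted = _merge_direct_labels(my_assignments, gts, events, iid)

        part = phase_sets.get(iid) if phase_sets else None
        final: dict[int, tuple[int, str]] = {}
        if part is not None:
            conflicted |= part.conflicted
            events.extend(part.events)
            groups: dict[int, list[int]] = {}
            for m, (root, _) in part.component.items():
                groups.setdefault(root, []).append(m)
            set_summary[iid] = [sorted(g) for g in sorted(groups.values(), key=min)]

            for root, members in groups.items():
                anchors = {
                    merged[m][0] ^ part.component[m][1]
                    for m in members
                    if m in merged and merged[m][1] == CERTAIN and m not in conflicted
                }
                if len(anchors) > 1:
                    conflicted.update(members)
                    events.append(
                        f"{iid}: phase set {sorted(members)} received contradictory "
                        f"certain labels; whole set marked conflict"
                    )
                    continue
                if anchors:
                    z = next(iter(anchors))
                    for m in members:
                        if m in conflicted:
                            continue
                        pa = z ^ part.component[m][1]
                        if m in merged and merged[m][1] == ASSUMED and merged[m][0] != pa:
                            events.append(
                                f"{iid}: heuristic label at marker {m} contradicted "
                                f"by phase-set propagation; overridden"
                            )
                        final[m] = (pa, CERTAIN)
        else:
            set_summary[iid] = [[m] for m in markers.het_markers(iid)]

        for m, lab in merged.items():
            if m not in final and m not in conflicted:
                final[m] = lab

        has_certain = any(conf == CERTAIN for _, conf in final.values())
        if not has_certain and part is not None:
            candidates = [
                members
                for members in set_summary[iid]
                if len(members) >= 2 and not any(m in conflicted for m in members)
            ]
            if candidates:
                biggest = max(candidates, key=lambda g: (len(g), -g[0]))
                anchor = biggest[0]
                z = 1 ^ part.component[anchor][1]  # alt on hap1 at the anchor
                for m in biggest:
                    final[m] = (z ^ part.component[m][1], RELATIVE)

        hap1 = []
        hap2 = []
        origin: list[Origin] = []
        confidence: list[Optional[str]] = []
        for m, gt in enumerate(gts):
            if gt is Genotype.MISSING:
                hap1.append("?"); hap2.append("?")
                origin.append(Origin.UNPHASED); confidence.append(None)
            elif gt is Genotype.HOM_REF:
                hap1.append("0"); hap2.append("0")
                origin.append(Origin.UNPHASED); confidence.append(None)
            elif gt is Genotype.HOM_ALT:
                hap1.append("1"); hap2.append("1")
                origin.append(Origin.UNPHASED); confidence.append(None)
            elif m in conflicted:
                hap1.append("?"); hap2.append("?")
                origin.append(Origin.CONFLICT); confidence.append(None)
            elif m in final:
                pa, conf = final[m]
                if conf in (CERTAIN, RELATIVE):
                    hap1.append(str(pa)); hap2.append(str(1 - pa))
                else:  # assumed: reported, not asserted in the strings
                    hap1.append("?"); hap2.append("?")
                origin.append(
                    Origin.UNPHASED
                    if conf == RELATIVE
                    else (Origin.PATERNAL if pa == 1 else Origin.MATERNAL)
                )
                confidence.append(conf)
            else:
                hap1.append("?"); hap2.append("?")
                origin.append(Origin.UNPHASED); confidence.append(None)

        phasing[iid] = IndividualPhasing(
            hap1="".join(hap1), hap2="".join(hap2), origin=origin, confidence=confidence
        )

    return PhasedHaplotypes(
        markers=markers, phasing=phasing, phase_sets=set_summary, events=events
    )


@dataclass
class SharingReport:
    """Verdict of the identical-haplotype-sharing test over an interval."""

    individuals: tuple[str, ...]
    n_markers: int
    informative_count: int
    consistent_count: int
    shared: bool
    valid: bool
    min_informative: int
    witness: Optional[str]
    conflicts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "individuals": list(self.individuals),
            "n_markers": self.n_markers,
            "informative_count": self.informative_count,
            "consistent_count": self.consistent_count,
            "shared": self.shared,
            "valid": self.valid,
            "min_informative": self.min_informative,
            "witness": self.witness,
            "conflicts": self.conflicts,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def assess_sharing(
    haps: PhasedHaplotypes,
    individual_ids: Sequence[str],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> SharingReport:
    """Search for one haplotype per individual agreeing at all jointly-known
    markers.

    ``shared`` is true iff such a choice exists *and* it is supported by at
    least ``min_informative`` markers known in every chosen haplotype
    (``valid`` flags that support requirement on its own).  Unknown alleles —
    unphased, heuristically phased, or conflicted markers — act as wildcards,
    so exclusion rests only on confidently phased evidence.
    """
    ids = tuple(individual_ids)
    if len(ids) < 2:
        raise ValueError("sharing assessment needs at least two individuals")
    if len(ids) > 16:
        raise ValueError("sharing assessment limited to 16 individuals")
    for iid in ids:
        if iid not in haps.phasing:
            raise ValueError(f"individual {iid!r} absent from phased haplotypes")

    n = haps.markers.n_markers
    pairs = [(haps.phasing[iid].hap1, haps.phasing[iid].hap2) for iid in ids]

    best = None  # (conflicts, -informative, assignment, conflict_markers)
    for choice in itertools.product((0, 1), repeat=len(ids)):
        chosen = [pairs[i][c] for i, c in enumerate(choice)]
        informative = 0
        conflict_markers: list[int] = []
        for m in range(n):
            column = [h[m] for h in chosen]
            if "?" in column:
                continue
            informative += 1
            if len(set(column)) > 1:
                conflict_markers.append(m)
        cand = (len(conflict_markers), -informative, choice, chosen, conflict_markers)
        if best is None or cand[:2] < best[:2]:
            best = cand

    n_conflicts, neg_inf, choice, chosen, conflict_markers = best
    informative = -neg_inf
    valid = informative >= min_informative
    shared = n_conflicts == 0 and valid

    witness = None
    if n_conflicts == 0:
        # The witness is asserted only at informative markers (known in every
        # chosen haplotype, hence agreed); elsewhere it is left unknown.
        wit = []
        for m in range(n):
            column = [h[m] for h in chosen]
            wit.append(column[0] if "?" not in column else "?")
        witness = "".join(wit)

    conflicts = [
        {
            "marker": haps.markers.keys[m],
            "alleles": {iid: chosen[i][m] for i, iid in enumerate(ids)},
        }
        for m in conflict_markers
    ]
    return SharingReport(
        individuals=ids,
        n_markers=n,
        informative_count=informative,
        consistent_count=informative - n_conflicts,
        shared=shared,
        valid=valid,
        min_informative=min_informative,
        witness=witness,
        conflicts=conflicts,
    )


# ---------------------------------------------------------------------------
# Phase-link TSV dialect: individual, key_a, allele_a, key_b, allele_b
# (alleles as base strings, matching the marker's ref/alt).

def write_links(
    links: Iterable[PhaseLink], markers: MarkerGenotypes, path: Union[str, Path]
) -> None:
    rows = []
    for ln in links:
        rows.append(
            {
                "individual": ln.individual_id,
                "key_a": markers.keys[ln.marker_a],
                "allele_a": (markers.alts if ln.allele_a else markers.refs)[ln.marker_a],
                "key_b": markers.keys[ln.marker_b],
                "allele_b": (markers.alts if ln.allele_b else markers.refs)[ln.marker_b],
            }
        )
    pd.DataFrame(rows, columns=["individual", "key_a", "allele_a", "key_b", "allele_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_links(path: Union[str, Path], markers: MarkerGenotypes) -> list[PhaseLink]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    index = {k: m for m, k in enumerate(markers.keys)}
    links: list[PhaseLink] = []
    for row in df.itertuples(index=False):
        for key in (row.key_a, row.key_b):
            if key not in index:
                raise ValueError(f"{path}: link names unknown marker {key!r}")
        a, b = index[row.key_a], index[row.key_b]

        def allele_bit(marker: int, base: str, key: str) -> int:
            if base == markers.refs[marker]:
                return 0
            if base == markers.alts[marker]:
                return 1
            raise ValueError(f"{path}: allele {base!r} matches neither allele of {key}")

        links.append(
            PhaseLink(
                individual_id=row.individual,
                marker_a=a,
                marker_b=b,
                allele_a=allele_bit(a, row.allele_a, row.key_a),
                allele_b=allele_bit(b, row.allele_b, row.key_b),
            )
        )
    return links
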