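"""Pedigree data model and 6-column PED input/output.

A pedigree is a directed family graph: each individual optionally points to a
father and a mother, carries a sex, an affection status and a flag saying
whether a DNA sample was genotyped.  Affection status ``UNKNOWN`` is a
first-class state (late-onset disease leaves the youngest generation
undiagnosable), and such individuals impose no constraint anywhere downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


# PED numeric code tables (sex: 1/2/0, phenotype: 2/1/0 or -9)
_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_CODE_FROM_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_STATUS_FROM_CODE = {
    "2": Status.AFFECTED,
    "1": Status.UNAFFECTED,
    "0": Status.UNKNOWN,
    "-9": Status.UNKNOWN,
}
_CODE_FROM_STATUS = {
    Status.AFFECTED: "2",
    Status.UNAFFECTED: "1",
    Status.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders.  ``genotyped``
    marks members with a usable DNA sample (Sanger or WGS).
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNKNOWN
    genotyped: bool = False

    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Violation:
    """A single pedigree-invariant violation (data, not an exception)."""

    code: str
    individual_id: str
    message: str


@dataclass
class Pedigree:
    """Ordered collection of :class:`Individual` with graph accessors."""

    individuals: list[Individual] = field(default_factory=list)
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.individuals}

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder()]

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if parent_id in (ind.father_id, ind.mother_id)
        ]

    def parents_of(self, individual_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        """Return (father, mother); ``None`` where absent or unresolvable."""
        ind = self.get(individual_id)
        father = self._by_id.get(ind.father_id) if ind.father_id else None
        mother = self._by_id.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def genotyped_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.genotyped]

    def affected_ids(self, genotyped_only: bool = False) -> list[str]:
        return [
            ind.id
            for ind in self.individuals
            if ind.status is Status.AFFECTED and (ind.genotyped or not genotyped_only)
        ]

    def unaffected_ids(self, genotyped_only: bool = False) -> list[str]:
        return [
            ind.id
            for ind in self.individuals
            if ind.status is Status.UNAFFECTED and (ind.genotyped or not genotyped_only)
        ]

    def with_individual(self, individual: Individual) -> "Pedigree":
        """Return a copy with ``individual`` appended (or replaced by id)."""
        members = [i for i in self.individuals if i.id != individual.id]
        members.append(individual)
        return Pedigree(members, family_id=self.family_id)


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check every pedigree invariant; an empty report means valid.

    Checks: non-empty unique ids, resolvable parent references, acyclicity
    (nobody is their own ancestor) and the existence of at least one founder.
    Violations are returned as data so callers can report them all at once.
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for ind in ped.individuals:
        if not ind.id:
            violations.append(Violation("empty-id", ind.id, "individual with empty id"))
        if ind.id in seen:
            violations.append(
                Violation("duplicate-id", ind.id, f"id {ind.id!r} appears more than once")
            )
        seen.add(ind.id)

    for ind in ped.individuals:
        for label, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            if pid is not None and pid not in seen:
                violations.append(
                    Violation(
                        "missing-parent",
                        ind.id,
                        f"{label} {pid!r} of {ind.id!r} is not in the pedigree",
                    )
                )

    # Cycle detection over the child -> parent edges (iterative DFS, three-colour).
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {ind.id: WHITE for ind in ped.individuals}

    def parents(iid: str) -> list[str]:
        ind = ped._by_id.get(iid)
        if ind is None:
            return []
        return [p for p in (ind.father_id, ind.mother_id) if p is not None and p in colour]

    for start in list(colour):
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [(start, iter(parents(start)))]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    violations.append(
                        Violation(
                            "self-ancestor",
                            nxt,
                            f"{nxt!r} is its own ancestor (cycle through {node!r})",
                        )
                    )
                elif colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(parents(nxt))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()

    if ped.individuals and not ped.founders():
        violations.append(Violation("no-founder", "", "pedigree has no founder"))
    return violations


def read_ped(path: Union[str, Path]) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Columns: family, id, father, mother, sex (1/2/0), phenotype (2/1/0/-9).
    A ``0`` parent means absent.  Raises ``ValueError`` naming the offending
    line on a wrong column count or an unknown code.
    """
    individuals: list[Individual] = []
    family_id = "FAM1"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex_code, pheno_code = fields
            family_id = fam
            if sex_code not in _SEX_FROM_CODE:
                raise ValueError(f"{path}: line {lineno}: bad sex code {sex_code!r}")
            if pheno_code not in _STATUS_FROM_CODE:
                raise ValueError(
                    f"{path}: line {lineno}: bad phenotype code {pheno_code!r}"
                )
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_FROM_CODE[sex_code],
                    status=_STATUS_FROM_CODE[pheno_code],
                    genotyped=True,
                )
            )
    return Pedigree(individuals, family_id=family_id)


def write_ped(ped: Pedigree, path: Union[str, Path]) -> None:
    """Write a 6-column PED file (genotyped flag is not representable in PED)."""
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                " ".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _CODE_FROM_SEX[ind.sex],
                        _CODE_FROM_STATUS[ind.status],
                    ]
                )
                + "\n"
            )


def mark_genotyped(ped: Pedigree, genotyped_ids: Iterable[str]) -> Pedigree:
    """Return a pedigree whose ``genotyped`` flags match ``genotyped_ids``."""
    wanted = set(genotyped_ids)
    return Pedigree(
        [replace(ind, genotyped=ind.id in wanted) for ind in ped.individuals],
        family_id=ped.family_id,
    )
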