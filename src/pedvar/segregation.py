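"""Autosomal-dominant co-segregation testing against an extended pedigree.

Under a fully penetrant dominant model every affected, genotyped individual
must carry at least one alternate allele and every unaffected, genotyped
individual must carry none.  Individuals with unknown disease status (the
young, undiagnosable generation) or missing genotypes impose no constraint.
No LOD score is computed: this is the deterministic check used to confirm or
refute candidate variants by targeted re-genotyping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from .pedigree import Pedigree, Status
from .variants import Genotype, VariantKey

AFFECTED_NONCARRIER = "affected_noncarrier"
UNAFFECTED_CARRIER = "unaffected_carrier"


@dataclass(frozen=True)
class SegregationVerdict:
    key: VariantKey
    segregates: bool
    violations: tuple[tuple[str, str], ...]  # (individual id, reason)
    informative_count: int
    hom_alt_carriers: tuple[str, ...] = ()  # dominant model generalization, flagged

    def __post_init__(self) -> None:
        if self.segregates != (len(self.violations) == 0):
            raise ValueError("segregates must equal (violations empty)")


def check_dominant_segregation(
    key: VariantKey,
    genotypes: Mapping[str, Genotype],
    pedigree: Pedigree,
    max_violations: int = 0,
) -> SegregationVerdict:
    """Verdict for one variant under full-penetrance dominance.

    ``max_violations`` (default 0) tolerates that many violations before the
    verdict flips; it exists for reuse on imperfect data and is off by
    default.  Homozygous-alternate affecteds count as carriers (>= 1 alt
    allele) and are flagged, since a het-only family makes them unexpected.
    """
    for sid in genotypes:
        if sid not in pedigree:
            raise ValueError(f"genotyped sample {sid!r} is not in the pedigree")

    violations: list[tuple[str, str]] = []
    hom_alt: list[str] = []
    informative = 0
    for ind in pedigree:
        if not ind.genotyped or ind.status is Status.UNKNOWN:
            continue
        informative += 1  # genotyped with known status
        gt = genotypes.get(ind.id, Genotype.MISSING)
        if gt is Genotype.MISSING:
            continue  # no constraint from an unobserved genotype
        if ind.status is Status.AFFECTED:
            if not gt.carries_alt():
                violations.append((ind.id, AFFECTED_NONCARRIER))
            elif gt is Genotype.HOM_ALT:
                hom_alt.append(ind.id)
        elif ind.status is Status.UNAFFECTED:
            if gt.carries_alt():
                violations.append((ind.id, UNAFFECTED_CARRIER))

    # segregates is tied to an empty recorded violation list; violations within
    # the (default 0) tolerance are therefore dropped from the record.
    segregates = len(violations) <= max_violations
    return SegregationVerdict(
        key=key,
        segregates=segregates,
        violations=() if segregates else tuple(violations),
        informative_count=informative,
        hom_alt_carriers=tuple(hom_alt),
    )


def segregation_filter(
    keys: Iterable[VariantKey],
    genotypes: Mapping[VariantKey, Mapping[str, Genotype]],
    pedigree: Pedigree,
    max_violations: int = 0,
) -> frozenset[VariantKey]:
    """Retain exactly the keys whose dominant-segregation verdict is positive."""
    return frozenset(
        key
        for key in keys
        if check_dominant_segregation(
            key, genotypes.get(key, {}), pedigree, max_violations
        ).segregates
    )


def write_verdicts_tsv(
    verdicts: Iterable[SegregationVerdict], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("key\tsegregates\tinformative\tviolations\thom_alt_carriers\n")
        for v in verdicts:
            vio = ";".join(f"{iid}:{reason}" for iid, reason in v.violations)
            fh.write(
                f"{v.key}\t{str(v.segregates).lower()}\t{v.informative_count}"
                f"\t{vio}\t{','.join(v.hom_alt_carriers)}\n"
            )


def write_verdicts_json(
    verdicts: Iterable[SegregationVerdict], path: Union[str, Path]
) -> None:
    payload = [
        {
            "key": v.key,
            "segregates": v.segregates,
            "informative_count": v.informative_count,
            "violations": [
                {"individual": iid, "reason": reason} for iid, reason in v.violations
            ],
            "hom_alt_carriers": list(v.hom_alt_carriers),
        }
        for v in verdicts
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
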