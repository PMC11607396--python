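"""Genome-wide rare-variant filtering cascade with per-stage accounting.

The cascade mirrors a family-based dominant discovery analysis: exclude the
known disease-gene panel first, keep variants heterozygous in every sequenced
affected, then apply population frequency (MAF < threshold, strict), coding
consequence, and deleteriousness (CADD > threshold, strict) filters, and
finally require co-segregation across the extended pedigree.  Every stage is
a pure set predicate and the result object records input/surviving counts so
that each dropped variant is attributable to exactly one stage.

Missing-annotation semantics are explicit configuration:

* absent MAF defaults to ``treat_as_zero`` — a variant absent from the
  population database is novel (frequency 0) and must survive a rarity filter;
* absent CADD defaults to ``retain_flagged`` — scores are undefined for some
  indels, and silently dropping unscored candidates is the error the
  stringent-threshold cautionary tale warns about;
* variants with no annotation row at all are dropped (and counted) by each
  annotation-dependent filter, which keeps the final candidate set invariant
  under reordering of the MAF/consequence/CADD stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .annotations import AnnotationMap
from .pedigree import Pedigree
from .segregation import segregation_filter
from .variants import Genotype, VariantKey, VariantRecord

DEFAULT_MAF_THRESHOLD = 0.001
DEFAULT_CADD_THRESHOLD = 10.0
DEFAULT_EXONIC_CLASSES = frozenset({"exonic"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and policies for one cascade run."""

    affected_sample_ids: tuple[str, ...]
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD
    exonic_classes: frozenset[str] = DEFAULT_EXONIC_CLASSES
    panel_genes: frozenset[str] = frozenset()
    missing_maf_policy: str = "treat_as_zero"  # or "drop"
    missing_cadd_policy: str = "retain_flagged"  # or "drop"

    def __post_init__(self) -> None:
        if not self.affected_sample_ids:
            raise ValueError("affected_sample_ids must be non-empty")
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValueError(f"maf_threshold must be in (0,1], got {self.maf_threshold}")
        if self.cadd_threshold < 0:
            raise ValueError(f"cadd_threshold must be >= 0, got {self.cadd_threshold}")
        if self.missing_maf_policy not in ("treat_as_zero", "drop"):
            raise ValueError(f"unknown missing_maf_policy {self.missing_maf_policy!r}")
        if self.missing_cadd_policy not in ("retain_flagged", "drop"):
            raise ValueError(f"unknown missing_cadd_policy {self.missing_cadd_policy!r}")


@dataclass(frozen=True)
class CascadeStage:
    """Ledger entry for one filtering stage."""

    name: str
    predicate: str
    input_count: int
    surviving_count: int
    surviving_keys: frozenset[VariantKey]
    unannotated_dropped: int = 0

    def __post_init__(self) -> None:
        if self.surviving_count != len(self.surviving_keys):
            raise ValueError("surviving_count must equal len(surviving_keys)")
        if self.surviving_count > self.input_count:
            raise ValueError("surviving_count exceeds input_count")


@dataclass
class FilterCascadeResult:
    """Ordered stage ledger plus the final candidate set."""

    stages: list[CascadeStage] = field(default_factory=list)

    @property
    def final_candidates(self) -> frozenset[VariantKey]:
        return self.stages[-1].surviving_keys if self.stages else frozenset()

    def to_table(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "predicate": s.predicate,
                "input": s.input_count,
                "surviving": s.surviving_count,
                "dropped": s.input_count - s.surviving_count,
                "unannotated_dropped": s.unannotated_dropped,
            }
            for s in self.stages
        ]

    def write_tsv(self, path: Union[str, Path]) -> None:
        rows = self.to_table()
        with open(path, "w") as fh:
            cols = ["stage", "predicate", "input", "surviving", "dropped", "unannotated_dropped"]
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    def write_json(self, path: Union[str, Path]) -> None:
        payload = {
            "stages": self.to_table(),
            "final_candidates": sorted(self.final_candidates),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def shared_heterozygous(
    variants: Iterable[VariantRecord], affected_ids: Sequence[str]
) -> frozenset[VariantKey]:
    """Keys where *every* listed sample is heterozygous.

    Homozygous (ref or alt) or missing calls in any listed sample exclude the
    variant: under a dominant model with unrelated-spouse founders the shared
    causal allele is expected heterozygous in every affected.
    """
    if not affected_ids:
        raise ValueError("affected_ids must be non-empty")
    out: set[VariantKey] = set()
    for rec in variants:
        for sid in affected_ids:
            if sid not in rec.genotypes:
                raise ValueError(f"sample {sid!r} absent from genotypes of {rec.key}")
        if all(rec.genotypes[sid] is Genotype.HET for sid in affected_ids):
            out.add(rec.key)
    return frozenset(out)


def filter_by_maf(
    keys: Iterable[VariantKey],
    annotations: AnnotationMap,
    threshold: float = DEFAULT_MAF_THRESHOLD,
    missing_maf_policy: str = "treat_as_zero",
) -> frozenset[VariantKey]:
    """Retain keys with population MAF strictly below ``threshold``.

    Absent MAF is treated as 0 (novel) by default, so an unseen variant
    survives; ``missing_maf_policy='drop'`` inverts that.  Keys without any
    annotation row are always dropped (counted by the cascade).
    """
    out: set[VariantKey] = set()
    for key in keys:
        ann = annotations.get(key)
        if ann is None:
            continue
        maf = ann.maf
        if maf is None:
            if missing_maf_policy == "treat_as_zero":
                out.add(key)
            continue
        if maf < threshold:
            out.add(key)
    return frozenset(out)


def filter_consequence(
    keys: Iterable[VariantKey],
    annotations: AnnotationMap,
    allowed_classes: Iterable[str] = DEFAULT_EXONIC_CLASSES,
) -> frozenset[VariantKey]:
    """Retain keys whose consequence class is in ``allowed_classes`` (case-folded)."""
    allowed = {c.casefold() for c in allowed_classes}
    if not allowed:
        raise ValueError("allowed_classes must be non-empty")
    return frozenset(
        key
        for key in keys
        if (ann := annotations.get(key)) is not None
        and ann.consequence.casefold() in allowed
    )


def filter_by_cadd(
    keys: Iterable[VariantKey],
    annotations: AnnotationMap,
    threshold: float = DEFAULT_CADD_THRESHOLD,
    missing_cadd_policy: str = "retain_flagged",
) -> frozenset[VariantKey]:
    """Retain keys with CADD strictly above ``threshold``.

    Absent CADD is retained (flagged upstream) by default; configurable to
    drop.  Keys without an annotation row are dropped.
    """
    out: set[VariantKey] = set()
    for key in keys:
        ann = annotations.get(key)
        if ann is None:
            continue
        if ann.cadd is None:
            if missing_cadd_policy == "retain_flagged":
                out.add(key)
            continue
        if ann.cadd > threshold:
            out.add(key)
    return frozenset(out)


def exclude_gene_panel(
    keys: Iterable[VariantKey],
    annotations: AnnotationMap,
    panel_genes: Iterable[str],
) -> frozenset[VariantKey]:
    """Drop keys in known disease-panel genes (case-insensitive).

    Keys with an absent gene symbol — or no annotation row at all — are
    retained: panel membership cannot be established for them.
    """
    panel = {g.casefold() for g in panel_genes}
    out: set[VariantKey] = set()
    for key in keys:
        ann = annotations.get(key)
        gene = ann.gene if ann is not None else None
        if gene is not None and gene.casefold() in panel:
            continue
        out.add(key)
    return frozenset(out)


def run_cascade(
    variants: Iterable[VariantRecord],
    annotations: AnnotationMap,
    pedigree: Pedigree,
    config: FilterConfig,
) -> FilterCascadeResult:
    """Run the full fixed-order cascade and return the stage ledger.

    Order: panel exclusion -> shared heterozygous -> MAF -> consequence ->
    CADD -> segregation.  Counts are monotone non-increasing and each dropped
    variant fails at the first stage whose predicate it violates.
    """
    variants = list(variants)
    by_key = {rec.key: rec for rec in variants}
    result = FilterCascadeResult()

    def n_unannotated(keys: Iterable[VariantKey]) -> int:
        return sum(1 for k in keys if k not in annotations)

    def push(name: str, predicate: str, input_keys: frozenset, surviving: frozenset,
             unannotated: int = 0) -> frozenset:
        result.stages.append(
            CascadeStage(
                name=name,
                predicate=predicate,
                input_count=len(input_keys),
                surviving_count=len(surviving),
                surviving_keys=surviving,
                unannotated_dropped=unannotated,
            )
        )
        return surviving

    current = frozenset(by_key)
    current = push(
        "panel_exclusion",
        f"gene not in panel ({len(config.panel_genes)} genes)",
        current,
        exclude_gene_panel(current, annotations, config.panel_genes),
    )
    shared = shared_heterozygous(
        (by_key[k] for k in current), config.affected_sample_ids
    )
    current = push(
        "shared_heterozygous",
        f"het in all of {list(config.affected_sample_ids)}",
        current,
        shared,
    )
    survivors = filter_by_maf(
        current, annotations, config.maf_threshold, config.missing_maf_policy
    )
    current = push(
        "maf",
        f"MAF < {config.maf_threshold} (absent: {config.missing_maf_policy})",
        current,
        survivors,
        n_unannotated(current),
    )
    survivors = filter_consequence(current, annotations, config.exonic_classes)
    current = push(
        "consequence",
        f"class in {sorted(config.exonic_classes)}",
        current,
        survivors,
        n_unannotated(current),
    )
    survivors = filter_by_cadd(
        current, annotations, config.cadd_threshold, config.missing_cadd_policy
    )
    current = push(
        "cadd",
        f"CADD > {config.cadd_threshold} (absent: {config.missing_cadd_policy})",
        current,
        survivors,
        n_unannotated(current),
    )
    genotypes = {k: by_key[k].genotypes for k in current}
    survivors = segregation_filter(current, genotypes, pedigree)
    push("segregation", "dominant co-segregation in pedigree", current, survivors)
    return result
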