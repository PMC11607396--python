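"""End-to-end orchestration: discovery cascade and locus exclusion.

``run_discovery`` executes panel exclusion -> shared-heterozygous -> MAF ->
consequence -> CADD -> segregation on loaded inputs and emits a
re-executable :class:`RunReport`.  ``run_locus_exclusion`` applies the three
phasing rules across every genotyped nuclear family, assembles haplotypes,
and returns the sharing verdict for the requested individuals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import __version__
from .annotations import AnnotationMap, AnnotationRecord, annotation_map
from .filtering import FilterCascadeResult, FilterConfig, run_cascade
from .haplotype import (
    DEFAULT_MIN_INFORMATIVE,
    MarkerGenotypes,
    OriginAssignment,
    PhaseLink,
    PhasedHaplotypes,
    SharingReport,
    assemble_haplotypes,
    assess_sharing,
    phase_rule_parent_shared,
    phase_rule_read_links,
    phase_rule_sib_only,
)
from .intervals import GenomicInterval
from .pedigree import Pedigree, Status
from .segregation import (
    SegregationVerdict,
    check_dominant_segregation,
    write_verdicts_json,
    write_verdicts_tsv,
)
from .variants import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything needed to re-execute and audit one discovery run."""

    config: dict
    cascade: FilterCascadeResult
    verdicts: list[SegregationVerdict]
    candidates: list[str]
    annotations: dict[str, dict]
    version: str = __version__
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "cascade": self.cascade.to_table(),
            "verdicts": [
                {
                    "key": v.key,
                    "segregates": v.segregates,
                    "informative_count": v.informative_count,
                    "violations": [list(x) for x in v.violations],
                }
                for v in self.verdicts
            ],
            "candidates": self.candidates,
            "candidate_annotations": self.annotations,
        }

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out_dir / "report.json",
            "cascade": out_dir / "cascade.tsv",
            "verdicts": out_dir / "verdicts.tsv",
        }
        with open(paths["report"], "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
        self.cascade.write_tsv(paths["cascade"])
        write_verdicts_tsv(self.verdicts, paths["verdicts"])
        return paths


def discover(
    variants: Iterable[VariantRecord],
    pedigree: Pedigree,
    annotations: Union[AnnotationMap, Iterable[AnnotationRecord]],
    config: FilterConfig,
    seed: Optional[int] = None,
) -> RunReport:
    """Run the discovery cascade on in-memory inputs."""
    variants = list(variants)
    if not isinstance(annotations, dict):
        annotations = annotation_map(annotations)
    cascade = run_cascade(variants, annotations, pedigree, config)
    for stage in cascade.to_table():
        logger.info(
            "stage %-20s input=%6d surviving=%6d", stage["stage"], stage["input"],
            stage["surviving"],
        )

    by_key = {v.key: v for v in variants}
    cadd_stage = next(s for s in cascade.stages if s.name == "cadd")
    verdicts = [
        check_dominant_segregation(key, by_key[key].genotypes, pedigree)
        for key in sorted(cadd_stage.surviving_keys)
    ]
    candidates = sorted(cascade.final_candidates)
    ann_out = {}
    for key in candidates:
        ann = annotations.get(key)
        ann_out[key] = {
            "gene": ann.gene if ann else None,
            "consequence": ann.consequence if ann else None,
            "maf": ann.maf if ann else None,
            "cadd": ann.cadd if ann else None,
        }
    return RunReport(
        config={
            "affected_sample_ids": list(config.affected_sample_ids),
            "maf_threshold": config.maf_threshold,
            "cadd_threshold": config.cadd_threshold,
            "exonic_classes": sorted(config.exonic_classes),
            "panel_genes": sorted(config.panel_genes),
            "missing_maf_policy": config.missing_maf_policy,
            "missing_cadd_policy": config.missing_cadd_policy,
        },
        cascade=cascade,
        verdicts=verdicts,
        candidates=candidates,
        annotations=ann_out,
        seed=seed,
    )


def run_discovery(
    vcf_path: Union[str, Path],
    ped_path: Union[str, Path],
    annotations_path: Union[str, Path],
    panel_path: Optional[Union[str, Path]] = None,
    out_dir: Optional[Union[str, Path]] = None,
    affected_sample_ids: Optional[Sequence[str]] = None,
    maf_threshold: float = 0.001,
    cadd_threshold: float = 10.0,
    exonic_classes: Iterable[str] = ("exonic",),
    seed: Optional[int] = None,
) -> RunReport:
    """File-level discovery entry point (the ``run-all`` CLI core)."""
    from .annotations import read_annotations
    from .pedigree import mark_genotyped, read_ped
    from .variants import read_vcf

    samples, variants = read_vcf(vcf_path)
    pedigree = mark_genotyped(read_ped(ped_path), samples)
    annotations = annotation_map(read_annotations(annotations_path))
    panel: frozenset[str] = frozenset()
    if panel_path is not None:
        panel = frozenset(
            line.strip()
            for line in Path(panel_path).read_text().splitlines()
            if line.strip()
        )
    if affected_sample_ids is None:
        affected_sample_ids = [
            iid for iid in samples if pedigree.get(iid).status is Status.AFFECTED
        ]
    config = FilterConfig(
        affected_sample_ids=tuple(affected_sample_ids),
        maf_threshold=maf_threshold,
        cadd_threshold=cadd_threshold,
        exonic_classes=frozenset(exonic_classes),
        panel_genes=panel,
    )
    report = discover(variants, pedigree, annotations, config, seed=seed)
    if out_dir is not None:
        report.write(out_dir)
    return report


def pedigree_phase_assignments(
    pedigree: Pedigree,
    markers: MarkerGenotypes,
    mode: str = "literal",
) -> list[OriginAssignment]:
    """Apply the parent-shared and sib-only rules across every nuclear family.

    Both the full genotyped sib group and each child singly are passed to the
    rules; group and singleton applications agree where both fire, and the
    confidence machinery arbitrates heuristic against exclusion-backed labels.
    """
    assignments: list[OriginAssignment] = []
    families: dict[tuple[str, str], list[str]] = {}
    typed = set(markers.genotypes)
    for ind in pedigree:
        if ind.id in typed and ind.father_id and ind.mother_id:
            families.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
    for (father, mother), children in sorted(families.items()):
        for parent in (father, mother):
            if parent not in typed:
                continue
            child_sets = [children] + [[c] for c in children if len(children) > 1]
            for group in child_sets:
                assignments.extend(
                    phase_rule_parent_shared(pedigree, markers, parent, group, mode=mode)
                )
                assignments.extend(
                    phase_rule_sib_only(pedigree, markers, parent, group)
                )
    return assignments


def run_locus_exclusion(
    markers: MarkerGenotypes,
    pedigree: Pedigree,
    links: Iterable[PhaseLink],
    individual_ids: Sequence[str],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    mode: str = "literal",
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[SharingReport, PhasedHaplotypes]:
    """Phase the interval and test haplotype sharing among ``individual_ids``."""
    assignments = pedigree_phase_assignments(pedigree, markers, mode=mode)
    phase_sets = phase_rule_read_links(markers, links)
    haps = assemble_haplotypes(markers, assignments, phase_sets, pedigree)
    report = assess_sharing(haps, individual_ids, min_informative=min_informative)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.write_json(out_dir / "sharing.json")
        haps.to_table().to_csv(out_dir / "phase_labels.tsv", sep="\t", index=False)
    return report, haps
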