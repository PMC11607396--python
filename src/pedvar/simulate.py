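"""Gene-dropping cohort simulator.

Generates synthetic pedigree cohorts with the statistical structure the
discovery analysis assumes, so every pipeline stage is testable without
patient data: founder marker haplotypes drawn from an allele-frequency
spectrum and dropped down the pedigree (optionally with one crossover per
meiosis), one implanted heterozygous causal variant carried by every
affected, a background of independent variants with a realistic MAF/CADD
spectrum, and read links between adjacent heterozygous markers.  A
``TruthRecord`` carries the simulated ground truth (founder haplotypes and
per-individual transmitted haplotypes) for oracle comparisons.

The marker interval deliberately models a *non-causal* candidate region on a
different chromosome from the causal variant, mirroring a locus-exclusion
analysis: transmission of the marker haplotypes is independent of disease
status unless ``affected_haplotype_mode`` forces a scenario:

* ``random`` — unconstrained gene dropping;
* ``shared`` — every affected inherits one designated founder haplotype
  through the interval (the verdict should be "shared");
* ``distinct`` — founder haplotypes are pairwise distinct and the affected
  sib pair receives complementary haplotypes from both parents, so no single
  haplotype is common to the sequenced affecteds (the verdict should be
  "not shared").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .annotations import AnnotationRecord, read_annotations, write_annotations
from .haplotype import MarkerGenotypes, PhaseLink, read_links, write_links
from .intervals import GenomicInterval
from .pedigree import (
    Individual,
    Pedigree,
    Sex,
    Status,
    mark_genotyped,
    read_ped,
    write_ped,
)
from .variants import Genotype, VariantRecord, read_vcf, write_vcf

DEFAULT_INTERVAL = GenomicInterval("12", 91_251_926, 91_637_312)
DEFAULT_PANEL = tuple(f"CDGENE{i:02d}" for i in range(1, 13))

_CONSEQUENCE_CLASSES = (
    ("exonic", 0.03),
    ("splicing", 0.01),
    ("UTR5", 0.03),
    ("UTR3", 0.05),
    ("intronic", 0.55),
    ("ncRNA_intronic", 0.03),
    ("intergenic", 0.30),
)
_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when a simulation request is internally inconsistent."""


def build_default_pedigree() -> Pedigree:
    """Three-plus-generation dominant pedigree fixture.

    Eight affected members across four generations descending from an
    affected founder grandmother, an affected proband with two affected sons
    and an affected first cousin; exactly five affected and four unaffected
    members are flagged genotyped, and the youngest generation has unknown
    status (too young for a late-onset diagnosis).
    """
    M, F, U = Sex.MALE, Sex.FEMALE, Sex.UNKNOWN
    AFF, UN, UNK = Status.AFFECTED, Status.UNAFFECTED, Status.UNKNOWN

    def ind(iid, father, mother, sex, status, genotyped=False):
        return Individual(iid, father, mother, sex, status, genotyped)

    return Pedigree(
        [
            ind("I-1", None, None, M, UN),
            ind("I-2", None, None, F, AFF),  # affected founder grandmother
            ind("II-1", None, None, M, UN),
            ind("II-2", "I-1", "I-2", F, AFF, genotyped=True),
            ind("II-3", "I-1", "I-2", M, AFF),
            ind("II-4", None, None, F, UN),
            ind("II-5", "I-1", "I-2", F, AFF),
            ind("III-1", "II-1", "II-2", M, AFF, genotyped=True),  # proband
            ind("III-2", None, None, F, UN, genotyped=True),
            ind("III-3", "II-1", "II-2", F, UN, genotyped=True),
            ind("III-8", "II-3", "II-4", F, AFF, genotyped=True),  # first cousin
            ind("III-9", None, None, M, UN, genotyped=True),
            ind("IV-1", "III-1", "III-2", M, AFF, genotyped=True),
            ind("IV-2", "III-1", "III-2", F, UN, genotyped=True),
            ind("IV-3", "III-1", "III-2", M, AFF, genotyped=True),
            ind("IV-5", "III-8", "III-9", U, UNK),
            ind("IV-6", "III-8", "III-9", U, UNK),
        ]
    )


DEFAULT_WGS_IDS = ("III-1", "III-8", "IV-1", "IV-3")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated cohort; the seed is explicit, never global."""

    seed: int
    pedigree: Optional[Pedigree] = None  # default: build_default_pedigree()
    n_background_variants: int = 1000
    rare_fraction: float = 0.5
    novel_given_rare: float = 0.3
    cadd_range: tuple[float, float] = (0.0, 40.0)
    cadd_missing_rate: float = 0.03
    annotation_missing_rate: float = 0.02
    panel_genes: tuple[str, ...] = DEFAULT_PANEL
    panel_gene_fraction: float = 0.02
    n_markers: int = 11
    interval: GenomicInterval = DEFAULT_INTERVAL
    marker_allele_freq: float = 0.5
    recombination_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    read_link_rate: float = 0.8
    affected_haplotype_mode: str = "random"  # random | shared | distinct
    wgs_ids: tuple[str, ...] = DEFAULT_WGS_IDS
    causal_chrom: str = "4"
    causal_pos: int = 88_394_487
    causal_gene: str = "SPARCL1"
    causal_cadd_range: tuple[float, float] = (10.0, 15.0)

    def __post_init__(self) -> None:
        for name in (
            "rare_fraction",
            "novel_given_rare",
            "recombination_rate",
            "genotype_missing_rate",
            "read_link_rate",
            "panel_gene_fraction",
            "cadd_missing_rate",
            "annotation_missing_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1], got {value}")
        if self.n_markers < 0 or self.n_background_variants < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.affected_haplotype_mode not in ("random", "shared", "distinct"):
            raise ConfigurationError(
                f"unknown affected_haplotype_mode {self.affected_haplotype_mode!r}"
            )


@dataclass
class TruthRecord:
    """Simulation ground truth, consistent with every emitted genotype."""

    causal_key: str
    marker_keys: list[str]
    founder_haplotypes: dict[str, list[str]]  # founder -> [hap0, hap1]
    haplotypes: dict[str, list[str]]  # individual -> [paternal, maternal]
    transmissions: dict[str, dict]  # individual -> per-side source record
    shared_haplotype: Optional[str]  # forced-shared founder haplotype, if any
    wgs_ids: list[str]
    samples: list[str]

    def to_dict(self) -> dict:
        return {
            "causal_key": self.causal_key,
            "marker_keys": self.marker_keys,
            "founder_haplotypes": self.founder_haplotypes,
            "haplotypes": self.haplotypes,
            "transmissions": self.transmissions,
            "shared_haplotype": self.shared_haplotype,
            "wgs_ids": self.wgs_ids,
            "samples": self.samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigree: Pedigree
    samples: list[str]
    variants: list[VariantRecord]  # background + causal (genome-wide)
    annotations: list[AnnotationRecord]
    marker_genotypes: MarkerGenotypes
    links: list[PhaseLink]
    truth: TruthRecord


def disease_founder(ped: Pedigree) -> str:
    """The unique founder from whom every affected can inherit one haplotype.

    Raises :class:`ConfigurationError` when no founder is an ancestor (or
    self) of all affected members.
    """
    affected = set(ped.affected_ids())
    if not affected:
        raise ConfigurationError("pedigree has no affected members")
    candidates = []
    for founder in ped.founders():
        reach = {founder.id}
        frontier = [founder.id]
        while frontier:
            nxt = []
            for pid in frontier:
                for child in ped.children_of(pid):
                    if child.id not in reach:
                        reach.add(child.id)
                        nxt.append(child.id)
            frontier = nxt
        if affected <= reach:
            candidates.append(founder.id)
    if not candidates:
        raise ConfigurationError(
            "no single founder haplotype can reach all affected members"
        )
    return candidates[0]


def _topological_order(ped: Pedigree) -> list[Individual]:
    placed: set[str] = set()
    ordered: list[Individual] = []
    pending = list(ped)
    while pending:
        progressed = False
        for ind in list(pending):
            ok = all(
                pid is None or pid in placed
                for pid in (ind.father_id, ind.mother_id)
            )
            if ok:
                ordered.append(ind)
                placed.add(ind.id)
                pending.remove(ind)
                progressed = True
        if not progressed:
            raise ConfigurationError("pedigree is cyclic or has dangling parents")
    return ordered


def _transmit(
    parent_haps: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    recombination_rate: float,
    forced_hap: Optional[int] = None,
) -> tuple[np.ndarray, dict]:
    """One meiosis: pick a parental haplotype, optionally with one crossover."""
    n = parent_haps[0].shape[0]
    hap_index = int(rng.integers(2)) if forced_hap is None else forced_hap
    crossover = None
    hap = parent_haps[hap_index].copy()
    if (
        forced_hap is None
        and recombination_rate > 0
        and n > 1
        and rng.random() < recombination_rate
    ):
        crossover = int(rng.integers(1, n))
        hap[crossover:] = parent_haps[1 - hap_index][crossover:]
    return hap, {"hap": hap_index, "crossover": crossover}


def _draw_founder_haplotypes(
    founder_ids: Sequence[str],
    freqs: np.ndarray,
    rng: np.random.Generator,
    require_distinct: bool,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    n_markers = freqs.shape[0]
    for attempt in range(200):
        haps = {
            fid: (
                (rng.random(n_markers) < freqs).astype(np.int8),
                (rng.random(n_markers) < freqs).astype(np.int8),
            )
            for fid in founder_ids
        }
        if not require_distinct:
            return haps
        strings = [h.tobytes() for pair in haps.values() for h in pair]
        if len(set(strings)) == len(strings):
            return haps
    raise ConfigurationError(
        "could not draw pairwise-distinct founder haplotypes "
        f"({2 * len(founder_ids)} haplotypes over {n_markers} markers)"
    )


def _gene_drop(
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], dict[str, dict], Optional[np.ndarray], dict[str, list[int]]]:
    """Drop founder haplotypes down the pedigree.

    Returns (haplotypes per individual as (paternal, maternal), transmission
    records, the forced-shared haplotype or None, and per-individual flags of
    which hap index carries the shared haplotype)."""
    n = config.n_markers
    freqs = np.full(n, config.marker_allele_freq, dtype=float) if np.isscalar(
        config.marker_allele_freq
    ) else np.asarray(config.marker_allele_freq, dtype=float)
    mode = config.affected_haplotype_mode
    founders = [ind.id for ind in ped.founders()]
    founder_haps = _draw_founder_haplotypes(
        founders, freqs, rng, require_distinct=(mode == "distinct")
    )

    shared_hap: Optional[np.ndarray] = None
    carrier_hap_index: dict[str, int] = {}
    if mode == "shared":
        root = disease_founder(ped)
        shared_hap = founder_haps[root][0].copy()
        carrier_hap_index[root] = 0

    # Complementary routing for the affected full-sib pair (distinct mode).
    forced: dict[tuple[str, str], int] = {}  # (child, parent) -> hap index
    if mode == "distinct":
        by_parents: dict[tuple, list[str]] = {}
        for iid in config.wgs_ids:
            if iid in ped:
                ind = ped.get(iid)
                if ind.father_id and ind.mother_id:
                    by_parents.setdefault((ind.father_id, ind.mother_id), []).append(iid)
        for (father, mother), sibs in by_parents.items():
            for k, sib in enumerate(sorted(sibs)):
                forced[(sib, father)] = k % 2
                forced[(sib, mother)] = k % 2

    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    transmissions: dict[str, dict] = {}
    affected = set(ped.affected_ids())
    for ind in _topological_order(ped):
        if ind.is_founder():
            haplotypes[ind.id] = founder_haps[ind.id]
            transmissions[ind.id] = {"paternal": None, "maternal": None}
            continue
        sides = {}
        haps = []
        for side, pid in (("paternal", ind.father_id), ("maternal", ind.mother_id)):
            parent_haps = haplotypes[pid]
            forced_hap = forced.get((ind.id, pid))
            if (
                mode == "shared"
                and ind.id in affected
                and pid in carrier_hap_index
            ):
                forced_hap = carrier_hap_index[pid]
            hap, rec = _transmit(parent_haps, rng, config.recombination_rate, forced_hap)
            rec["parent"] = pid
            sides[side] = rec
            haps.append(hap)
            if (
                mode == "shared"
                and pid in carrier_hap_index
                and rec["hap"] == carrier_hap_index[pid]
                and rec["crossover"] is None
            ):
                carrier_hap_index[ind.id] = 0 if side == "paternal" else 1
        haplotypes[ind.id] = (haps[0], haps[1])
        transmissions[ind.id] = sides

    if mode == "shared":
        missing = [iid for iid in affected if iid not in carrier_hap_index]
        if missing:  # cannot happen with forced transmissions, kept as a guard
            raise ConfigurationError(
                f"shared haplotype failed to reach affecteds: {missing}"
            )
    carriers = {iid: [carrier_hap_index[iid]] for iid in carrier_hap_index}
    return haplotypes, transmissions, shared_hap, carriers


def _genotype_from_haps(pat: int, mat: int) -> Genotype:
    total = pat + mat
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[total]


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _background_variants(
    config: SimulationConfig,
    samples: list[str],
    rng: np.random.Generator,
    reserved_keys: set[str],
) -> tuple[list[VariantRecord], list[AnnotationRecord]]:
    n, s = config.n_background_variants, len(samples)
    if n == 0:
        return [], []

    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(10_000, 200_000_000, size=n)

    # MAF spectrum: rare (novel point mass + log-uniform below the rarity
    # threshold) versus common (log-uniform above it).
    is_rare = rng.random(n) < config.rare_fraction
    is_novel = is_rare & (rng.random(n) < config.novel_given_rare)
    log_lo, log_mid, log_hi = np.log10(1e-6), np.log10(1e-3), np.log10(0.5)
    mafs = np.where(
        is_rare,
        10 ** rng.uniform(log_lo, log_mid, size=n),
        10 ** rng.uniform(log_mid, log_hi, size=n),
    )
    mafs[is_novel] = 0.0

    classes = [c for c, _ in _CONSEQUENCE_CLASSES]
    class_probs = np.array([p for _, p in _CONSEQUENCE_CLASSES])
    consequence = rng.choice(len(classes), size=n, p=class_probs / class_probs.sum())

    cadd = rng.uniform(*config.cadd_range, size=n)
    cadd_absent = rng.random(n) < config.cadd_missing_rate
    ann_absent = rng.random(n) < config.annotation_missing_rate
    in_panel = rng.random(n) < config.panel_gene_fraction
    panel_pick = rng.integers(0, len(config.panel_genes), size=n)
    gene_number = rng.integers(0, 99_999, size=n)
    novel_maf_absent = rng.random(n) < 0.5  # novel: absent from the database
    indel_kind = rng.random(n)  # <0.05 insertion, <0.10 deletion, else SNV

    # Genotypes: Hardy-Weinberg draws at the population frequency,
    # conditioned on the site being variant in the cohort (>=1 carrier).
    draw_freq = np.maximum(mafs, 1.0 / (4.0 * max(s, 1)))
    p_rr = (1.0 - draw_freq) ** 2
    p_het = 2.0 * draw_freq * (1.0 - draw_freq)
    u = rng.random((n, s))
    gt_matrix = np.where(
        u < p_rr[:, None],
        int(Genotype.HOM_REF),
        np.where(u < (p_rr + p_het)[:, None], int(Genotype.HET), int(Genotype.HOM_ALT)),
    ).astype(np.int8)
    no_carrier = (gt_matrix == int(Genotype.HOM_REF)).all(axis=1)
    forced_sample = rng.integers(0, s, size=n)
    gt_matrix[no_carrier, forced_sample[no_carrier]] = int(Genotype.HET)

    variants: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    seen = set(reserved_keys)
    for i in range(n):
        ref, alt = _random_snv_alleles(rng)
        if indel_kind[i] < 0.05:
            alt = ref + alt  # insertion
        elif indel_kind[i] < 0.10:
            ref, alt = ref + alt, ref  # deletion
        chrom, pos = str(chroms[i]), int(positions[i])
        key = f"{chrom}:{pos}:{ref}:{alt}"
        while key in seen:
            pos += 1
            key = f"{chrom}:{pos}:{ref}:{alt}"
        seen.add(key)
        genotypes = {
            sid: Genotype(int(gt_matrix[i, j])) for j, sid in enumerate(samples)
        }
        variants.append(VariantRecord(chrom, pos, ref, alt, genotypes))
        if ann_absent[i]:
            continue
        klass = classes[consequence[i]]
        if klass == "intergenic":
            gene = None
        elif in_panel[i]:
            gene = config.panel_genes[panel_pick[i]]
        else:
            gene = f"G{gene_number[i]:05d}"
        maf: Optional[float] = float(mafs[i])
        if is_novel[i] and novel_maf_absent[i]:
            maf = None
        annotations.append(
            AnnotationRecord(
                key=key,
                gene=gene,
                consequence=klass,
                maf=maf,
                cadd=None if cadd_absent[i] else float(cadd[i]),
            )
        )
    return variants, annotations


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort; identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    ped = config.pedigree if config.pedigree is not None else build_default_pedigree()
    samples = ped.genotyped_ids()
    disease_founder(ped)  # validates the causal-descent requirement early

    # --- causal variant -----------------------------------------------------
    causal_ref, causal_alt = "G", "A"
    causal_key = f"{config.causal_chrom}:{config.causal_pos}:{causal_ref}:{causal_alt}"
    causal_genotypes = {}
    for iid in samples:
        status = ped.get(iid).status
        causal_genotypes[iid] = (
            Genotype.HET if status is Status.AFFECTED else Genotype.HOM_REF
        )
    causal_variant = VariantRecord(
        config.causal_chrom, config.causal_pos, causal_ref, causal_alt, causal_genotypes
    )
    lo, hi = config.causal_cadd_range
    causal_annotation = AnnotationRecord(
        key=causal_key,
        gene=config.causal_gene,
        consequence="exonic",
        maf=0.0,
        cadd=float(np.nextafter(lo, hi) + rng.random() * (hi - np.nextafter(lo, hi))),
    )

    # --- background ---------------------------------------------------------
    background, bg_annotations = _background_variants(
        config, samples, rng, reserved_keys={causal_key}
    )

    # --- marker haplotypes (gene dropping) ----------------------------------
    if config.n_markers > 0:
        marker_pos = np.sort(
            rng.choice(
                np.arange(config.interval.start, config.interval.end + 1),
                size=config.n_markers,
                replace=False,
            )
        )
        marker_alleles = [_random_snv_alleles(rng) for _ in range(config.n_markers)]
        haplotypes, transmissions, shared_hap, _ = _gene_drop(ped, config, rng)
        marker_keys = [
            f"{config.interval.chrom}:{int(p)}:{r}:{a}"
            for p, (r, a) in zip(marker_pos, marker_alleles)
        ]
    else:
        marker_keys = []
        haplotypes = {
            ind.id: (np.zeros(0, dtype=np.int8), np.zeros(0, dtype=np.int8))
            for ind in ped
        }
        transmissions = {ind.id: {"paternal": None, "maternal": None} for ind in ped}
        shared_hap = None

    genotypes: dict[str, list[Genotype]] = {}
    for iid in samples:
        pat, mat = haplotypes[iid]
        row = [_genotype_from_haps(int(p), int(m)) for p, m in zip(pat, mat)]
        if config.genotype_missing_rate > 0:
            mask = rng.random(len(row)) < config.genotype_missing_rate
            row = [Genotype.MISSING if mask[m] else g for m, g in enumerate(row)]
        genotypes[iid] = row
    marker_genotypes = MarkerGenotypes(
        interval=config.interval, keys=marker_keys, genotypes=genotypes
    )

    # --- read links between adjacent heterozygous markers -------------------
    links: list[PhaseLink] = []
    for iid in samples:
        het = marker_genotypes.het_markers(iid)
        pat = haplotypes[iid][0]
        for a, b in zip(het, het[1:]):
            if rng.random() < config.read_link_rate:
                links.append(
                    PhaseLink(
                        individual_id=iid,
                        marker_a=a,
                        marker_b=b,
                        allele_a=int(pat[a]),
                        allele_b=int(pat[b]),
                    )
                )

    truth = TruthRecord(
        causal_key=causal_key,
        marker_keys=marker_keys,
        founder_haplotypes={
            ind.id: [
                "".join(map(str, haplotypes[ind.id][0])),
                "".join(map(str, haplotypes[ind.id][1])),
            ]
            for ind in ped.founders()
        },
        haplotypes={
            ind.id: [
                "".join(map(str, haplotypes[ind.id][0])),
                "".join(map(str, haplotypes[ind.id][1])),
            ]
            for ind in ped
        },
        transmissions=transmissions,
        shared_haplotype="".join(map(str, shared_hap)) if shared_hap is not None else None,
        wgs_ids=[iid for iid in config.wgs_ids if iid in ped],
        samples=list(samples),
    )
    return SimulatedCohort(
        config=config,
        pedigree=ped,
        samples=list(samples),
        variants=background + [causal_variant],
        annotations=bg_annotations + [causal_annotation],
        marker_genotypes=marker_genotypes,
        links=links,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture files

FIXTURE_FILES = {
    "vcf": "cohort.vcf",
    "ped": "pedigree.ped",
    "annotations": "annotations.tsv",
    "markers": "markers.vcf",
    "links": "links.tsv",
    "panel": "panel.txt",
    "truth": "truth.json",
}


def write_fixture(cohort: SimulatedCohort, directory: Union[str, Path]) -> dict[str, Path]:
    """Emit the cohort in the exact dialects the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in FIXTURE_FILES.items()}

    write_vcf(paths["vcf"], cohort.samples, cohort.variants)
    write_ped(cohort.pedigree, paths["ped"])
    write_annotations(cohort.annotations, paths["annotations"])

    marker_records = [
        VariantRecord(
            *_key_fields(key),
            genotypes={
                iid: cohort.marker_genotypes.genotype(iid, m)
                for iid in cohort.samples
            },
        )
        for m, key in enumerate(cohort.marker_genotypes.keys)
    ]
    write_vcf(paths["markers"], cohort.samples, marker_records)
    write_links(cohort.links, cohort.marker_genotypes, paths["links"])
    paths["panel"].write_text("".join(f"{g}\n" for g in cohort.config.panel_genes))
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=2)
        fh.write("\n")
    return paths


def _key_fields(key: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = key.split(":")
    return chrom, int(pos), ref, alt


@dataclass
class FixtureSet:
    """Round-trippable view of an on-disk cohort fixture."""

    samples: list[str]
    variants: list[VariantRecord]
    pedigree: Pedigree
    annotations: list[AnnotationRecord]
    marker_genotypes: MarkerGenotypes
    links: list[PhaseLink]
    panel: tuple[str, ...]
    truth: TruthRecord


def read_fixture(directory: Union[str, Path], interval: Optional[GenomicInterval] = None) -> FixtureSet:
    directory = Path(directory)
    paths = {name: directory / fname for name, fname in FIXTURE_FILES.items()}
    samples, variants = read_vcf(paths["vcf"])
    pedigree = mark_genotyped(read_ped(paths["ped"]), samples)
    annotations = read_annotations(paths["annotations"])
    with open(paths["truth"]) as fh:
        truth = TruthRecord.from_dict(json.load(fh))
    _, marker_variants = read_vcf(paths["markers"])
    if interval is None:
        interval = DEFAULT_INTERVAL
        if truth.marker_keys:
            positions = [int(k.split(":")[1]) for k in truth.marker_keys]
            chrom = truth.marker_keys[0].split(":")[0]
            if not all(
                DEFAULT_INTERVAL.contains(chrom, p) for p in positions
            ):  # custom interval: recover the tightest span
                interval = GenomicInterval(chrom, min(positions), max(positions))
    marker_genotypes = MarkerGenotypes.from_variants(
        marker_variants, interval, sample_ids=samples
    )
    links = read_links(paths["links"], marker_genotypes)
    panel = tuple(
        line.strip() for line in paths["panel"].read_text().splitlines() if line.strip()
    )
    return FixtureSet(
        samples=samples,
        variants=variants,
        pedigree=pedigree,
        annotations=annotations,
        marker_genotypes=marker_genotypes,
        links=links,
        panel=panel,
        truth=truth,
    )
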