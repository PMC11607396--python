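"""Per-variant annotation table: gene, consequence class, MAF, CADD.

Annotations are *inputs* here (the upstream annotator is out of scope).
Absent MAF/CADD cells are preserved as absent, never coerced to zero: the
filtering stage owns the interpretation (e.g. absent MAF = novel), so the
policy is explicit and logged rather than baked into I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .variants import VariantKey, parse_variant_key

_COLUMNS = ["key", "gene", "consequence", "maf", "cadd"]


@dataclass(frozen=True)
class AnnotationRecord:
    key: VariantKey
    gene: Optional[str] = None
    consequence: str = ""
    maf: Optional[float] = None
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        parse_variant_key(self.key)  # validates format
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf out of [0,1] for {self.key}: {self.maf}")
        if self.cadd is not None and (not math.isfinite(self.cadd) or self.cadd < 0):
            raise ValueError(f"cadd must be finite and >= 0 for {self.key}: {self.cadd}")


AnnotationMap = Mapping[VariantKey, AnnotationRecord]


def annotation_map(records: Iterable[AnnotationRecord]) -> dict[VariantKey, AnnotationRecord]:
    """Index annotation records by variant key (last record wins on duplicates)."""
    return {rec.key: rec for rec in records}


def read_annotations(path: Union[str, Path]) -> list[AnnotationRecord]:
    """Read the TSV annotation table (header: key, gene, consequence, maf, cadd).

    Empty cells mean *absent* and stay absent.  A MAF outside [0, 1] raises a
    ``ValueError`` naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table lacks columns {missing}")
    records: list[AnnotationRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        maf_s, cadd_s = row.maf.strip(), row.cadd.strip()
        try:
            maf = float(maf_s) if maf_s else None
            cadd = float(cadd_s) if cadd_s else None
            rec = AnnotationRecord(
                key=row.key,
                gene=row.gene.strip() or None,
                consequence=row.consequence.strip(),
                maf=maf,
                cadd=cadd,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_number}: {exc}") from exc
        records.append(rec)
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: Union[str, Path]) -> None:
    """Write annotation records as TSV; absent values become empty cells."""

    def fmt(x: Optional[float]) -> str:
        return "" if x is None else repr(float(x))

    df = pd.DataFrame(
        [
            {
                "key": r.key,
                "gene": r.gene or "",
                "consequence": r.consequence,
                "maf": fmt(r.maf),
                "cadd": fmt(r.cadd),
            }
            for r in records
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
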