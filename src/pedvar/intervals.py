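"""Genomic intervals: 1-based inclusive internally, BED converted on read."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .variants import normalize_chrom


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval [start, end] in 1-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start > end ({self.start} > {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int, chrom_style: str = "plain") -> bool:
        return (
            normalize_chrom(chrom, chrom_style) == normalize_chrom(self.chrom, chrom_style)
            and self.start <= pos <= self.end
        )

    def region_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(region: str, chrom_style: str = "plain") -> GenomicInterval:
    """Parse ``"chrom:start-end"`` (thousands separators tolerated)."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValueError(f"cannot parse region {region!r} (want chrom:start-end)")
    chrom, start_s, end_s = m.groups()
    return GenomicInterval(
        chrom=normalize_chrom(chrom, chrom_style),
        start=int(start_s.replace(",", "")),
        end=int(end_s.replace(",", "")),
    )


def read_bed(path: Union[str, Path], chrom_style: str = "plain") -> list[GenomicInterval]:
    """Read BED3 (0-based half-open) into 1-based inclusive intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            intervals.append(
                GenomicInterval(
                    chrom=normalize_chrom(chrom, chrom_style),
                    start=start0 + 1,
                    end=end0,
                )
            )
    return intervals
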