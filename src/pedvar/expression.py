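"""TPM (transcripts per million) computation and tissue expression ranking.

TPM length-normalizes read counts before library-size normalization, so each
sample column sums to one million and values are comparable across tissues:

    rate_g   = count_g / (length_g / 1000)          (reads per kilobase)
    TPM_g    = rate_g / sum_h rate_h * 1e6

Gene length is a user-supplied effective length in base pairs; whether that
is union-exon or transcript length is the caller's contract, not computed
here.  Alignment and read counting are upstream of this module.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd


def compute_tpm(
    counts: pd.DataFrame, lengths: Union[pd.Series, Mapping[str, float]]
) -> pd.DataFrame:
    """TPM matrix from a gene x sample count matrix and gene lengths (bp).

    Raises ``ValueError`` naming the gene on a missing or non-positive
    length, and on negative counts.  An all-zero sample column yields an
    all-zero TPM column with a warning rather than an error.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise ValueError(f"no gene length for: {', '.join(map(str, missing[:5]))}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"gene length must be positive (gene {bad!r})")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")

    rates = values / (lengths.to_numpy()[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"all-zero count column(s): {list(counts.columns[zero_cols])}; "
            f"TPM set to zero",
            stacklevel=2,
        )
    safe_totals = np.where(zero_cols, 1.0, totals)
    tpm = rates / safe_totals * 1e6
    tpm[:, zero_cols] = 0.0
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def rank_tissues(gene: str, tpm: pd.DataFrame) -> list[tuple[str, float]]:
    """Tissues ordered by descending TPM for one gene.

    Ties are broken by tissue label (lexicographic) and flagged with a
    warning, since a tie makes the printed order partly arbitrary.
    """
    if gene not in tpm.index:
        raise ValueError(f"gene {gene!r} not in TPM matrix")
    row = tpm.loc[gene]
    if row.duplicated().any():
        warnings.warn(f"tied TPM values for {gene}; ties broken by tissue label",
                      stacklevel=2)
    ordered = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(tissue, float(value)) for tissue, value in ordered]


def read_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Gene x sample read counts from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_gene_lengths(path: Union[str, Path]) -> pd.Series:
    """Gene lengths from a two-column TSV (gene, length_bp)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_tpm(tpm: pd.DataFrame, path: Union[str, Path]) -> None:
    tpm.to_csv(path, sep="\t")


def write_ranking(
    ranking: list[tuple[str, float]], gene: str, path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"gene": gene, "ranking": [{"tissue": t, "tpm": v} for t, v in ranking]},
            fh,
            indent=2,
        )
        fh.write("\n")
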