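"""Count normalization to log2 RPKM and relative (minimum-subtracted) profiles.

RPKM here is reads per kilobase of gene per million *effective* library
reads, where the effective library size of a sample is

    N_eff = merged_filtered_reads * mapped_fraction

i.e. the post-rRNA merged read count scaled by the fraction of those reads
that mapped to the target genome. A pseudocount (default 1 read) is added
before the log so zero counts stay finite. The total unmerged read count of
each run is carried as provenance metadata (``DataFrame.attrs``), not in the
per-value formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LibraryFactors:
    """Per-sample normalization quantities."""

    sample_id: str
    total_unmerged_reads: int
    merged_filtered_reads: int
    mapped_fraction: float

    def __post_init__(self) -> None:
        if self.merged_filtered_reads < 1:
            raise ValueError(f"{self.sample_id}: merged_filtered_reads must be >= 1")
        if not 0.0 < self.mapped_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: mapped_fraction must be in (0, 1]")

    @property
    def effective_library_size(self) -> float:
        return self.merged_filtered_reads * self.mapped_fraction


def compute_log2_rpkm(
    counts: pd.DataFrame,
    factors: Mapping[str, LibraryFactors],
    gene_lengths: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 RPKM from a genes x samples count table.

    RPKM = (count + pseudocount) * 1e9 / (gene_length_bp * N_eff).
    Every sample must have factors and every gene a length >= 1.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    missing = set(counts.columns) - set(factors)
    if missing:
        raise ValueError(f"missing library factors for samples {sorted(missing)}")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError(
            f"missing gene lengths for {list(lengths.index[lengths.isna()])[:5]}"
        )
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    n_eff = pd.Series(
        {s: factors[s].effective_library_size for s in counts.columns}, dtype=float
    )
    if (n_eff <= 0).any():
        raise ValueError("effective library size must be positive")
    rpkm = (counts + pseudocount).div(lengths, axis=0).div(n_eff, axis=1) * 1e9
    out = np.log2(rpkm)
    out.attrs["pseudocount"] = pseudocount
    out.attrs["total_unmerged_reads"] = {
        s: factors[s].total_unmerged_reads for s in counts.columns
    }
    return out


def relative_to_min(values: pd.DataFrame | pd.Series):
    """Subtract each gene's minimum over timepoints; the per-gene minimum of
    the result is exactly 0 (the dLog2 RPKM profile). Idempotent."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite expression values")
    if isinstance(values, pd.Series):
        return values - values.min()
    return values.sub(values.min(axis=1), axis=0)


def pearson(x, y) -> float:
    """Product-moment correlation. Returns NaN (the documented "undefined"
    sentinel) for a constant series rather than a silent 0; callers decide
    how to treat it."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


# ---------------------------------------------------------------- file I/O

def read_counts(path: str | Path) -> pd.DataFrame:
    """TSV with gene_id in the first column, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return df


def read_factors(path: str | Path) -> dict[str, LibraryFactors]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.sample_id: LibraryFactors(
            sample_id=row.sample_id,
            total_unmerged_reads=int(row.total_unmerged_reads),
            merged_filtered_reads=int(row.merged_filtered_reads),
            mapped_fraction=float(row.mapped_fraction),
        )
        for row in df.itertuples(index=False)
    }


def write_factors(factors: Mapping[str, LibraryFactors], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "total_unmerged_reads": f.total_unmerged_reads,
                "merged_filtered_reads": f.merged_filtered_reads,
                "mapped_fraction": f.mapped_fraction,
            }
            for f in factors.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6f", index_label="gene_id")
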