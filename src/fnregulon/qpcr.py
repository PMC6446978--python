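"""RT-qPCR analysis: primer/amplicon arithmetic, reference-gene
normalization, fold change, contamination check, and cross-validation of
qPCR profiles against RNA-seq relative profiles.

Validation rule set: a gene whose reference-normalized qPCR series changes
less than ``fc_min``-fold over the cycle is called "no_significant_change"
(its correlation is still reported, but not judged); otherwise it is
"validated" when the Pearson correlation between log2 qPCR and the RNA-seq
dlog2 RPKM profile exceeds ``r_min`` (default 0.5), else "not_validated".

The amplicon length convention is end - start (not end - start + 1): the
coordinate dialect under which each primer's printed span equals its
length. Declared-vs-computed mismatches are surfaced, never silently
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import pearson

DEFAULT_REFERENCE_GENE = "rpoN"
DEFAULT_R_MIN = 0.5
DEFAULT_FC_MIN = 2.0
DEFAULT_NRTC_ADVISORY_CYCLES = 5.0


@dataclass(frozen=True)
class PrimerPair:
    gene_id: str
    forward_seq: str
    reverse_seq: str
    forward_start: int
    forward_end: int
    reverse_start: int
    reverse_end: int
    declared_amplicon_bp: int | None = None


@dataclass
class QpcrSeries:
    """Copy numbers over the sampled timepoints for one gene."""

    gene_id: str
    series: pd.Series  # index: timepoint labels, values: copies > 0
    reference_gene_id: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        if (self.series <= 0).any():
            raise ValueError(f"{self.gene_id}: copy numbers must be positive")


@dataclass(frozen=True)
class ValidationResult:
    gene_id: str
    pearson_r: float
    fold_change: float
    verdict: str  # validated | no_significant_change | not_validated


def amplicon_length(pair: PrimerPair) -> int:
    """Amplicon span: reverse_end - forward_start."""
    if pair.reverse_end <= pair.forward_start:
        raise ValueError(
            f"{pair.gene_id}: reverse_end ({pair.reverse_end}) must exceed "
            f"forward_start ({pair.forward_start})"
        )
    return pair.reverse_end - pair.forward_start


def amplicon_mismatch(pair: PrimerPair) -> int | None:
    """computed - declared amplicon length, or None when no declared value.
    Non-zero means the primer table row is internally inconsistent."""
    if pair.declared_amplicon_bp is None:
        return None
    return amplicon_length(pair) - pair.declared_amplicon_bp


def load_primer_table(path: str | Path | None = None) -> list[PrimerPair]:
    """Read a primer table TSV. With no path, loads the bundled
    Accumulibacter respiratory-gene primer set."""
    if path is None:
        ref = resources.files("fnregulon") / "data" / "accumulibacter_primers.tsv"
        df = pd.read_csv(ref.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        PrimerPair(
            gene_id=r.gene_id,
            forward_seq=r.forward_seq,
            reverse_seq=r.reverse_seq,
            forward_start=int(r.forward_start),
            forward_end=int(r.forward_end),
            reverse_start=int(r.reverse_start),
            reverse_end=int(r.reverse_end),
            declared_amplicon_bp=int(r.declared_amplicon_bp)
            if "declared_amplicon_bp" in df.columns and pd.notna(r.declared_amplicon_bp)
            else None,
        )
        for r in df.itertuples(index=False)
    ]


def normalize_to_reference(target: QpcrSeries, reference: QpcrSeries) -> pd.Series:
    """Element-wise target/reference copy ratio over matching timepoints."""
    if list(target.series.index) != list(reference.series.index):
        raise ValueError(
            f"timepoint mismatch between {target.gene_id} and {reference.gene_id}"
        )
    if (reference.series <= 0).any():
        raise ValueError("reference copies must be positive")
    return target.series / reference.series


def relative_to_min_copies(series: pd.Series) -> pd.Series:
    """Each point divided by the cycle minimum; the minimum becomes exactly 1.
    Invariant to multiplicative rescaling of the input."""
    if (series <= 0).any():
        raise ValueError("copy ratios must be positive")
    return series / series.min()


def fold_change(series: pd.Series) -> float:
    """max/min over the cycle (>= 1)."""
    if (series <= 0).any():
        raise ValueError("values must be positive")
    return float(series.max() / series.min())


def validate(
    qpcr_normalized: pd.Series,
    rnaseq_profile: pd.Series,
    gene_id: str = "",
    r_min: float = DEFAULT_R_MIN,
    fc_min: float = DEFAULT_FC_MIN,
) -> ValidationResult:
    """Cross-validate a reference-normalized qPCR series against the RNA-seq
    dlog2 RPKM profile of the same gene over matching timepoints."""
    if len(qpcr_normalized) != len(rnaseq_profile):
        raise ValueError("qPCR and RNA-seq series must cover the same timepoints")
    fc = fold_change(qpcr_normalized)
    r = pearson(np.log2(qpcr_normalized.to_numpy(dtype=float)),
                rnaseq_profile.to_numpy(dtype=float))
    if fc < fc_min:
        verdict = "no_significant_change"
    elif r > r_min:
        verdict = "validated"
    else:
        verdict = "not_validated"
    return ValidationResult(gene_id=gene_id, pearson_r=r, fold_change=fc,
                            verdict=verdict)


def nrtc_delta_ct(
    ct_cdna: Sequence[float],
    ct_nrtc: Sequence[float],
    advisory_threshold: float = DEFAULT_NRTC_ADVISORY_CYCLES,
) -> tuple[float, bool]:
    """Genomic-DNA contamination check: mean (NRTC - cDNA) threshold-cycle
    difference over paired reactions. Returns (mean dCT, contamination
    advisory flag); the flag is set when the mean dCT falls below the
    advisory threshold (default 5 cycles), i.e. the no-RT control amplifies
    suspiciously close to the cDNA."""
    c = np.asarray(ct_cdna, dtype=float)
    n = np.asarray(ct_nrtc, dtype=float)
    if c.shape != n.shape or c.ndim != 1 or c.size == 0:
        raise ValueError("cDNA and NRTC CT values must be paired")
    mean_delta = float((n - c).mean())
    return mean_delta, mean_delta < advisory_threshold


def write_validation(results: Sequence[ValidationResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": r.gene_id, "pearson_r": round(r.pearson_r, 4),
             "fold_change": round(r.fold_change, 4), "verdict": r.verdict}
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: str | Path) -> dict[str, QpcrSeries]:
    """Long TSV (gene_id, timepoint, copies) -> per-gene series."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        out[gid] = QpcrSeries(
            gene_id=gid,
            series=pd.Series(sub.copies.to_numpy(dtype=float),
                             index=list(sub.timepoint)),
        )
    return out


def write_qpcr_table(series: Sequence[QpcrSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for tp, v in s.series.items():
            rows.append({"gene_id": s.gene_id, "timepoint": tp, "copies": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
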