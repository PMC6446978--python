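"""Operon prediction from strand, intergenic gap, and co-expression.

Adjacent genes are merged into one transcription unit when they lie on the
same contig and strand, the intergenic gap is at most ``max_gap_bp``
(default 1,000; overlapping genes count as gap <= 0), and their expression
profiles correlate with Pearson r >= ``min_pearson`` (default 0.7). An
undefined correlation (constant profile, or a gene without a profile) never
merges. Chaining is adjacent-pair by default; ``all_pairs=True`` requires
every within-operon pair to pass the correlation threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .expression import pearson
from .genome import GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OperonConfig:
    min_pearson: float = 0.7
    max_gap_bp: int = 1000
    all_pairs: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.min_pearson <= 1.0:
            raise ValueError("min_pearson must be in [-1, 1]")
        if self.max_gap_bp < 0:
            raise ValueError("max_gap_bp must be >= 0")


@dataclass
class Operon:
    """A maximal run of adjacent co-expressed same-strand genes.

    ``member_gene_ids`` is ordered 5'->3' in transcription order; the anchor
    is the 5'-most member (lowest start on '+', highest end on '-')."""

    operon_id: str
    contig_id: str
    strand: str
    member_gene_ids: list[str] = field(default_factory=list)

    @property
    def anchor_gene_id(self) -> str:
        if not self.member_gene_ids:
            raise ValueError("empty operon")
        return self.member_gene_ids[0]

    def __len__(self) -> int:
        return len(self.member_gene_ids)


def operon_anchor(operon: Operon) -> str:
    """The 5'-most member: transcription starts here, so its upstream region
    is the operon's promoter."""
    return operon.anchor_gene_id


def intergenic_gap(left: GeneAnnotation, right: GeneAnnotation) -> int:
    """Gap in bp between two genes in genomic order; negative if overlapping."""
    return right.start - left.end - 1


def _profile_r(profiles: pd.DataFrame | None, a: str, b: str) -> float:
    if profiles is None or a not in profiles.index or b not in profiles.index:
        return math.nan
    return pearson(profiles.loc[a], profiles.loc[b])


def call_operons(
    genome: GenomeRecord,
    profiles: pd.DataFrame | None,
    config: OperonConfig = OperonConfig(),
) -> list[Operon]:
    """Partition all genes of a genome into putative operons.

    ``profiles`` is a genes x timepoints table of (relative) log2 RPKM;
    Pearson correlation is shift-invariant, so raw and minimum-subtracted
    profiles give identical calls. Genes absent from ``profiles`` become
    singletons (logged). Returns one Operon per run; every gene appears in
    exactly one.
    """
    if profiles is None:
        logger.warning("no expression profiles supplied; gap/strand rules only "
                       "cannot merge (every gene becomes a singleton)")
    missing = [g.gene_id for g in genome.genes
               if profiles is None or g.gene_id not in profiles.index]
    if missing and profiles is not None:
        logger.warning("%d genes lack expression profiles; forced singletons",
                       len(missing))

    operons: list[Operon] = []
    runs: list[list[GeneAnnotation]] = []
    prev: GeneAnnotation | None = None
    for gene in genome.genes:  # sorted by (contig, start)
        merge = False
        if prev is not None and gene.contig_id == prev.contig_id \
                and gene.strand == prev.strand \
                and intergenic_gap(prev, gene) <= config.max_gap_bp:
            r = _profile_r(profiles, prev.gene_id, gene.gene_id)
            if not math.isnan(r) and r >= config.min_pearson:
                merge = True
                if config.all_pairs:
                    for member in runs[-1][:-1]:
                        r2 = _profile_r(profiles, member.gene_id, gene.gene_id)
                        if math.isnan(r2) or r2 < config.min_pearson:
                            merge = False
                            break
        if merge:
            runs[-1].append(gene)
        else:
            runs.append([gene])
        prev = gene

    for i, run in enumerate(runs):
        members = [g.gene_id for g in run]
        if run[0].strand == "-":
            members = members[::-1]  # transcription order is right-to-left
        operons.append(
            Operon(
                operon_id=f"{genome.genome_id}_op{i + 1:04d}",
                contig_id=run[0].contig_id,
                strand=run[0].strand,
                member_gene_ids=members,
            )
        )
    return operons


def write_operons(operons: list[Operon], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "operon_id": op.operon_id,
                "contig_id": op.contig_id,
                "strand": op.strand,
                "members": ",".join(op.member_gene_ids),
                "anchor": op.anchor_gene_id,
            }
            for op in operons
        ]
    ).to_csv(path, sep="\t", index=False)
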