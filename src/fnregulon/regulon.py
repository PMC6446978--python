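"""Multi-genome regulon conservation: which gene families carry the motif
in which genomes, filtered to well-supported families.

Each (genome, family) cell takes exactly one of three states: the genome
lacks the family entirely (ABSENT), possesses it without an upstream motif
hit (PRESENT_NO_MOTIF), or possesses it with a hit (PRESENT_WITH_MOTIF).
Orthology (the gene -> family mapping) is an input, never inferred here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GenomeRecord
from .operons import Operon

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


class ConservationState(IntEnum):
    ABSENT = 0
    PRESENT_NO_MOTIF = 1
    PRESENT_WITH_MOTIF = 2


@dataclass
class ConservationMatrix:
    """genomes x families table of ConservationState values."""

    states: pd.DataFrame  # index: genome_ids, columns: family_ids, int cells

    @property
    def genome_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.states.columns)

    def motif_support(self) -> pd.Series:
        """Per family, the number of genomes in the PRESENT_WITH_MOTIF state."""
        return (self.states == ConservationState.PRESENT_WITH_MOTIF).sum(axis=0)


def build_conservation_matrix(
    hits_by_genome: Mapping[str, Iterable[str]],
    genomes: Mapping[str, GenomeRecord],
    family_map: Mapping[str, str],
    operons_by_genome: Mapping[str, Sequence[Operon]] | None = None,
) -> ConservationMatrix:
    """Classify every (genome, family) pair into the three-state scheme.

    ``hits_by_genome`` lists, per genome, the anchor gene ids whose promoter
    carries a motif hit. When ``operons_by_genome`` is supplied a hit on an
    operon anchor counts for every member gene of that operon (operon-leader
    promoter mode); otherwise hits are per-gene. Genes with hits missing from
    ``family_map`` are bucketed under the "unassigned" family and logged.
    """
    fam_of = dict(family_map)
    hit_genes: dict[str, set[str]] = {}
    for gid, anchors in hits_by_genome.items():
        expanded: set[str] = set()
        anchor_to_members = {}
        if operons_by_genome and gid in operons_by_genome:
            anchor_to_members = {
                op.anchor_gene_id: op.member_gene_ids for op in operons_by_genome[gid]
            }
        for a in anchors:
            expanded.update(anchor_to_members.get(a, [a]))
        hit_genes[gid] = expanded

    families: set[str] = set()
    present: dict[tuple[str, str], bool] = {}
    with_motif: dict[tuple[str, str], bool] = {}
    for gid, genome in genomes.items():
        hits = hit_genes.get(gid, set())
        for gene in genome.genes:
            fam = fam_of.get(gene.gene_id)
            if fam is None:
                if gene.gene_id in hits:
                    logger.warning(
                        "gene %s has a motif hit but no family assignment; "
                        "bucketed as %r", gene.gene_id, UNASSIGNED,
                    )
                    fam = UNASSIGNED
                else:
                    continue
            families.add(fam)
            present[(gid, fam)] = True
            if gene.gene_id in hits:
                with_motif[(gid, fam)] = True

    fam_order = sorted(families)
    gen_order = list(genomes)
    df = pd.DataFrame(
        int(ConservationState.ABSENT), index=gen_order, columns=fam_order, dtype=int
    )
    for (gid, fam), _ in present.items():
        df.loc[gid, fam] = int(
            ConservationState.PRESENT_WITH_MOTIF
            if with_motif.get((gid, fam))
            else ConservationState.PRESENT_NO_MOTIF
        )
    return ConservationMatrix(df)


def filter_by_support(
    matrix: ConservationMatrix, min_genomes: int = 4
) -> ConservationMatrix:
    """Keep only families whose motif appears in at least ``min_genomes``
    genomes (default 4)."""
    if min_genomes < 1:
        raise ValueError("min_genomes must be >= 1")
    keep = matrix.motif_support() >= min_genomes
    return ConservationMatrix(matrix.states.loc[:, keep[keep].index])


def summarize_categories(
    retained_families: Iterable[str], category_map: Mapping[str, str]
) -> pd.Series:
    """Tally retained families per functional category (e.g. KEGG class);
    families without a mapping count under "unassigned"."""
    cats = [category_map.get(f, UNASSIGNED) for f in retained_families]
    return pd.Series(cats, dtype="object").value_counts().sort_index()


def write_conservation(matrix: ConservationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# conservation states: 0=absent, 1=present_no_motif, "
                 "2=present_with_motif\n")
        matrix.states.to_csv(fh, sep="\t", index_label="genome_id")


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
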