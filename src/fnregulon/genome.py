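"""Genome sequence/annotation I/O and promoter extraction.

Coordinates follow the GFF3 dialect externally (1-based, inclusive on both
ends); all internal slice arithmetic is 0-based half-open, converted only at
the I/O boundary. A "promoter" here is the strictly intergenic sequence
immediately upstream of a gene's annotated coding start (no TSS mapping is
attempted), capped at a configurable window (default 300 bp) and truncated at
the nearest annotated feature boundary on either strand and at the contig
edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_WINDOW = 300

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with 1-based inclusive coordinates on a contig."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """Contigs plus genes sorted by (contig_id, start)."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start, g.end))
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._by_id[g.gene_id] = g
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds contig "
                    f"{g.contig_id} length {len(self.contigs[g.contig_id])}"
                )

    def gene(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome_id}")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_on(self, contig_id: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.contig_id == contig_id]


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream intergenic sequence, oriented 5'->3' relative to its anchor.

    ``start``/``end`` are 1-based inclusive forward-contig coordinates of the
    (possibly empty) region; for an empty promoter start > end and
    ``sequence`` is "".
    """

    anchor_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    window_bp: int = DEFAULT_PROMOTER_WINDOW

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (case-insensitive input,
    upper-case output). Applying twice returns the input."""
    s = seq.upper()
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"cannot reverse-complement letters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    genome_id: str | None = None,
    feature_types: Sequence[str] = ("gene", "CDS"),
    id_attribute: str = "ID",
) -> GenomeRecord:
    """Load contigs from FASTA and gene annotations from GFF3.

    Features of the first type in ``feature_types`` that is present are used
    (so a file annotated only with CDS records still loads). Sequences are
    upper-cased; non-ACGT letters are preserved but flagged with a warning.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        odd = set(seq) - set("ACGT")
        if odd:
            logger.warning(
                "contig %s contains non-ACGT letters %s", rec.id, sorted(odd)
            )
        contigs[rec.id] = seq

    genes: list[GeneAnnotation] = []
    used_type = None
    try:
        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        feats = []
    else:
        for ftype in feature_types:
            feats = list(db.features_of_type(ftype))
            if feats:
                used_type = ftype
                break
        else:
            feats = []
    if not feats:
        logger.warning("no %s features found in %s", "/".join(feature_types), gff_path)
    for i, feat in enumerate(feats):
        gid = feat.attributes.get(id_attribute, [f"{used_type}_{i + 1}"])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {gid}: unknown strand symbol {feat.strand!r}")
        product = feat.attributes.get("product", [None])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gid, contig_id=feat.seqid, start=feat.start,
                end=feat.end, strand=feat.strand, product=product,
            )
        )
    return GenomeRecord(
        genome_id=genome_id or fasta_path.stem, contigs=contigs, genes=genes
    )


def write_genome(
    genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write contigs as wrapped FASTA and genes as GFF3 (feature type 'gene')."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tfnregulon\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def extract_promoter(
    genome: GenomeRecord,
    anchor_gene: str,
    window_bp: int = DEFAULT_PROMOTER_WINDOW,
) -> PromoterRegion:
    """Up to ``window_bp`` bases of intergenic sequence immediately upstream of
    the anchor gene's 5' end, truncated at the nearest annotated feature on
    either strand and at the contig edge. May be empty (overlapping upstream
    gene, or anchor at the contig edge)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    anchor = genome.gene(anchor_gene)
    contig = genome.contigs[anchor.contig_id]
    others = [
        g for g in genome.genes_on(anchor.contig_id) if g.gene_id != anchor.gene_id
    ]

    if anchor.strand == "+":
        lo = max(1, anchor.start - window_bp)
        hi = anchor.start - 1
        # take the maximal gene-free run ending immediately before the anchor
        for g in others:
            if g.start <= hi and g.end >= lo:
                lo = max(lo, g.end + 1)
        if lo > hi:
            return PromoterRegion(anchor.gene_id, anchor.contig_id, 1, 0, "+", "", window_bp)
        seq = contig[lo - 1 : hi]
        return PromoterRegion(anchor.gene_id, anchor.contig_id, lo, hi, "+", seq, window_bp)

    lo = anchor.end + 1
    hi = min(len(contig), anchor.end + window_bp)
    for g in others:
        if g.start <= hi and g.end >= lo:
            hi = min(hi, g.start - 1)
    if lo > hi:
        return PromoterRegion(anchor.gene_id, anchor.contig_id, 1, 0, "-", "", window_bp)
    seq = reverse_complement(contig[lo - 1 : hi])
    return PromoterRegion(anchor.gene_id, anchor.contig_id, lo, hi, "-", seq, window_bp)


def extract_promoters(
    genome: GenomeRecord,
    anchor_ids: Iterable[str] | None = None,
    window_bp: int = DEFAULT_PROMOTER_WINDOW,
    drop_empty: bool = True,
) -> list[PromoterRegion]:
    """Promoters for the given anchors (default: every gene). Empty promoters
    (fully overlapped upstream) are dropped with a warning unless requested."""
    ids = list(anchor_ids) if anchor_ids is not None else genome.gene_ids
    out = []
    for gid in ids:
        p = extract_promoter(genome, gid, window_bp)
        if len(p) == 0 and drop_empty:
            logger.warning("gene %s has an empty promoter; excluded", gid)
            continue
        out.append(p)
    return out
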