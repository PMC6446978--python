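"""Synthetic study generator with known ground truth.

Emulates the experimental design the pipeline targets: a small set of
related genomes sharing orthologous gene families laid out in operons; a
planted oxygen-regulon whose operon promoters carry an FNR-box-like motif
at controlled information content and occupancy; a six-timepoint
anaerobic/microaerobic expression series in which positively regulated
genes are induced under low oxygen and negatively regulated genes under
high oxygen, with negative-binomial count noise and per-sample library
factors; and noisy qPCR copy-number series for selected genes.

Every generator is a pure function of (scenario, seed): random streams are
derived per component (families / layout / sequence / planting / counts /
qPCR) so changing one knob does not reshuffle unrelated outputs.

What this emulates and what it does not: counts are NB around smooth
per-operon temporal profiles (no batch structure, no rRNA carryover, no
mapping ambiguity), sequences are 0-order background (no codon structure),
and orthology is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import LibraryFactors
from .genome import GenomeRecord, GeneAnnotation, PromoterRegion, extract_promoter, \
    reverse_complement
from .motifs import BASES, PWM, Background
from .qpcr import QpcrSeries

# stream ids for per-component RNGs
_STREAM_FAMILIES, _STREAM_LAYOUT, _STREAM_SEQUENCE = 0, 1, 2
_STREAM_PLANT, _STREAM_COUNTS, _STREAM_QPCR = 3, 4, 5


@dataclass(frozen=True)
class SyntheticScenario:
    """Default values reproduce the study design: 6 timepoints spanning an
    anaerobic-then-microaerobic cycle, 4-fold induction of the planted
    regulon, ~48-50% of the library mapping to the target genome, a 14-bp
    planted motif at 1.5 bits/column and 80% promoter occupancy."""

    seed: int = 0
    n_genomes: int = 8
    n_families: int = 60
    n_positive: int = 10
    n_negative: int = 6
    operon_size_probs: tuple[float, ...] = (0.55, 0.20, 0.15, 0.10)
    gene_length_range: tuple[int, int] = (600, 1500)
    intra_operon_gap_range: tuple[int, int] = (0, 200)
    inter_operon_gap_range: tuple[int, int] = (100, 1500)
    regulon_gap_range: tuple[int, int] = (250, 800)
    strand_probability: float = 0.5
    family_dropout: float = 0.1
    background_composition: tuple[float, float, float, float] = (
        0.19, 0.31, 0.31, 0.19)  # GC-rich, Accumulibacter-like
    motif_consensus: str = "TTGATCTAGATCAA"
    motif_ic_bits_per_column: float = 1.5
    occupancy: float = 0.8
    timepoints: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")
    phase_labels: tuple[str, ...] = (
        "anaerobic", "anaerobic",
        "microaerobic", "microaerobic", "microaerobic", "microaerobic")
    induction_fold: float = 4.0
    dispersion: float = 0.05
    baseline_log2_rpkm: tuple[float, float] = (6.0, 1.0)  # mean, sd
    temporal_sd: float = 1.0
    member_jitter_sd: float = 0.05
    merged_filtered_range: tuple[int, int] = (1_500_000, 2_500_000)
    mapped_fraction_range: tuple[float, float] = (0.48, 0.50)
    unmerged_ratio: float = 2.2
    qpcr_noise_cv: float = 0.1
    qpcr_base_copies: float = 1e4

    def __post_init__(self) -> None:
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background_composition must sum to 1")
        if len(self.timepoints) != len(self.phase_labels):
            raise ValueError("one phase label per timepoint")
        if self.n_positive + self.n_negative > self.n_families:
            raise ValueError("regulon larger than the family set")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated genome."""

    genome_id: str
    operons: list[list[str]] = field(default_factory=list)  # transcription order
    operon_strands: list[str] = field(default_factory=list)
    operon_family: list[str] = field(default_factory=list)
    family_of: dict[str, str] = field(default_factory=dict)  # gene -> family
    sign_of_family: dict[str, str] = field(default_factory=dict)
    planted_sites: dict[str, tuple[int, str]] = field(default_factory=dict)
    true_log2: pd.DataFrame | None = None

    def sign_of_gene(self, gene_id: str) -> str:
        return self.sign_of_family.get(self.family_of.get(gene_id, ""), "none")

    @property
    def regulon_genes(self) -> list[str]:
        return [g for g in self.family_of
                if self.sign_of_gene(g) in ("positive", "negative")]


def _rng(scenario: SyntheticScenario, stream: int, index: int = 0):
    return np.random.default_rng([scenario.seed & 0x7FFFFFFF, stream, index])


# ------------------------------------------------------------- planted PWM

def match_probability_for_ic(ic_bits: float) -> float:
    """Consensus-base probability p (off-bases (1-p)/3 each) achieving the
    requested per-column information content against a uniform background.
    Solved by bisection on the monotone branch p in [0.25, 1)."""
    if not 0.0 <= ic_bits < 2.0:
        raise ValueError("per-column IC must be in [0, 2) bits")

    def ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        out = p * np.log2(4.0 * p) if p > 0 else 0.0
        if q > 0:
            out += 3.0 * q * np.log2(4.0 * q)
        return out

    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ic(mid) < ic_bits:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def planted_pwm(scenario: SyntheticScenario) -> PWM:
    """PWM implied by the scenario's consensus and per-column IC."""
    p = match_probability_for_ic(scenario.motif_ic_bits_per_column)
    q = (1.0 - p) / 3.0
    mat = np.full((len(scenario.motif_consensus), 4), q)
    for j, b in enumerate(scenario.motif_consensus):
        mat[j, BASES.index(b)] = p
    return PWM(mat)


# ------------------------------------------------------------ genome layout

def generate_background(length: int, composition: Sequence[float], seed) -> str:
    """iid nucleotide string; ``seed`` may be an int or a Generator."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if length == 0:
        return ""
    draws = rng.choice(4, size=length, p=np.asarray(composition, dtype=float))
    return "".join(BASES[i] for i in draws)


def _family_structure(scenario: SyntheticScenario):
    """Operon sizes and regulation signs per family, shared by all genomes."""
    rng = _rng(scenario, _STREAM_FAMILIES)
    sizes = rng.choice(
        np.arange(1, len(scenario.operon_size_probs) + 1),
        size=scenario.n_families, p=scenario.operon_size_probs,
    )
    order = rng.permutation(scenario.n_families)
    signs = {}
    for rank, fam_idx in enumerate(order):
        fam = f"fam{fam_idx:03d}"
        if rank < scenario.n_positive:
            signs[fam] = "positive"
        elif rank < scenario.n_positive + scenario.n_negative:
            signs[fam] = "negative"
        else:
            signs[fam] = "none"
    return sizes, signs


def generate_genome_layout(
    scenario: SyntheticScenario, genome_index: int = 0
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Lay out one genome on a single contig: operons in family order with
    gaps drawn from the scenario's distributions. Genes within a truth
    operon share strand and sit closer than the operon-caller gap default;
    regulon operons get enough upstream intergenic room to hold a promoter.
    Genome 0 (the expression/reference genome) keeps every family; other
    genomes drop families at the dropout rate.
    """
    sizes, signs = _family_structure(scenario)
    genome_id = f"genome{genome_index:02d}"
    lay = _rng(scenario, _STREAM_LAYOUT, genome_index)

    present = np.ones(scenario.n_families, dtype=bool)
    if genome_index > 0:
        present = lay.random(scenario.n_families) >= scenario.family_dropout

    truth = SyntheticTruth(genome_id=genome_id, sign_of_family=signs)
    genes: list[GeneAnnotation] = []
    pos = 1  # next unoccupied 1-based coordinate
    serial = 0
    strands = lay.random(scenario.n_families) < scenario.strand_probability
    fam_ids = [f"fam{i:03d}" for i in range(scenario.n_families)]
    for i, fam in enumerate(fam_ids):
        if not present[i]:
            continue
        strand = "+" if strands[i] else "-"
        is_regulon = signs[fam] in ("positive", "negative")
        # the promoter-side gap must fit a promoter for regulon operons:
        # it precedes a + operon and follows a - operon
        prev_reg_minus = (genes and genes[-1].strand == "-"
                          and truth.sign_of_gene(genes[-1].gene_id) != "none")
        lo, hi = (scenario.regulon_gap_range
                  if (is_regulon and strand == "+") or prev_reg_minus
                  else scenario.inter_operon_gap_range)
        pos += int(lay.integers(lo, hi + 1))
        members: list[str] = []
        for k in range(sizes[i]):
            if k > 0:
                glo, ghi = scenario.intra_operon_gap_range
                pos += int(lay.integers(glo, ghi + 1))
            length = int(lay.integers(*scenario.gene_length_range))
            serial += 1
            gid = f"{genome_id}_g{serial:04d}"
            genes.append(GeneAnnotation(gid, "contig_1", pos, pos + length - 1, strand))
            truth.family_of[gid] = fam
            members.append(gid)
            pos = pos + length
        if strand == "-":
            members = members[::-1]
        truth.operons.append(members)
        truth.operon_strands.append(strand)
        truth.operon_family.append(fam)

    contig_len = (genes[-1].end if genes else 0) + scenario.regulon_gap_range[1]
    seq_rng = _rng(scenario, _STREAM_SEQUENCE, genome_index)
    contig = generate_background(contig_len, scenario.background_composition, seq_rng)
    genome = GenomeRecord(genome_id, {"contig_1": contig}, genes)

    genome, planted = _plant_regulon_motifs(genome, truth, scenario, genome_index)
    truth.planted_sites = planted
    return genome, truth


# ------------------------------------------------------------ motif planting

def plant_motif(
    promoters: Sequence[PromoterRegion],
    pwm: PWM,
    occupancy: float,
    seed,
) -> tuple[list[PromoterRegion], dict[str, tuple[int, str]]]:
    """Plant one PWM-sampled site into a Bernoulli(occupancy) subset of the
    promoters, at a uniform position and strand. Returns modified promoters
    plus the truth map anchor -> (offset, strand). Promoters shorter than
    the motif are skipped."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = pwm.width
    out: list[PromoterRegion] = []
    truth: dict[str, tuple[int, str]] = {}
    for prom in promoters:
        if rng.random() >= occupancy or len(prom) < w:
            out.append(prom)
            continue
        offset = int(rng.integers(0, len(prom) - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = "".join(BASES[rng.choice(4, p=pwm.matrix[j])] for j in range(w))
        insert = site if strand == "+" else reverse_complement(site)
        seq = prom.sequence[:offset] + insert + prom.sequence[offset + w:]
        out.append(PromoterRegion(prom.anchor_id, prom.contig_id, prom.start,
                                  prom.end, prom.strand, seq, prom.window_bp))
        truth[prom.anchor_id] = (offset, strand)
    return out, truth


def _apply_promoter_sequences(
    genome: GenomeRecord, promoters: Sequence[PromoterRegion]
) -> GenomeRecord:
    """Write (possibly modified) promoter sequences back into the contigs,
    honoring each promoter's strand orientation."""
    contigs = dict(genome.contigs)
    for p in promoters:
        if len(p) == 0:
            continue
        fwd = p.sequence if p.strand == "+" else reverse_complement(p.sequence)
        c = contigs[p.contig_id]
        contigs[p.contig_id] = c[: p.start - 1] + fwd + c[p.end:]
    return GenomeRecord(genome.genome_id, contigs, list(genome.genes))


def _plant_regulon_motifs(genome, truth, scenario, genome_index):
    rng = _rng(scenario, _STREAM_PLANT, genome_index)
    pwm = planted_pwm(scenario)
    anchors = [members[0] for members, fam in
               zip(truth.operons, truth.operon_family)
               if truth.sign_of_family[fam] != "none"]
    promoters = [extract_promoter(genome, a) for a in anchors]
    modified, planted = plant_motif(promoters, pwm, scenario.occupancy, rng)
    return _apply_promoter_sequences(genome, modified), planted


# ------------------------------------------------------------- expression

def simulate_expression(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    scenario: SyntheticScenario,
    genome_index: int = 0,
) -> tuple[pd.DataFrame, dict[str, LibraryFactors]]:
    """Negative-binomial counts for the six-timepoint cycle.

    Every operon carries a shared smooth random temporal profile (so
    co-members co-express whether or not they are regulated); regulon
    operons additionally gain log2(induction_fold) during their favored
    oxygen phase. Count means scale with expression, gene length, and the
    per-sample effective library size. Dispersion 0 degenerates to Poisson.
    Also fills ``truth.true_log2`` (true log2 relative expression)."""
    rng = _rng(scenario, _STREAM_COUNTS, genome_index)
    tps = list(scenario.timepoints)
    phases = np.asarray(scenario.phase_labels)
    low = phases == "anaerobic"
    n_tp = len(tps)
    mean0, sd0 = scenario.baseline_log2_rpkm
    log2_fold = np.log2(scenario.induction_fold)

    gene_ids = genome.gene_ids
    true_log2 = pd.DataFrame(0.0, index=gene_ids, columns=tps)
    for members, fam in zip(truth.operons, truth.operon_family):
        base = rng.normal(mean0, sd0)
        temporal = rng.normal(0.0, scenario.temporal_sd, size=n_tp)
        sign = truth.sign_of_family[fam]
        phase = np.zeros(n_tp)
        if sign == "positive":
            phase[low] = log2_fold
        elif sign == "negative":
            phase[~low] = log2_fold
        for gid in members:
            jitter = rng.normal(0.0, scenario.member_jitter_sd)
            true_log2.loc[gid] = base + jitter + temporal + phase

    factors: dict[str, LibraryFactors] = {}
    counts = pd.DataFrame(0, index=gene_ids, columns=tps, dtype=int)
    lengths = np.array([genome.gene(g).length_bp for g in gene_ids], dtype=float)
    for tp in tps:
        merged = int(rng.integers(*scenario.merged_filtered_range))
        mapped = float(rng.uniform(*scenario.mapped_fraction_range))
        factors[tp] = LibraryFactors(
            sample_id=tp,
            total_unmerged_reads=int(merged * scenario.unmerged_ratio),
            merged_filtered_reads=merged,
            mapped_fraction=mapped,
        )
        n_eff = merged * mapped
        mu = (2.0 ** true_log2[tp].to_numpy()) * (lengths / 1e3) * (n_eff / 1e6)
        if scenario.dispersion > 0:
            lam = rng.gamma(shape=1.0 / scenario.dispersion,
                            scale=mu * scenario.dispersion)
        else:
            lam = mu
        counts[tp] = rng.poisson(lam)
    truth.true_log2 = true_log2.sub(true_log2.min(axis=1), axis=0)
    return counts, factors


# ------------------------------------------------------------------- qPCR

def simulate_qpcr(
    true_profile: pd.Series,
    noise_cv: float,
    seed,
    gene_id: str = "target",
    base_copies: float = 1e4,
    reference_gene_id: str = "rpoN",
) -> tuple[QpcrSeries, QpcrSeries]:
    """Copy numbers proportional to 2**profile with lognormal noise of the
    given coefficient of variation, plus a constant-truth reference series
    generated the same way."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    n = len(true_profile)

    def noisy(mean_copies: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return mean_copies
        return mean_copies * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n))

    target = QpcrSeries(
        gene_id=gene_id,
        series=pd.Series(
            noisy(base_copies * 2.0 ** true_profile.to_numpy(dtype=float)),
            index=true_profile.index),
        reference_gene_id=reference_gene_id,
    )
    reference = QpcrSeries(
        gene_id=reference_gene_id,
        series=pd.Series(noisy(np.full(n, base_copies)), index=true_profile.index),
        reference_gene_id=reference_gene_id,
    )
    return target, reference


# --------------------------------------------------------------- truth I/O

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "genome_id": truth.genome_id,
        "operons": truth.operons,
        "operon_strands": truth.operon_strands,
        "operon_family": truth.operon_family,
        "family_of": truth.family_of,
        "sign_of_family": truth.sign_of_family,
        "planted_sites": {k: list(v) for k, v in truth.planted_sites.items()},
    }
    if truth.true_log2 is not None:
        payload["true_log2"] = {
            "index": list(truth.true_log2.index),
            "columns": list(truth.true_log2.columns),
            "values": truth.true_log2.round(6).to_numpy().tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def scenario_to_dict(scenario: SyntheticScenario) -> dict:
    return asdict(scenario)
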