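"""End-to-end orchestration: normalize -> operons -> promoters -> motif
discovery/scan -> regulon conservation -> clustering -> qPCR validation.

A single PipelineConfig carries every numeric parameter (defaults are the
analysis defaults used throughout: 300-bp promoter window, scan alpha 1e-5,
operon r >= 0.7 and gap <= 1,000 bp, >= 4-genome regulon support,
validation r > 0.5 and 2-fold change). With no explicit inputs the bundled
synthetic scenario is generated from the config seed, so the whole pipeline
runs from an empty directory and is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, expression, genome as genome_io, motifs, operons, qpcr, \
    regulon, synthetic

logger = logging.getLogger(__name__)

_CATEGORY_CYCLE = (
    "energy metabolism", "carbohydrate metabolism", "amino acid metabolism",
    "signal transduction", "membrane transport",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    promoter_window_bp: int = 300
    scan_alpha: float = 1e-5
    min_pearson: float = 0.7
    max_gap_bp: int = 1000
    min_genomes: int = 4
    cluster_k: int | None = 6
    cluster_cut_height: float | None = None
    linkage: str = "average"
    flat_tolerance: float = 0.5
    r_min: float = 0.5
    fc_min: float = 2.0
    motif_width: int = 14
    n_restarts: int = 5
    discovery_min_contrast: float = 1.0
    discovery_max_promoters: int = 12
    log_level: str = "INFO"
    inputs: dict | None = None  # optional paths; None -> synthetic scenario

    def __post_init__(self) -> None:
        if not 0.0 < self.scan_alpha <= 1.0:
            raise ValueError("scan_alpha must be in (0, 1]")
        if self.promoter_window_bp <= 0:
            raise ValueError("promoter_window_bp must be positive")
        if not -1.0 <= self.min_pearson <= 1.0:
            raise ValueError("min_pearson must be in [-1, 1]")
        if self.max_gap_bp < 0:
            raise ValueError("max_gap_bp must be >= 0")
        if self.min_genomes < 1:
            raise ValueError("min_genomes must be >= 1")
        if not 6 <= self.motif_width <= 30:
            raise ValueError("motif_width must be in [6, 30]")
        if self.cluster_k is not None and self.cluster_cut_height is not None:
            raise ValueError("give cluster_k or cluster_cut_height, not both")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    seed: int
    parameters: dict
    stage_counts: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def default_category_map(family_ids) -> dict[str, str]:
    """Deterministic family -> functional-category assignment for synthetic
    runs (a stand-in for an externally supplied KEGG-style mapping)."""
    return {f: _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
            for i, f in enumerate(sorted(family_ids))}


def run_all(config: PipelineConfig, out_dir: str | Path,
            scenario: synthetic.SyntheticScenario | None = None) -> RunReport:
    """Execute every stage, writing per-stage TSV outputs plus report.json
    under ``out_dir``. Deterministic given (config, scenario)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, parameters={
        k: v for k, v in dataclasses.asdict(config).items() if k != "inputs"})

    def emit(path: Path) -> Path:
        report.outputs.append(str(path.relative_to(out)))
        return path

    # ---- stage: inputs (simulate or load) --------------------------------
    if config.inputs is None:
        scenario = scenario or synthetic.SyntheticScenario(seed=config.seed)
        genomes, truths = {}, {}
        for i in range(scenario.n_genomes):
            g, t = synthetic.generate_genome_layout(scenario, i)
            genomes[g.genome_id] = g
            truths[g.genome_id] = t
        ref_id = "genome00"
        counts, factors = synthetic.simulate_expression(
            genomes[ref_id], truths[ref_id], scenario, 0)
        family_map = {g: f for t in truths.values() for g, f in t.family_of.items()}
        category_map = default_category_map(set(family_map.values()))
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        for gid, g in genomes.items():
            genome_io.write_genome(g, emit(inputs_dir / f"{gid}.fasta"),
                                   emit(inputs_dir / f"{gid}.gff"))
        counts.to_csv(emit(inputs_dir / "counts.tsv"), sep="\t",
                      index_label="gene_id")
        expression.write_factors(factors, emit(inputs_dir / "factors.tsv"))
        pd.DataFrame(sorted(family_map.items()),
                     columns=["gene_id", "family_id"]).to_csv(
            emit(inputs_dir / "family_map.tsv"), sep="\t", index=False)
        synthetic.write_truth(truths[ref_id], emit(inputs_dir / "truth.json"))
        # reload through the pipeline's own readers (round-trip guarantee)
        counts = expression.read_counts(inputs_dir / "counts.tsv")
        factors = expression.read_factors(inputs_dir / "factors.tsv")
    else:
        inp = config.inputs
        genomes = {}
        for spec_g in inp["genomes"]:
            g = genome_io.read_genome(spec_g["fasta"], spec_g["gff"],
                                      genome_id=spec_g.get("genome_id"))
            genomes[g.genome_id] = g
        ref_id = inp.get("reference_genome", next(iter(genomes)))
        counts = expression.read_counts(inp["counts"])
        factors = expression.read_factors(inp["factors"])
        family_map = regulon.read_family_map(inp["family_map"])
        category_map = (regulon.read_family_map(inp["category_map"])
                        if inp.get("category_map") else {})
        truths = None
        scenario = None
    report.stage_counts["genomes"] = len(genomes)

    # ---- stage: normalize ------------------------------------------------
    ref = genomes[ref_id]
    lengths = pd.Series({g.gene_id: g.length_bp for g in ref.genes})
    expr = expression.compute_log2_rpkm(counts, factors, lengths)
    profiles = expression.relative_to_min(expr)
    expression.write_expression(expr, emit(out / "log2_rpkm.tsv"))
    expression.write_expression(profiles, emit(out / "relative_profiles.tsv"))
    report.stage_counts["expressed_genes"] = len(expr)

    # ---- stage: operons --------------------------------------------------
    op_cfg = operons.OperonConfig(min_pearson=config.min_pearson,
                                  max_gap_bp=config.max_gap_bp)
    called = operons.call_operons(ref, profiles, op_cfg)
    operons.write_operons(called, emit(out / "operons.tsv"))
    report.stage_counts["operons"] = len(called)

    # ---- stage: promoters ------------------------------------------------
    promoters_by_genome = {
        gid: genome_io.extract_promoters(g, window_bp=config.promoter_window_bp)
        for gid, g in genomes.items()
    }
    report.stage_counts["promoters"] = sum(map(len, promoters_by_genome.values()))

    # ---- stage: discover -------------------------------------------------
    # seed set: operon-leader promoters of the most oxygen-contrasted
    # transcription units in the reference genome (the respiratory-operon
    # analogue of a curated seed list)
    phases = np.asarray(scenario.phase_labels) if scenario is not None else \
        np.asarray(config.inputs.get("phase_labels", []))
    low = phases == "anaerobic"
    contrasts = profiles.loc[:, low].mean(axis=1) - profiles.loc[:, ~low].mean(axis=1)
    seed_anchors = []
    for op in called:
        c = contrasts.reindex(op.member_gene_ids).mean()
        if abs(c) >= config.discovery_min_contrast:
            seed_anchors.append((abs(c), op.anchor_gene_id))
    seed_anchors = [a for _, a in sorted(seed_anchors, reverse=True)
                    [: config.discovery_max_promoters]]
    seed_proms = [p for p in promoters_by_genome[ref_id]
                  if p.anchor_id in set(seed_anchors)
                  and len(p) >= config.motif_width]
    background = motifs.Background.from_sequences(
        p.sequence for p in promoters_by_genome[ref_id])
    disc = motifs.discover_motif(
        seed_proms, width=config.motif_width, n_restarts=config.n_restarts,
        seed=config.seed, background=background)
    motifs.write_meme(disc.pwm, background, emit(out / "motif.meme"),
                      n_sites=len(seed_proms))
    report.stage_counts["discovery_promoters"] = len(seed_proms)

    # ---- stage: scan -----------------------------------------------------
    hits_by_genome: dict[str, set[str]] = {}
    n_hits = 0
    for gid, proms in promoters_by_genome.items():
        hits = motifs.scan(disc.pwm, proms, background, alpha=config.scan_alpha)
        motifs.write_hits(hits, emit(out / f"hits_{gid}.tsv"),
                          width=disc.pwm.width)
        hits_by_genome[gid] = {h.anchor_id for h in hits}
        n_hits += len(hits)
    report.stage_counts["motif_hits"] = n_hits

    # ---- stage: regulon --------------------------------------------------
    matrix = regulon.build_conservation_matrix(hits_by_genome, genomes, family_map)
    retained = regulon.filter_by_support(matrix, config.min_genomes)
    regulon.write_conservation(retained, emit(out / "conservation.tsv"))
    tally = regulon.summarize_categories(retained.family_ids, category_map)
    tally.rename_axis("category").to_frame("n_families").to_csv(
        emit(out / "category_summary.tsv"), sep="\t")
    report.stage_counts["conserved_families"] = len(retained.family_ids)

    # ---- stage: cluster --------------------------------------------------
    hit_genes = sorted(hits_by_genome.get(ref_id, set()) & set(profiles.index))
    if len(hit_genes) >= 2 and len(phases):
        sub = profiles.loc[hit_genes]
        k = config.cluster_k
        if k is not None:
            k = min(k, max(2, (sub.var(axis=1) > 0).sum()))
        assign = clustering.cluster_profiles(
            sub, k=k, cut_height=config.cluster_cut_height,
            linkage_method=config.linkage)
        calls = clustering.classify_regulation_sign(
            clustering.cluster_means(sub, assign), list(phases),
            tolerance=config.flat_tolerance)
        clustering.write_clusters(assign, calls, emit(out / "clusters.tsv"))
        report.stage_counts["clustered_genes"] = len(hit_genes)
    else:
        report.skipped.append("cluster")

    # ---- stage: qPCR validation -----------------------------------------
    qpcr_series = None
    if config.inputs is not None and config.inputs.get("qpcr"):
        qpcr_series = qpcr.read_qpcr_table(config.inputs["qpcr"])
    elif scenario is not None and truths is not None:
        rng = np.random.default_rng([scenario.seed & 0x7FFFFFFF, 99])
        truth = truths[ref_id]
        chosen = [g for g in truth.regulon_genes if g in profiles.index][:5]
        qpcr_series = {}
        for g in chosen:
            target, refseries = synthetic.simulate_qpcr(
                truth.true_log2.loc[g], scenario.qpcr_noise_cv, rng, gene_id=g)
            qpcr_series[g] = target
            qpcr_series.setdefault("__reference__" + g, refseries)
    if qpcr_series:
        results = []
        for g, series in qpcr_series.items():
            if g.startswith("__reference__") or g not in profiles.index:
                continue
            refseries = qpcr_series.get("__reference__" + g)
            if refseries is None:
                continue
            ratio = qpcr.normalize_to_reference(series, refseries)
            norm = qpcr.relative_to_min_copies(ratio)
            results.append(qpcr.validate(
                norm, profiles.loc[g].set_axis(norm.index), gene_id=g,
                r_min=config.r_min, fc_min=config.fc_min))
        qpcr.write_validation(results, emit(out / "qpcr_validation.tsv"))
        report.stage_counts["qpcr_validated"] = sum(
            r.verdict == "validated" for r in results)
    else:
        report.skipped.append("qpcr_validation")

    report.outputs.append("report.json")
    report.save(out / "report.json")
    for rel in report.outputs:
        if not (out / rel).exists():
            raise RuntimeError(f"stage output missing: {rel}")
    return report
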