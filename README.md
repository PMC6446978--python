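# fnregulon

Inference of an oxygen-responsive (FNR-type) regulon in bacteria from
time-series bulk RNA-seq, comparative genomics, and RT-qPCR — built around
the analysis used to show that the polyphosphate-accumulating organism
*"Ca.* Accumulibacter phosphatis*"* co-respires oxygen and nitrate during
anaerobic/microaerobic reactor cycles.

FNR (fumarate and nitrate reduction regulator) is a CRP-family
transcription factor that is active under anoxia and inactivated by
oxygen. Genes it controls carry a palindromic binding site (an "FNR box")
in their promoters and swing in expression with oxygen tension. The
package reconstructs such a regulon end to end:

1. **Normalization** — gene counts become log2 RPKM with
   `RPKM = (count + 1) · 10⁹ / (L · N_eff)`, where `L` is gene length (bp)
   and `N_eff = merged_filtered_reads × mapped_fraction` is the effective
   per-sample library size; profiles are reported as Δlog2 RPKM relative to
   each gene's cycle minimum.
2. **Operon calling** — adjacent genes merge into one transcription unit
   when they share a strand, sit ≤ 1,000 bp apart, and co-express with
   Pearson r ≥ 0.7.
3. **Motif discovery and scanning** — a ZOOPS (zero-or-one occurrence per
   sequence) expectation–maximization learns a PWM from operon-leader
   promoters; promoters (≤ 300 bp of upstream intergenic sequence) are then
   scanned on both strands, calling hits at exact null p-values ≤ 10⁻⁵
   computed by dynamic programming over the discretized log-odds score.
4. **Regulon conservation** — per (genome, gene family) the matrix records
   absent / present-without-motif / present-with-motif, keeping families
   supported in ≥ 4 genomes.
5. **Clustering and sign calls** — hit-gene profiles cluster under the
   1 − Pearson distance; each cluster is called positively regulated
   (induced under low oxygen), negatively regulated, or flat from its
   anaerobic-vs-microaerobic contrast.
6. **RT-qPCR cross-validation** — copy numbers normalized to the *rpoN*
   reference validate an RNA-seq profile when r > 0.5, with a fold-change
   < 2 exemption for genes that never move.

A synthetic-study generator (`fnregulon.synthetic`) produces genomes with
planted operons, promoters with a planted FNR-box-like motif at controlled
information content and occupancy, negative-binomial six-timepoint count
series, and noisy qPCR series — with full ground truth, so every stage is
testable without any external download.

## Worked example

```python
import pandas as pd
from fnregulon import (SyntheticScenario, generate_genome_layout,
                       simulate_expression, compute_log2_rpkm,
                       relative_to_min, call_operons, OperonConfig,
                       extract_promoters, discover_motif, scan, Background)

sc = SyntheticScenario(seed=3)
genome, truth = generate_genome_layout(sc, 0)
counts, factors = simulate_expression(genome, truth, sc, 0)
lengths = pd.Series({g.gene_id: g.length_bp for g in genome.genes})
profiles = relative_to_min(compute_log2_rpkm(counts, factors, lengths))

operons = call_operons(genome, profiles, OperonConfig())
print(len(genome.genes), "genes in", len(operons), "operons")

promoters = extract_promoters(genome)
seed_proms = [p for p in promoters if p.anchor_id in truth.planted_sites]
result = discover_motif(seed_proms, width=14, n_restarts=5, seed=3)
print("discovered consensus:", result.pwm.consensus)

hits = scan(result.pwm, promoters, alpha=1e-5)
print(len(hits), "promoter hits on", len({h.anchor_id for h in hits}), "genes")
```

prints

```
104 genes in 64 operons
discovered consensus: TTGATCTAGATCAA
36 promoter hits on 19 genes
```

The 104 genes were laid out in 60 true operons (the caller reports 64
because count noise occasionally splits a unit); EM recovered the planted
consensus exactly, and scanning at p ≤ 10⁻⁵ flagged 19 gene promoters —
the 14 planted sites plus their palindrome-mirror strand duplicates and a
few operon-internal genes.

The same flow is available from the shell:

```bash
fnregulon run-all --seed 3 --out-dir results/run3
```

which writes per-stage TSVs (`log2_rpkm.tsv`, `operons.tsv`, `motif.meme`,
`hits_<genome>.tsv`, `conservation.tsv`, `clusters.tsv`,
`qpcr_validation.tsv`) and a `report.json` manifest.

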