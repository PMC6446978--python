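# Methods

This note documents the models, parameter choices, and numerical decisions
behind `fnregulon`, and what the synthetic-study tests do and do not show
about real data.

## Normalization model

Counts are converted to reads per kilobase per million *effective* library
reads:

    RPKM_gs = (c_gs + ε) · 10⁹ / (L_g · N_eff,s),    value = log2 RPKM

with gene length `L_g` in bp and `N_eff,s = merged_filtered_reads_s ×
mapped_fraction_s`. Three library quantities are tracked per sample: the
total unmerged read count of the run, the merged read count surviving rRNA
filtering, and the fraction of merged reads mapping to the target genome.
Only the product of the last two enters the per-value formula — that is
the only combination with units of "per million reads attributable to this
genome" — while the total unmerged count is carried as provenance metadata
(`DataFrame.attrs`) for cross-run reporting. The pseudocount ε defaults to
1 read so zero counts stay finite; it is configurable and its value only
shifts low-count genes.

Relative profiles subtract each gene's minimum over the cycle (Δlog2
RPKM), so the per-gene minimum is exactly 0. Pearson correlation is
invariant to that shift, so operon calling is identical on raw or relative
profiles.

Degenerate inputs: a constant series has no defined correlation; `pearson`
returns NaN as an explicit "undefined" sentinel rather than 0, and every
caller treats undefined as failing its threshold.

## Operon model

Adjacent genes on one contig merge into a transcription unit when they
share a strand, their intergenic gap (`start₂ − end₁ − 1`, negative for
overlapping genes) is at most 1,000 bp, and their profiles correlate at
r ≥ 0.7. Chaining is adjacent-pair (transitive), the common convention for
distance/co-expression operon callers; a strict all-pairs mode is
available behind `OperonConfig(all_pairs=True)`. The 5′-most member is the
operon anchor and owns the promoter. The caller is validated against an
independent connected-components oracle on random synthetic layouts.

## Promoters

A promoter is up to 300 bp of strictly intergenic sequence immediately
upstream of the annotated coding start (no TSS mapping is attempted),
truncated at the nearest annotated feature boundary on either strand and
at the contig edge, reverse-complemented for minus-strand anchors.
Coordinates are 1-based inclusive at the file boundary (GFF3 dialect) and
0-based half-open internally; the conversion happens only at I/O. Genes
whose upstream neighbour overlaps their start get an empty promoter and
are excluded from scanning with a logged warning — not an error, since
overlapping annotations are routine in bacterial drafts.

## Motif scanning with exact p-values

Windows are scored as log2-odds sums against a 0-order background
(estimated from the scanned promoter set by default; uniform by flag). The
null distribution of the score is computed exactly by dynamic programming
over integer-discretized per-column scores at 1,000 steps per bit — the
discretization is the sole approximation, and scanner and null use the
same integer grid, so reported p-values are exact for the discretized
score. Hits are reported wherever `P(score ≥ s) ≤ α` (default 10⁻⁵) on
either strand; the p-value is per-strand (no two-strand doubling), and no
multiple-testing correction is applied, matching standard raw-threshold
promoter scans. Windows containing ambiguous bases are skipped. Zero
columns in a pseudocount-free PWM are floored far below any passing score
so the tail of the null is unaffected.

## ZOOPS-EM motif discovery

The discovery model is zero-or-one occurrence per sequence over both
strands: with probability γ a sequence carries one site at a uniformly
chosen position/strand, else it is pure background. The E-step computes
per-sequence posteriors over all windows plus the no-site option; the
M-step re-estimates the PWM (with a Dirichlet prior of weight 0.25
proportional to the background) and γ. The recorded iteration trace is the
penalized (MAP) log-likelihood, which EM increases monotonically — the
property tests assert this exactly.

Two search heuristics matter in practice, both in the spirit of MEME:

- **Substring seeding.** Random restarts almost never initialize near a
  true site, so ~40 candidate k-mer initializations are screened with two
  EM iterations each and full EM runs only from the top `n_restarts`.
- **Phase refinement.** A model offset by one or two columns from the true
  register is a local optimum; after convergence the model is re-seeded at
  ±1/±2 column shifts and the hill-climb repeats while the objective
  improves.

The motif width defaults to 14 (configurable 6–30); it is the width of the
synthetic FNR-box scenario, not a claim about any particular organism's
site. Occupancy is initialized at 0.5 and clamped to (10⁻⁶, 1 − 10⁻⁶).
Non-convergence within 200 iterations returns the best model with a
warning flag.

**Known limitation.** When the discovery set is heavily diluted (under
roughly 40% of sequences carrying a site in 300-bp GC-rich promoters), a
low-information pattern present in *every* sequence can genuinely exceed
the planted motif's ZOOPS likelihood — this was verified by initializing
EM at the true model and comparing objectives. In the full pipeline the
≥ 4-genome conservation filter is the safeguard: a spurious motif does not
replicate across genomes and yields an empty conserved regulon rather
than a wrong one.

## Regulon conservation

Orthology is an input mapping (gene → family), never inferred. Each
(genome, family) cell takes exactly one state: absent, present without
motif, or present with motif (encoded 0/1/2 in the TSV). Families are
retained when the motif appears in ≥ 4 genomes. Hits on genes missing from
the family map are bucketed as "unassigned" and logged. Functional-category
tallies likewise consume an external family → category mapping.

## Clustering and sign calls

Profiles cluster agglomeratively (average linkage by default) under the
correlation distance 1 − r, with a user-supplied cluster count or cut
height — the published six clusters are an observed outcome, not a
parameter, so no automatic model selection is performed. Constant profiles
cannot be placed under a correlation distance and go to a dedicated flat
cluster (label 0). Labels are renumbered in order of first appearance so
the partition is deterministic and invariant to input order. Each
cluster's mean profile is contrasted as mean(anaerobic timepoints) −
mean(microaerobic timepoints); |contrast| below 0.5 Δlog2 RPKM is called
flat (the threshold echoes the "no notable change" criterion of < 1 Δlog2
used for flat genes, at half that span), otherwise the sign gives
positive (FNR-activated) or negative regulation.

## qPCR validation

Target copy numbers are divided by the reference-gene series (*rpoN* by
convention — a constitutively expressed sigma-factor gene), then by the
cycle minimum. A gene validates its RNA-seq profile when the Pearson
correlation between log2-normalized qPCR and Δlog2 RPKM exceeds 0.5 and
the qPCR fold change is ≥ 2; series with fold change < 2 are classed
"no significant change" and exempt from the correlation judgement (the
behaviour observed for *norZ*-like flat genes). The verdict is invariant
to multiplicative rescaling of the copy numbers. The no-RT control check
reports the mean CT difference (NRTC − cDNA) and raises an advisory flag
below 5 cycles (a 10-cycle difference ≈ 1,000-fold template excess is
comfortably clean).

Amplicon lengths use the convention `reverse_end − forward_start` — the
coordinate dialect under which each primer's printed span equals its
length. Five of the seven bundled respiratory-gene primer rows are
internally consistent under it; the *narG* (computed 88 vs declared 91)
and *rpoN* (458 vs 487) rows are contradictory in the source table itself,
so they are flagged as mismatches and never silently corrected.

## Synthetic study generator

The generator emulates the study design rather than any particular
dataset. Defaults (all configurable through `SyntheticScenario`):

| parameter | default | rationale |
|---|---|---|
| genomes | 8 | a small related-genome panel for conservation |
| families / genome | 60 operons (sizes 1–4, mean ≈ 1.8) | tractable desk-scale genome (~110 genes) |
| regulon | 10 positive + 6 negative families | both FNR-activated and FNR-repressed classes |
| timepoints | 6 (2 anaerobic + 4 microaerobic) | the cycle's sampling scheme |
| induction fold | 4 | strong but not caricatured phase response |
| count noise | negative binomial, dispersion 0.05 | overdispersed counts; 0 degenerates to Poisson |
| per-operon temporal wander | σ = 1.0 log2 | see below |
| background | A/T 0.19, C/G 0.31 | GC-rich genome like the target organism |
| motif | 14-bp palindromic consensus, 1.5 bits/column | FNR-box-like dyad; IC sets site degeneracy |
| occupancy | 0.8 | sites present in most but not all regulon promoters |
| mapped fraction | 0.48–0.50 | the genome's typical share of a metatranscriptome |
| qPCR noise | lognormal, CV 0.1 | triplicate-quality quantification |

Every operon — regulated or not — carries a shared random temporal profile
(iid N(0, 1) per timepoint in log2, shared by co-members) so that
co-expression-based operon calling has signal genome-wide, as it does in
real transcriptomes where most operons move for reasons other than the
factor under study. The amplitude is a compromise: larger wander
strengthens co-member correlation against the count-noise floor
(≈ 0.32 log2 at dispersion 0.05) but injects phase-contrast noise into
sign classification. At σ = 1.0, ~90% of adjacent co-member pairs reach
r ≥ 0.7 (median ≈ 0.8) and ~96% of regulated genes get the correct sign —
both asserted distributionally in the tests; a literal all-pairs r ≥ 0.7
is not achievable with six-point sample correlations at this dispersion.

Random streams are derived per component (family structure, layout,
sequence, planting, counts, qPCR) from the scenario seed, so changing one
knob never reshuffles unrelated outputs, and every generator is a pure
function of (scenario, seed).

What passing tests do **not** show about real data: sequences are 0-order
background (no codon or regulatory structure beyond the planted site),
orthology is exact, there is no batch structure, mapping ambiguity, rRNA
carryover, or annotation error, and the expression model has no
growth-phase confounding. Results on real metatranscriptomes will be
noisier in all of these directions.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
genomes of ~110 genes, 20–25 promoters per discovery/scanning experiment,
20 seeded replicates for stochastic properties, 100 layouts for the operon
oracle, and exhaustive enumeration up to width 6 for p-value exactness.
These sizes give the statistical assertions comfortable margins while the
whole suite runs in about a minute.
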