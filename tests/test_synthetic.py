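"""Ground-truth generators: determinism, construction guarantees, and
statistical behavior of the emulated study."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from fnregulon import (
    SyntheticScenario, compute_log2_rpkm, generate_background,
    generate_genome_layout, pearson, planted_pwm, plant_motif,
    relative_to_min, simulate_expression, simulate_qpcr, validate,
    PromoterRegion,
)
from fnregulon.operons import intergenic_gap
from fnregulon.synthetic import match_probability_for_ic


def _profiles(scenario, genome, truth, index=0):
    counts, factors = simulate_expression(genome, truth, scenario, index)
    lengths = pd.Series({g.gene_id: g.length_bp for g in genome.genes})
    return relative_to_min(compute_log2_rpkm(counts, factors, lengths))


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        sc = SyntheticScenario(seed=9)
        g1, t1 = generate_genome_layout(sc, 0)
        g2, t2 = generate_genome_layout(sc, 0)
        assert g1.contigs == g2.contigs
        assert g1.genes == g2.genes
        assert t1.planted_sites == t2.planted_sites
        c1, _ = simulate_expression(g1, t1, sc, 0)
        c2, _ = simulate_expression(g2, t2, sc, 0)
        assert c1.equals(c2)

    def test_empty_genome(self):
        sc = SyntheticScenario(seed=0, n_families=0, n_positive=0,
                               n_negative=0)
        g, t = generate_genome_layout(sc, 0)
        assert g.genes == [] and t.operons == []


class TestLayoutConstruction:
    def test_truth_operons_satisfy_caller_preconditions(self):
        for seed in range(25):
            sc = SyntheticScenario(seed=seed, n_families=30)
            genome, truth = generate_genome_layout(sc, 0)
            by_id = {g.gene_id: g for g in genome.genes}
            for members, strand in zip(truth.operons, truth.operon_strands):
                genes = sorted((by_id[m] for m in members),
                               key=lambda g: g.start)
                assert all(g.strand == strand for g in genes)
                for a, b in zip(genes, genes[1:]):
                    assert intergenic_gap(a, b) <= 1000

    def test_planted_sites_lie_in_regulon_promoters(self):
        sc = SyntheticScenario(seed=3)
        genome, truth = generate_genome_layout(sc, 0)
        regulon_anchors = {m[0] for m, f in
                           zip(truth.operons, truth.operon_family)
                           if truth.sign_of_family[f] != "none"}
        assert set(truth.planted_sites) <= regulon_anchors


class TestBackground:
    def test_length_zero(self):
        assert generate_background(0, (0.25,) * 4, 0) == ""

    def test_composition_within_binomial_bounds(self):
        comp = (0.19, 0.31, 0.31, 0.19)
        seq = generate_background(100_000, comp, 1)
        n = len(seq)
        for base, p in zip("ACGT", comp):
            obs = seq.count(base)
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) < 3 * sigma

    def test_seed_reproducibility(self):
        assert generate_background(500, (0.25,) * 4, 7) == \
            generate_background(500, (0.25,) * 4, 7)


class TestPlantMotif:
    def _promoters(self, n, rng):
        return [PromoterRegion(f"p{i}", "c", 1, 300, "+",
                               generate_background(300, (0.25,) * 4, rng))
                for i in range(n)]

    def test_occupancy_zero_changes_nothing(self):
        rng = np.random.default_rng(0)
        proms = self._promoters(10, rng)
        out, truth = plant_motif(proms, planted_pwm(SyntheticScenario()), 0.0, rng)
        assert truth == {}
        assert [p.sequence for p in out] == [p.sequence for p in proms]

    def test_occupancy_one_plants_exactly_one_site_each(self):
        sc = SyntheticScenario(seed=1)
        rng = np.random.default_rng(1)
        proms = self._promoters(15, rng)
        out, truth = plant_motif(proms, planted_pwm(sc), 1.0, rng)
        assert set(truth) == {p.anchor_id for p in proms}
        w = len(sc.motif_consensus)
        for p in out:
            off, strand = truth[p.anchor_id]
            assert 0 <= off <= len(p) - w
            assert strand in "+-"

    def test_ic_calibration(self):
        # match probability solves the requested per-column information
        p = match_probability_for_ic(1.5)
        q = (1 - p) / 3
        ic = p * np.log2(4 * p) + 3 * q * np.log2(4 * q)
        assert ic == pytest.approx(1.5, abs=1e-9)


class TestExpression:
    def test_null_scenario_regulon_indistinguishable(self):
        # with induction fold 1 the planted regulon has no phase signal
        hits = 0
        for seed in range(20):
            sc = dataclasses.replace(SyntheticScenario(seed=seed),
                                     induction_fold=1.0)
            genome, truth = generate_genome_layout(sc, 0)
            prof = _profiles(sc, genome, truth)
            phases = np.asarray(sc.phase_labels)
            low = phases == "anaerobic"
            contrast = (prof.loc[:, low].mean(1) -
                        prof.loc[:, ~low].mean(1)).abs()
            reg = truth.regulon_genes
            bgn = [g for g in prof.index if g not in set(reg)]
            p = mannwhitneyu(contrast[reg], contrast[bgn]).pvalue
            hits += p < 0.01
        assert hits <= 2  # non-significant in >= 18/20 seeds

    def test_operon_comembers_coexpress(self):
        rs = []
        for seed in range(10):
            sc = SyntheticScenario(seed=seed)
            genome, truth = generate_genome_layout(sc, 0)
            prof = _profiles(sc, genome, truth)
            for members in truth.operons:
                for a, b in zip(members, members[1:]):
                    rs.append(pearson(prof.loc[a], prof.loc[b]))
        rs = np.asarray(rs)
        # shared temporal profile dominates count noise for most pairs
        assert (rs >= 0.7).mean() >= 0.85
        assert np.median(rs) >= 0.75

    def test_equal_expression_different_length_same_rpkm(self):
        # RPKM removes gene length: genes of length L and 2L with equal true
        # expression land within 10% (pre-log) at high counts
        sc = dataclasses.replace(SyntheticScenario(seed=2),
                                 baseline_log2_rpkm=(11.0, 0.0),
                                 temporal_sd=0.0, dispersion=0.0,
                                 member_jitter_sd=0.0)
        genome, truth = generate_genome_layout(sc, 0)
        counts, factors = simulate_expression(genome, truth, sc, 0)
        lengths = pd.Series({g.gene_id: g.length_bp for g in genome.genes})
        expr = compute_log2_rpkm(counts, factors, lengths)
        plain = [g for g in truth.family_of
                 if truth.sign_of_gene(g) == "none"]
        short = min(plain, key=lambda g: lengths[g])
        long = max(plain, key=lambda g: lengths[g])
        ratio = 2.0 ** (expr.loc[short] - expr.loc[long])
        assert ((ratio > 0.9) & (ratio < 1.1)).all()


class TestQpcrSimulation:
    def test_zero_noise_is_exactly_proportional(self):
        profile = pd.Series([0.0, 1.0, 2.0], index=["t1", "t2", "t3"])
        target, ref = simulate_qpcr(profile, 0.0, 0, base_copies=100.0)
        assert np.allclose(target.series, [100.0, 200.0, 400.0])
        assert np.allclose(ref.series, 100.0)

    def test_seed_reproducibility(self):
        profile = pd.Series([0.0, 1.5, 0.5, 2.0])
        a, _ = simulate_qpcr(profile, 0.2, 11)
        b, _ = simulate_qpcr(profile, 0.2, 11)
        assert np.allclose(a.series, b.series)

    def test_induced_genes_validate_under_noise(self):
        # a 4-fold induced profile survives CV-10% qPCR noise
        from fnregulon import normalize_to_reference, relative_to_min_copies
        profile = pd.Series([2.0, 2.0, 0.0, 0.0, 0.0, 0.0],
                            index=[f"t{i}" for i in range(6)])
        ok = 0
        for seed in range(100):
            target, ref = simulate_qpcr(profile, 0.1, seed)
            norm = relative_to_min_copies(normalize_to_reference(target, ref))
            ok += validate(norm, profile).verdict == "validated"
        assert ok >= 95
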