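"""PWM estimation, exact p-values, scanning, ZOOPS-EM discovery, and the
regulon conservation matrix."""

import itertools

import numpy as np
import pytest

from conftest import consensus_agreement
from fnregulon import (
    Background, GeneAnnotation, GenomeRecord, PromoterRegion, PWM,
    ScoreDistribution, build_conservation_matrix, build_pwm, discover_motif,
    filter_by_support, generate_background, information_content,
    log_odds_score, plant_motif, planted_pwm, reverse_complement, scan,
    score_threshold_for_pvalue, summarize_categories, SyntheticScenario,
)
from fnregulon.motifs import read_meme, write_meme
from fnregulon.regulon import ConservationState


def _prom(anchor, seq):
    return PromoterRegion(anchor, "c1", 1, len(seq), "+", seq,
                          window_bp=max(300, len(seq)))


class TestBuildPwm:
    def test_single_site_gives_indicator_columns(self):
        pwm = build_pwm(["ACGT"], pseudocount_weight=0.0)
        assert np.allclose(pwm.matrix, np.eye(4))

    def test_observed_frequencies(self):
        pwm = build_pwm(["AAAA", "AATA"], pseudocount_weight=0.0)
        assert pwm.matrix[2, 0] == pytest.approx(0.5)  # A
        assert pwm.matrix[2, 3] == pytest.approx(0.5)  # T

    def test_balanced_sites_give_uniform_columns(self):
        pwm = build_pwm(["AC", "CA", "GT", "TG"], pseudocount_weight=0.0)
        assert np.allclose(pwm.matrix, 0.25)

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])


class TestInformationContent:
    def test_uniform_pwm_zero_bits(self):
        pwm = PWM(np.full((5, 4), 0.25))
        _, total = information_content(pwm)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_column_two_bits(self):
        pwm = build_pwm(["A"], pseudocount_weight=0.0)
        per_col, _ = information_content(pwm)
        assert per_col[0] == pytest.approx(2.0)

    def test_two_base_column_one_bit(self):
        pwm = PWM(np.array([[0.5, 0.5, 0.0, 0.0]]))
        per_col, _ = information_content(pwm)
        assert per_col[0] == pytest.approx(1.0)


class TestLogOddsScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.full((6, 4), 0.25))
        assert log_odds_score(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_near_indicator_consensus_is_about_eight_bits(self):
        pwm = build_pwm(["ACGT"], pseudocount_weight=1e-9)
        assert log_odds_score(pwm, "ACGT") == pytest.approx(8.0, abs=1e-6)

    def test_matches_hand_summed_column_terms(self):
        rng = np.random.default_rng(3)
        mat = rng.dirichlet(np.ones(4), size=5)
        pwm = PWM(mat)
        bg = Background((0.2, 0.3, 0.3, 0.2))
        window = "GTACC"
        manual = sum(
            np.log2(mat[j, "ACGT".index(b)] / bg.probs["ACGT".index(b)])
            for j, b in enumerate(window))
        assert log_odds_score(pwm, window, bg) == pytest.approx(manual)

    def test_ambiguous_base_is_undefined(self):
        pwm = PWM(np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            log_odds_score(pwm, "ACNT")


class TestExactPvalues:
    def test_alpha_one_threshold_is_minimum_score(self):
        pwm = build_pwm(["ACGT", "ACGA"], pseudocount_weight=0.5)
        dist = ScoreDistribution(pwm, Background.uniform())
        assert score_threshold_for_pvalue(pwm, alpha=1.0) == pytest.approx(
            dist.min_total / dist.granularity)

    def test_width_one_enumeration(self):
        pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01]]))
        dist = ScoreDistribution(pwm, Background.uniform())
        thr = dist.threshold(0.3)
        # only A scores above the threshold; P(score >= score(A)) = 1/4
        score_a = np.log2(0.97 / 0.25)
        assert thr <= score_a
        assert dist.pvalue(score_a) == pytest.approx(0.25)
        assert dist.pvalue(np.log2(0.01 / 0.25)) == pytest.approx(1.0)

    def test_dp_equals_enumeration_width3(self):
        rng = np.random.default_rng(11)
        mat = np.clip(rng.dirichlet(np.ones(4), size=3), 1e-9, None)
        mat /= mat.sum(axis=1, keepdims=True)
        bgp = np.array([0.2, 0.3, 0.3, 0.2])
        dist = ScoreDistribution(PWM(mat), Background(tuple(bgp)))
        for win in itertools.product(range(4), repeat=3):
            s = int(dist.int_scores[np.arange(3), list(win)].sum())
            enum = sum(
                np.prod(bgp[list(other)])
                for other in itertools.product(range(4), repeat=3)
                if dist.int_scores[np.arange(3), list(other)].sum() >= s)
            assert dist.pvalue_int(s) == pytest.approx(enum, abs=1e-12)

    def test_survival_monotone_in_score(self):
        pwm = build_pwm(["ACGTA", "ACGTT", "AGGTA"], pseudocount_weight=0.5)
        dist = ScoreDistribution(pwm, Background.uniform())
        assert (np.diff(dist.sf) <= 1e-15).all()

    def test_invalid_alpha_rejected(self):
        pwm = PWM(np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            score_threshold_for_pvalue(pwm, alpha=0.0)


class TestScan:
    def test_finds_planted_consensus(self):
        sc = SyntheticScenario(seed=0)
        pwm = planted_pwm(sc)
        rng = np.random.default_rng(2)
        seq = generate_background(300, sc.background_composition, rng)
        seq = seq[:50] + sc.motif_consensus + seq[50 + pwm.width:]
        hits = scan(pwm, [_prom("p1", seq)], Background.uniform(), alpha=1e-5)
        assert any(h.offset == 50 for h in hits)

    def test_promoter_shorter_than_motif_yields_no_hits(self):
        pwm = PWM(np.full((10, 4), 0.25))
        assert scan(pwm, [_prom("p1", "ACGTA")], Background.uniform()) == []

    def test_palindromic_consensus_hits_both_strands(self):
        sc = SyntheticScenario(seed=0)
        consensus = sc.motif_consensus
        assert reverse_complement(consensus) == consensus  # FNR-box dyad
        pwm = planted_pwm(sc)
        rng = np.random.default_rng(4)
        seq = generate_background(200, (0.25,) * 4, rng)
        seq = seq[:80] + consensus + seq[80 + pwm.width:]
        hits = scan(pwm, [_prom("p1", seq)], Background.uniform(), alpha=1e-4)
        strands = {h.strand_relative for h in hits if h.offset == 80}
        assert strands == {"+", "-"}

    def test_reverse_complement_promoter_mirrors_hits(self):
        sc = SyntheticScenario(seed=0)
        pwm = planted_pwm(sc)
        rng = np.random.default_rng(6)
        seq = generate_background(250, sc.background_composition, rng)
        seq = seq[:100] + sc.motif_consensus + seq[100 + pwm.width:]
        bg = Background.uniform()
        fwd = scan(pwm, [_prom("p", seq)], bg, alpha=1e-3)
        rev = scan(pwm, [_prom("p", reverse_complement(seq))], bg, alpha=1e-3)
        L, w = len(seq), pwm.width
        flip = {"+": "-", "-": "+"}
        assert {(L - w - h.offset, flip[h.strand_relative], round(h.score, 6))
                for h in fwd} == \
               {(h.offset, h.strand_relative, round(h.score, 6)) for h in rev}


class TestDiscovery:
    def _planted_promoters(self, n, seed, occupancy=1.0):
        sc = SyntheticScenario(seed=seed)
        rng = np.random.default_rng(seed)
        proms = [_prom(f"p{i}",
                       generate_background(300, sc.background_composition, rng))
                 for i in range(n)]
        planted, truth = plant_motif(proms, planted_pwm(sc), occupancy, rng)
        return sc, planted, truth

    def test_trace_is_monotone_and_recovery_on_planted_set(self):
        sc, proms, _ = self._planted_promoters(12, seed=5)
        res = discover_motif(proms, width=14, n_restarts=3, seed=5)
        assert (np.diff(res.ll_trace) >= -1e-8).all()
        assert consensus_agreement(res.pwm.consensus, sc.motif_consensus) >= 0.9

    def test_background_only_promoters_give_weaker_motif(self):
        sc, planted, _ = self._planted_promoters(12, seed=6)
        rng = np.random.default_rng(6)
        plain = [_prom(f"q{i}",
                       generate_background(300, sc.background_composition, rng))
                 for i in range(12)]
        bg = Background(sc.background_composition)
        res_planted = discover_motif(planted, width=14, n_restarts=3, seed=6,
                                     background=bg)
        res_plain = discover_motif(plain, width=14, n_restarts=3, seed=6,
                                   background=bg)
        _, ic_planted = information_content(res_planted.pwm, bg)
        _, ic_plain = information_content(res_plain.pwm, bg)
        assert ic_plain < ic_planted

    def test_too_few_promoters_rejected(self):
        with pytest.raises(ValueError):
            discover_motif([_prom("p", "ACGT" * 20)] * 3, width=8)


class TestMemeFormat:
    def test_roundtrip(self, tmp_path):
        pwm = build_pwm(["ACGTACGT", "ACGAACGT", "TCGTACGA"],
                        pseudocount_weight=0.5)
        bg = Background((0.2, 0.3, 0.3, 0.2))
        write_meme(pwm, bg, tmp_path / "m.meme")
        back, bg2 = read_meme(tmp_path / "m.meme")
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-5)
        assert np.allclose(bg2.array, bg.array, atol=1e-5)


def _toy_genome(gid, gene_ids):
    genes = [GeneAnnotation(g, "c1", 100 + 1000 * i, 500 + 1000 * i, "+")
             for i, g in enumerate(gene_ids)]
    return GenomeRecord(gid, {"c1": "A" * 20_000}, genes)


class TestConservation:
    def _fixture(self):
        # 8 genomes; family A in all, family B in genomes 0-3 only
        genomes, hits = {}, {}
        fam = {}
        for i in range(8):
            gid = f"G{i}"
            gene_ids = [f"G{i}_a"] + ([f"G{i}_b"] if i < 4 else [])
            genomes[gid] = _toy_genome(gid, gene_ids)
            fam[f"G{i}_a"] = "famA"
            if i < 4:
                fam[f"G{i}_b"] = "famB"
            hits[gid] = set()
            if i < 5:
                hits[gid].add(f"G{i}_a")     # famA hit in 5 genomes
            if i < 2:
                hits[gid].add(f"G{i}_b")     # famB hit in 2 genomes
        return hits, genomes, fam

    def test_three_state_classification(self):
        hits, genomes, fam = self._fixture()
        m = build_conservation_matrix(hits, genomes, fam)
        assert m.states.loc["G0", "famA"] == ConservationState.PRESENT_WITH_MOTIF
        assert m.states.loc["G6", "famA"] == ConservationState.PRESENT_NO_MOTIF
        assert m.states.loc["G6", "famB"] == ConservationState.ABSENT
        # exactly one of the three states everywhere
        assert m.states.isin([0, 1, 2]).all().all()
        assert m.motif_support().to_dict() == {"famA": 5, "famB": 2}

    def test_support_filter(self):
        hits, genomes, fam = self._fixture()
        m = build_conservation_matrix(hits, genomes, fam)
        assert filter_by_support(m, 4).family_ids == ["famA"]
        assert set(filter_by_support(m, 1).family_ids) == {"famA", "famB"}

    def test_hit_without_family_is_bucketed_unassigned(self):
        genomes = {"G0": _toy_genome("G0", ["G0_a", "G0_x"])}
        m = build_conservation_matrix({"G0": {"G0_x"}}, genomes,
                                      {"G0_a": "famA"})
        assert m.states.loc["G0", "unassigned"] == \
            ConservationState.PRESENT_WITH_MOTIF

    def test_category_tally(self):
        tally = summarize_categories(
            ["f1", "f2", "f3", "f4"],
            {"f1": "metabolism", "f2": "metabolism", "f3": "signaling"})
        assert tally.to_dict() == {"metabolism": 2, "signaling": 1,
                                   "unassigned": 1}
        assert summarize_categories([], {}).empty
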