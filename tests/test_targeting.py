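"""Expectation scoring, duplex energy ratio, degradome categories, consensus."""

import math

import numpy as np
import pytest

from mirnet import synthio, targeting
from mirnet.targeting import (NN_STACK, Site, classify_degradome, consensus,
                              duplex_energy, enrich_terms, predict_targets,
                              score_expectation, score_hybrid, score_site)
from mirnet.types import TargetEvidence, revcomp

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def site_for(mirna=MIRNA):
    return revcomp(mirna)


def expectation_oracle(mirna: str, site: str) -> float:
    """Direct per-position rule application (mismatch 1, G:U 0.5, core x2)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")
    total = 0.0
    for p in range(1, len(m) + 1):          # miRNA position, 5'->3'
        mb = m[p - 1]
        tb = s[len(m) - p]                  # antiparallel partner
        if tb == comp[mb]:
            pen = 0.0
        elif (mb, tb) in {("G", "T"), ("T", "G")}:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= p <= 13:
            pen *= 2
        total += pen
    return total


class TestExpectation:
    def test_perfect_complement_scores_zero(self):
        assert score_site(MIRNA, site_for()) == 0.0

    def test_single_wobble_outside_core(self):
        # G:U at miRNA position 15: replace the paired transcript base
        site = list(site_for())
        p = 15
        mb = MIRNA[p - 1]
        assert mb in "AG" or True
        # make the transcript base wobble-pair the miRNA base
        site[len(MIRNA) - p] = {"G": "T", "T": "G"}.get(mb, "T")
        score = score_site(MIRNA, "".join(site))
        assert score == expectation_oracle(MIRNA, "".join(site))
        if mb in "GT":
            assert score == 0.5

    def test_single_core_mismatch_doubled(self):
        site = list(site_for())
        p = 5
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bad = next(b for b in "ACGT"
                   if b != comp[MIRNA[p - 1]]
                   and (MIRNA[p - 1], b) not in {("G", "T"), ("T", "G")})
        site[len(MIRNA) - p] = bad
        assert score_site(MIRNA, "".join(site)) == 2.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sites_match_rule_oracle(self, seed):
        local = np.random.default_rng(seed)
        site = "".join(local.choice(list("ACGT"), size=len(MIRNA)))
        assert score_site(MIRNA, site) == \
            pytest.approx(expectation_oracle(MIRNA, site))

    def test_scan_score_independent_of_position(self):
        site = site_for()
        for pad_left in (0, 13, 57):
            tx = "A" * pad_left + site + "G" * 30
            hits = score_expectation(MIRNA, tx, cutoff=3.0)
            assert any(h.start == pad_left and h.expectation == 0.0
                       for h in hits)

    def test_bulged_site_scored_with_gap_penalty(self):
        # one transcript bulge outside the core adds >= 2.0
        site = site_for()
        bulged = site[:3] + "A" + site[3:]
        score = score_site(MIRNA, bulged)
        assert score >= 2.0

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            score_expectation("ACGUACGUACGU", "ACGT" * 20)


class TestHybrid:
    def test_perfect_complement_ratio_one(self):
        energy, ratio, kept = score_hybrid(MIRNA, site_for())
        assert ratio == pytest.approx(1.0)
        assert kept and energy < 0

    def test_half_broken_duplex_dropped(self):
        site = list(site_for())
        for i in range(0, len(site), 2):  # break alternating pairs
            site[i] = "A" if site[i] != "A" else "C"
        _e, ratio, kept = score_hybrid(MIRNA, "".join(site))
        assert ratio < 0.75 and not kept

    @pytest.mark.parametrize("seed", range(6))
    def test_ratio_in_unit_interval(self, seed):
        local = np.random.default_rng(seed)
        site = "".join(local.choice(list("ACGT"), size=len(MIRNA) + 2))
        _e, ratio, _kept = score_hybrid(MIRNA, site)
        assert 0.0 <= ratio <= 1.0

    def test_energy_matches_stack_table_oracle(self):
        energy = duplex_energy(MIRNA, site_for())
        mir = MIRNA.replace("T", "U")
        expected = sum(NN_STACK[mir[i] + mir[i + 1]]
                       for i in range(len(mir) - 1))
        assert energy == pytest.approx(expected)

    def test_forced_helix_constraint(self):
        site = list(site_for())
        p = 10  # break pairing at a forced position
        site[len(MIRNA) - p] = "A" if site[len(MIRNA) - p] != "A" else "C"
        _e, _r, kept = score_hybrid(MIRNA, "".join(site), cutoff=0.5,
                                    force_paired=(8, 12))
        assert not kept

    def test_bad_site_length_raises(self):
        with pytest.raises(ValueError):
            score_hybrid(MIRNA, "ACGT")


class TestDegradomeCategories:
    SITE = Site("tx", 10, 31, 0.0)  # cleavage at 10 + 21 - 9 = 22

    def test_category_definitions_exhaustive(self):
        pos = self.SITE.cleavage_pos
        cases = [
            ({pos: 50, 3: 5, 7: 2}, 0),          # unique maximum
            ({pos: 30, 3: 30, 7: 2}, 1),         # tied maximum
            ({pos: 15, 3: 30, 7: 2, 9: 2}, 2),   # above mean, below max
            ({pos: 3, 3: 30, 7: 20, 9: 20}, 3),  # below or at mean
            ({pos: 1, 3: 30}, 4),                # singleton read
            ({3: 30}, None),                     # no read at cleavage site
        ]
        for density, expected in cases:
            cat, cpos = classify_degradome(self.SITE, density)
            assert cat == expected, density
            assert (cpos == pos) is (expected is not None)

    def test_empty_density_none(self):
        assert classify_degradome(self.SITE, {}) == (None, None)
        assert classify_degradome(self.SITE, None) == (None, None)

    def test_category_four_not_retained(self):
        assert 4 not in targeting.RETAINED_CATEGORIES
        assert targeting.RETAINED_CATEGORIES == {0, 1, 2}


class TestConsensus:
    def record(self, mid, tid, methods):
        cat, cpos = (0, 15) if "degradome" in methods else (None, None)
        return TargetEvidence(mid, tid, 0, 21, expectation=1.0,
                              energy_ratio=0.9, degradome_category=cat,
                              cleavage_pos=cpos, methods=set(methods))

    def test_two_methods_in_intersection(self):
        recs = [self.record("m1", "t1", {"expectation", "degradome"}),
                self.record("m1", "t2", {"hybrid"})]
        union, inter = consensus(recs)
        assert {r.pair for r in union} == {("m1", "t1"), ("m1", "t2")}
        assert {r.pair for r in inter} == {("m1", "t1")}

    def test_intersection_subset_of_union(self, rng):
        methods_pool = [{"expectation"}, {"hybrid"}, {"degradome"},
                        {"expectation", "hybrid"},
                        {"expectation", "hybrid", "degradome"}]
        recs = [self.record(f"m{i}", f"t{i}",
                            methods_pool[int(rng.integers(0, 5))])
                for i in range(30)]
        union, inter = consensus(recs)
        assert {r.pair for r in inter} <= {r.pair for r in union}


class TestPredictTargets:
    def test_planted_pairs_recovered_with_all_methods(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        degradome = synthio.generate_degradome_library(
            truth, transcripts, signal_reads=40, noise_reads=500, seed=3)
        mirnas = {pm.locus_id: pm.mature_seq
                  for pm in truth.planted_mirna_loci}
        records = predict_targets(mirnas, transcripts, degradome)
        _union, inter = consensus(records)
        inter_pairs = {r.pair for r in inter}
        for pt in truth.planted_target_pairs:
            assert (pt.mirna_id, pt.transcript_id) in inter_pairs

    def test_cutoff_tightening_shrinks_sets(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        mirnas = {pm.locus_id: pm.mature_seq
                  for pm in truth.planted_mirna_loci}
        loose = predict_targets(mirnas, transcripts, None,
                                expectation_cutoff=3.0, hybrid_cutoff=0.75)
        tight = predict_targets(mirnas, transcripts, None,
                                expectation_cutoff=1.0, hybrid_cutoff=0.9)
        for a, b in [(tight, loose)]:
            ua, ia = consensus(a)
            ub, ib = consensus(b)
            assert {r.pair for r in ua} <= {r.pair for r in ub}
            assert {r.pair for r in ia} <= {r.pair for r in ib}

    def test_without_degradome_intersection_needs_both_scores(self,
                                                              small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        mirnas = {pm.locus_id: pm.mature_seq
                  for pm in truth.planted_mirna_loci}
        records = predict_targets(mirnas, transcripts, None)
        _union, inter = consensus(records)
        for r in inter:
            assert r.methods >= {"expectation", "hybrid"}
            assert r.degradome_category is None


class TestEnrichment:
    def test_term_covering_background_is_not_enriched(self):
        bg = [f"g{i}" for i in range(50)]
        df = enrich_terms(bg[:10], bg, {"all": bg})
        assert df.loc["all", "p"] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_tail_oracle(self):
        N, K, n, k = 100, 10, 10, 5
        bg = [f"g{i}" for i in range(N)]
        annotated = bg[:K]
        selected = annotated[:k] + bg[K:K + (n - k)]
        df = enrich_terms(selected, bg, {"T": annotated})
        tail = sum(math.comb(K, x) * math.comb(N - K, n - x)
                   for x in range(k, min(K, n) + 1)) / math.comb(N, n)
        assert df.loc["T", "p"] == pytest.approx(tail, rel=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        bg = [f"g{i}" for i in range(60)]
        terms = {f"T{j}": [g for g in bg if rng.random() < 0.3]
                 for j in range(8)}
        df = enrich_terms(bg[:15], bg, terms)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()

    def test_empty_target_raises(self):
        with pytest.raises(ValueError):
            enrich_terms([], ["g1"], {"T": ["g1"]})

    def test_target_outside_background_raises(self):
        with pytest.raises(ValueError):
            enrich_terms(["x"], ["g1"], {"T": ["g1"]})
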