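"""Mapping, excision, duplex calling and plant-criteria acceptance."""

import numpy as np
import pytest

from mirnet import discovery, synthio
from mirnet.discovery import (Criteria, Rejection, apply_criteria,
                              call_duplex, excise_candidates, map_stacks,
                              summarize_loci)
from mirnet.types import GenomicInterval, HairpinCandidate, ReadStack, revcomp


@pytest.fixture(scope="module")
def toy_genome(rng):
    seq = "".join(np.random.default_rng(42).choice(list("ACGT"), size=50_000))
    return {"toy": seq}


class TestMapStacks:
    def test_single_forward_placement(self, toy_genome):
        seq = toy_genome["toy"][1000:1021]
        st = ReadStack(seq, {"lib": 1})
        map_stacks([st], toy_genome)
        plus = [p for p in st.placements if p.strand == "+"]
        assert GenomicInterval("toy", 1000, 1021, "+") in plus

    def test_absent_sequence_unplaced(self, toy_genome):
        st = ReadStack("ACGT" * 6, {"lib": 1})  # 24-mer repeat: very unlikely
        map_stacks([st], {"toy": "TTTT" * 1000})
        assert st.placements == []

    def test_agrees_with_bruteforce_substring_scan(self, toy_genome):
        g = toy_genome["toy"]
        local = np.random.default_rng(9)
        stacks = []
        for _ in range(25):
            pos = int(local.integers(0, len(g) - 21))
            seq = g[pos:pos + 21]
            stacks.append(ReadStack(seq if local.random() < 0.5 else revcomp(seq),
                                    {"lib": 1}))
        map_stacks(stacks, toy_genome)
        for st in stacks:
            expected = set()
            for strand, target in (("+", st.sequence), ("-", revcomp(st.sequence))):
                start = g.find(target)
                while start >= 0:
                    expected.add(("toy", start, start + 21, strand))
                    start = g.find(target, start + 1)
            got = {(p.chrom, p.start, p.end, p.strand) for p in st.placements}
            assert got == expected

    def test_multimap_flagging(self):
        genome = {"c": "A" * 30 + "ACGTTGCATGCAAGCTTGCAT" + "T" * 30
                       + "ACGTTGCATGCAAGCTTGCAT" + "G" * 30}
        st = ReadStack("ACGTTGCATGCAAGCTTGCAT", {"lib": 1})
        map_stacks([st], genome, max_hits=1)
        assert st.multimapped


class TestExcision:
    def test_two_windows_per_placement(self, toy_genome):
        st = ReadStack(toy_genome["toy"][10_000:10_021], {"lib": 9})
        st.placements = [GenomicInterval("toy", 10_000, 10_021, "+")]
        cands = excise_candidates([st], toy_genome, flank=250)
        spans = {(c.window.start, c.window.end) for c in cands
                 if c.window.strand == "+"}
        assert (9_750, 10_021) in spans
        assert (10_000, 10_271) in spans

    def test_edge_truncation_flagged(self, toy_genome):
        st = ReadStack(toy_genome["toy"][5:26], {"lib": 9})
        st.placements = [GenomicInterval("toy", 5, 26, "+")]
        cands = excise_candidates([st], toy_genome, flank=250)
        left = [c for c in cands if c.window.start == 0]
        assert left and left[0].truncated

    def test_merge_respects_interval_oracle(self, toy_genome):
        # windows from two stacks 10 nt apart merge into <= 2 windows
        s1 = ReadStack(toy_genome["toy"][20_000:20_021], {"lib": 9})
        s1.placements = [GenomicInterval("toy", 20_000, 20_021, "+")]
        s2 = ReadStack(toy_genome["toy"][20_031:20_052], {"lib": 9})
        s2.placements = [GenomicInterval("toy", 20_031, 20_052, "+")]
        cands = excise_candidates([s1, s2], toy_genome, flank=100,
                                  max_window=300)
        wins = sorted((c.window.start, c.window.end) for c in cands)
        # oracle: plain interval merge without the size cap
        raw = sorted([(19_900, 20_021), (20_000, 20_121),
                      (19_931, 20_052), (20_031, 20_152)])
        merged = [list(raw[0])]
        for s, e in raw[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # all merged spans fit the cap here, so results must agree
        assert wins == [tuple(m) for m in merged]
        assert len(wins) <= 2


def make_candidate(pm, mature_count=90, star_count=30, extra=()):
    mat = ReadStack(pm.mature_seq, {"lib": mature_count})
    mat.placements = [pm.mature]
    star = ReadStack(pm.star_seq, {"lib": star_count})
    star.placements = [pm.star]
    stacks = [mat, star]
    for seq, count, iv in extra:
        st = ReadStack(seq, {"lib": count})
        st.placements = [iv]
        stacks.append(st)
    return HairpinCandidate(window=pm.precursor, sequence=pm.precursor_seq,
                            stacks_in_window=stacks)


class TestCallDuplex:
    def test_star_matches_planted_interval(self, small_truth):
        _genome, truth = small_truth
        for pm in truth.planted_mirna_loci:
            call = call_duplex(make_candidate(pm))
            assert not isinstance(call, Rejection), pm.locus_id
            got = discovery._genomic_span(pm.precursor, *call.star_local)
            assert (got.start, got.end) == (pm.star.start, pm.star.end), \
                pm.locus_id

    def test_precision_reflects_signal_share(self, small_truth):
        _genome, truth = small_truth
        pm = truth.planted_mirna_loci[0]
        # an offset stack whose 5' end is far from both planted 5' ends
        loff = next(o for o in range(3, 60)
                    if abs(o - pm.mature_local[0]) > 2
                    and abs(o - pm.star_local[0]) > 2)
        iv = discovery._genomic_span(pm.precursor, loff, loff + 21)
        noise_seq = pm.precursor_seq[loff:loff + 21]
        call = call_duplex(make_candidate(
            pm, 90, 30, extra=[(noise_seq, 13, iv)]))
        assert call.precision == pytest.approx(120 / 133)

    def test_mature_spanning_loop_rejected(self, small_truth):
        _genome, truth = small_truth
        pm = truth.planted_mirna_loci[0]
        # a read centred on the loop, pairing into both arms
        ml, sl = sorted([pm.mature_local, pm.star_local])
        centre = (ml[1] + sl[0]) // 2
        lo, hi = centre - 10, centre + 11
        seq = pm.precursor_seq[lo:hi]
        iv = discovery._genomic_span(pm.precursor, lo, hi)
        st = ReadStack(seq, {"lib": 500})
        st.placements = [iv]
        cand = HairpinCandidate(window=pm.precursor, sequence=pm.precursor_seq,
                                stacks_in_window=[st])
        call = call_duplex(cand)
        assert isinstance(call, Rejection)

    def test_no_reads_rejected(self, small_truth):
        _genome, truth = small_truth
        pm = truth.planted_mirna_loci[0]
        cand = HairpinCandidate(window=pm.precursor,
                                sequence=pm.precursor_seq)
        assert isinstance(call_duplex(cand), Rejection)


class TestCriteria:
    def _call(self, small_truth, **overrides):
        _genome, truth = small_truth
        call = call_duplex(make_candidate(truth.planted_mirna_loci[0]))
        for key, value in overrides.items():
            setattr(call, key, value)
        return call

    def test_good_call_accepted(self, small_truth):
        ok, reason = apply_criteria(self._call(small_truth))
        assert ok, reason

    @pytest.mark.parametrize("field,value,reason", [
        ("precision", 0.5, "precision"),
        ("duplex_mismatches", 6, "duplex_mismatches"),
        ("asymmetric_bulge", 4, "asymmetric_bulge"),
        ("total_reads", 5, "read_support"),
    ])
    def test_threshold_violations(self, small_truth, field, value, reason):
        ok, got = apply_criteria(self._call(small_truth, **{field: value}))
        assert not ok and got == reason

    def test_thresholds_are_configuration(self, small_truth):
        call = self._call(small_truth, duplex_mismatches=6)
        ok, _ = apply_criteria(call, Criteria(max_duplex_mismatches=6))
        assert ok

    def test_acceptance_monotone_in_precision(self, small_truth):
        # raising precision never flips accept -> reject
        call = self._call(small_truth)
        for lo in np.linspace(0, 1, 21):
            call.precision = lo
            accepted_lo = apply_criteria(call)[0]
            call.precision = min(1.0, lo + 0.2)
            assert apply_criteria(call)[0] >= accepted_lo


class TestDiscoveryEndToEnd:
    def test_recovers_planted_loci(self, small_truth, small_loci):
        _genome, truth = small_truth
        loci, _rej, _pred = small_loci
        recovered = sum(
            1 for pm in truth.planted_mirna_loci
            if any(l.mature.overlaps(pm.mature)
                   and l.mature.strand == pm.mature.strand for l in loci))
        assert recovered >= 0.9 * len(truth.planted_mirna_loci)

    def test_no_sirna_locus_accepted(self, small_truth, small_loci):
        _genome, truth = small_truth
        loci, _rej, _pred = small_loci
        assert not any(l.precursor.overlaps(iv) for l in loci
                       for iv in truth.planted_sirna_loci)

    def test_every_mature_comes_from_input_stacks(self, small_loci):
        loci, _rej, pred = small_loci
        stack_seqs = {s.sequence for s in pred}
        assert all(l.mature_seq in stack_seqs for l in loci)

    def test_family_co_naming_by_mature_similarity(self, small_loci):
        loci, _rej, _pred = small_loci
        by_family = {}
        for l in loci:
            by_family.setdefault(l.family, []).append(l.mature_seq)
        for seqs in by_family.values():
            for s in seqs[1:]:
                assert len(s) == len(seqs[0])
                assert sum(a != b for a, b in zip(s, seqs[0])) <= 2


class TestSummaries:
    def test_tables_sum_to_one(self, small_loci):
        loci, _rej, _pred = small_loci
        tables = summarize_loci(loci)
        for name in ("precursor_length", "mature_length", "first_nt"):
            assert sum(tables[name].values()) == pytest.approx(1.0)
        assert set(tables["first_nt"]) == set("ACGU")

    def test_mature_length_rf(self, small_loci):
        loci, _rej, _pred = small_loci
        tables = summarize_loci(loci)
        lengths = [len(l.mature) for l in loci]
        for L, rf in tables["mature_length"].items():
            assert rf == pytest.approx(lengths.count(L) / len(lengths))

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            summarize_loci([])
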