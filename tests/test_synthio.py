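"""Synthetic-data generators: determinism, planted structure, recovery."""

import numpy as np
import pytest

from mirnet import correlation, io, srna, synthio
from mirnet.fold import default_engine, pair_table


class TestGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a, _ = synthio.generate_genome_with_hairpins(5, 5, 120_000, seed=7)
        b, _ = synthio.generate_genome_with_hairpins(5, 5, 120_000, seed=7)
        io.write_fasta(a, tmp_path / "a.fa")
        io.write_fasta(b, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_different_seed_differs(self):
        a, _ = synthio.generate_genome_with_hairpins(3, 3, 120_000, seed=1)
        b, _ = synthio.generate_genome_with_hairpins(3, 3, 120_000, seed=2)
        assert a != b

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            synthio.generate_genome_with_hairpins(1000, 0, 10_000, seed=0)

    def test_planted_hairpins_pair_mature_to_star(self, small_truth):
        _genome, truth = small_truth
        engine = default_engine()
        for pm in truth.planted_mirna_loci:
            structure, _ = engine.fold(pm.precursor_seq)
            pt = pair_table(structure)
            paired = sum(1 for i in range(*pm.mature_local)
                         if pt[i] >= 0
                         and pm.star_local[0] <= pt[i] < pm.star_local[1])
            assert paired >= 18, pm.locus_id

    def test_precursor_length_distribution(self):
        _g, truth = synthio.generate_genome_with_hairpins(60, 0, 2_000_000, seed=3)
        lens = np.array([len(pm.precursor_seq) for pm in truth.planted_mirna_loci])
        frac_short = (lens < 150).mean()
        # designed 80% < 150 nt, allow 2 binomial SE at n=60
        assert abs(frac_short - 0.80) <= 2 * np.sqrt(0.8 * 0.2 / 60) + 1e-9

    def test_loci_do_not_overlap(self, small_truth):
        _g, truth = small_truth
        ivs = ([pm.precursor for pm in truth.planted_mirna_loci]
               + list(truth.planted_sirna_loci))
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start


class TestSrnaLibrary:
    def test_zero_depth_raises(self, small_truth):
        genome, truth = small_truth
        with pytest.raises(ValueError):
            synthio.generate_srna_library(truth, genome, depth=0, seed=1)

    def test_precision_out_of_range_raises(self, small_truth):
        genome, truth = small_truth
        with pytest.raises(ValueError):
            synthio.generate_srna_library(truth, genome, depth=100,
                                          precision=0.5, seed=1)

    def test_reads_stack_on_planted_five_prime_ends(self, small_truth):
        genome, truth = small_truth
        stacks = synthio.generate_srna_library(truth, genome, depth=40_000,
                                               precision=0.9, seed=5)
        pm = truth.planted_mirna_loci[0]
        # reads whose sequence sits inside this locus's precursor
        pre = pm.precursor_seq
        total = signal = 0
        for st in stacks:
            pos = pre.find(st.sequence)
            if pos < 0:
                continue
            total += st.total_count
            if min(abs(pos - pm.mature_local[0]),
                   abs(pos - pm.star_local[0])) <= 2:
                signal += st.total_count
        assert total > 0
        assert signal / total >= 0.85  # binomial fluctuation around 0.9

    def test_length_histogram_is_bimodal_at_21_and_24(self, small_library):
        profile = srna.length_profile(list(small_library), "clean")
        mode = max(profile, key=profile.get)
        assert mode in (21, 24)
        # both peaks dominate their neighbourhoods
        assert profile[21] > profile[19] and profile[21] > profile[23]
        assert profile[24] > profile[23] and profile[24] > profile[26]

    def test_replicates_share_locus_means(self):
        genome, truth = synthio.generate_genome_with_hairpins(
            30, 0, 600_000, seed=13)
        counts = []
        for seed in (21, 22):
            stacks = synthio.generate_srna_library(truth, genome, depth=200_000,
                                                   precision=0.9, seed=seed)
            by_seq = {st.sequence: st.total_count for st in stacks}
            counts.append([by_seq.get(pm.mature_seq, 0)
                           for pm in truth.planted_mirna_loci])
        r = np.corrcoef(counts[0], counts[1])[0, 1]
        assert r > 0.9


class TestDegradome:
    def test_clean_signal_peaks_at_planted_cleavage(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        density = synthio.generate_degradome_library(
            truth, transcripts, signal_reads=50, noise_reads=0, seed=3)
        for pt in truth.planted_target_pairs:
            d = density[pt.transcript_id]
            assert max(d, key=d.get) == pt.cleavage_pos

    def test_no_signal_no_peak(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        density = synthio.generate_degradome_library(
            truth, transcripts, signal_reads=0, noise_reads=0, seed=3)
        assert density == {}

    def test_unknown_transcript_raises(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        with pytest.raises(ValueError, match="unknown transcript"):
            synthio.generate_degradome_library(truth, {"other": "ACGT"},
                                               signal_reads=5, seed=0)


class TestExpressionProfiles:
    def test_negative_pairs_are_exactly_anticorrelated_at_zero_noise(
            self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        me, te = synthio.generate_expression_profiles(
            truth, negative_fraction=1.0, noise_sd=0.0, seed=5)
        mm, tm = me.tissue_means(), te.tissue_means()
        for pt in truth.planted_target_pairs:
            r = np.corrcoef(mm.loc[pt.mirna_id], tm.loc[pt.transcript_id])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_fraction_gives_uncorrelated_pairs(self, small_truth):
        _genome, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        me, te = synthio.generate_expression_profiles(
            truth, negative_fraction=0.0, noise_sd=0.0, seed=5)
        assert truth.planted_negative_pairs == set()
        recs = correlation.correlate(
            me, te, [(p.mirna_id, p.transcript_id)
                     for p in truth.planted_target_pairs])
        rs = [rec.r for rec in recs if not rec.degenerate]
        assert abs(np.mean(rs)) < 0.5  # centred near zero, not at the edges

    def test_fraction_recovery_within_binomial_error(self):
        _g, truth = synthio.generate_genome_with_hairpins(40, 0, 1_200_000,
                                                          seed=9)
        transcripts, truth = synthio.generate_transcriptome(
            truth, targets_per_mirna=5, n_background=0, seed=9)
        n = len(truth.planted_target_pairs)
        f = 0.46
        me, te = synthio.generate_expression_profiles(
            truth, negative_fraction=f, noise_sd=0.02, seed=9)
        recs = correlation.correlate(
            me, te, [(p.mirna_id, p.transcript_id)
                     for p in truth.planted_target_pairs])
        est, _, _ = correlation.negative_fraction(recs)
        assert abs(est - f) <= 2 * np.sqrt(f * (1 - f) / n)

    def test_invalid_fraction_raises(self, small_truth):
        _genome, truth = small_truth
        with pytest.raises(ValueError):
            synthio.generate_expression_profiles(truth, negative_fraction=1.5)

    def test_too_few_tissues_raises(self, small_truth):
        _genome, truth = small_truth
        with pytest.raises(ValueError):
            synthio.generate_expression_profiles(truth, n_tissues=2)


class TestTfInputs:
    def test_pwm_rows_normalised_and_sites_exact(self):
        pwms, promoters, sites = synthio.generate_tf_motifs_and_promoters(
            n_tfs=4, n_sites=10, motif_length=8, seed=2)
        for pwm in pwms:
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
        by_id = {p.tf_id: p for p in pwms}
        for tf, pid, off in sites:
            assert promoters[pid][off:off + 8] == by_id[tf].consensus

    def test_site_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            synthio.generate_tf_motifs_and_promoters(
                n_tfs=2, n_sites=10_000, motif_length=8, n_promoters=1,
                promoter_length=100, seed=0)

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError):
            synthio.generate_tf_motifs_and_promoters(motif_length=5, seed=0)

    def test_pwm_determinism(self, tmp_path):
        for name in ("a", "b"):
            pwms, _, _ = synthio.generate_tf_motifs_and_promoters(seed=4)
            io.write_pwms(pwms, tmp_path / f"{name}.txt")
        assert (tmp_path / "a.txt").read_bytes() == (tmp_path / "b.txt").read_bytes()


class TestRoundTrips:
    def test_genome_fasta_round_trip(self, small_truth, tmp_path):
        genome, _ = small_truth
        io.write_fasta(genome, tmp_path / "g.fa")
        assert io.read_fasta(tmp_path / "g.fa") == genome

    def test_pwm_round_trip(self, tmp_path):
        pwms, _, _ = synthio.generate_tf_motifs_and_promoters(seed=5)
        io.write_pwms(pwms, tmp_path / "p.txt")
        back = io.read_pwms(tmp_path / "p.txt")
        assert [p.tf_id for p in back] == [p.tf_id for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)

    def test_density_table_round_trip(self, small_truth, tmp_path):
        _g, truth = small_truth
        transcripts, truth = synthio.generate_transcriptome(truth, seed=3)
        density = synthio.generate_degradome_library(
            truth, transcripts, signal_reads=20, noise_reads=100, seed=3)
        io.write_density_table(density, tmp_path / "d.tsv")
        assert io.read_density_table(tmp_path / "d.tsv") == density
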