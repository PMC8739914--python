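"""Predict miRNA targets by three evidence routes and form the consensus.

Expectation scoring penalises mismatches (1), G:U wobbles (0.5) and gaps
(2), doubled over miRNA positions 2-13, keeping sites at expectation <=
3.0. The hybrid route keeps sites whose duplex stacking energy reaches
75% of the perfect complement. Degradome 5'-end densities validate
cleavage (categories 0-2). The intersection keeps pairs with >= 2 routes.
"""

from mirnet import synthio, targeting

_genome, truth = synthio.generate_genome_with_hairpins(
    n_mirna=20, n_sirna=0, genome_length=600_000, seed=11)
transcripts, truth = synthio.generate_transcriptome(
    truth, n_background=30, seed=11)
degradome = synthio.generate_degradome_library(
    truth, transcripts, signal_reads=50, noise_reads=2_000, seed=11)

mirnas = {pm.locus_id: pm.mature_seq for pm in truth.planted_mirna_loci}
records = targeting.predict_targets(mirnas, transcripts, degradome)
union, intersection = targeting.consensus(records)

planted = {(pt.mirna_id, pt.transcript_id) for pt in truth.planted_target_pairs}
inter_pairs = {r.pair for r in intersection}
print(f"union: {len(union)} pairs; intersection (>=2 methods): "
      f"{len(intersection)}")
print(f"planted pairs recovered in the intersection: "
      f"{len(planted & inter_pairs)}/{len(planted)}")

rec = intersection[0]
print(f"\nexample: {rec.mirna_id} -> {rec.transcript_id}")
print(f"  expectation {rec.expectation:.1f}, energy ratio "
      f"{rec.energy_ratio:.2f}, degradome category {rec.degradome_category}"
      f" (cleavage at transcript position {rec.cleavage_pos})")
print(f"  methods: {sorted(rec.methods)}")
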