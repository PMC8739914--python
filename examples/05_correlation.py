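"""Correlate miRNA and target expression over tissue means.

Replicates are averaged per tissue first, so Pearson r runs over 4
points and significance uses Student's t with 2 degrees of freedom —
p < 0.05 then requires |r| > 0.95, which is why the "strict negative"
fraction (r < -0.9, p < 0.05) is a demanding criterion.
"""

from mirnet import correlation, synthio

_g, truth = synthio.generate_genome_with_hairpins(
    n_mirna=50, n_sirna=0, genome_length=1_500_000, seed=19)
_tx, truth = synthio.generate_transcriptome(
    truth, targets_per_mirna=20, n_background=0, seed=19)
mirna_expr, target_expr = synthio.generate_expression_profiles(
    truth, negative_fraction=0.46, noise_sd=0.02, seed=19)

pairs = [(p.mirna_id, p.transcript_id) for p in truth.planted_target_pairs]
records = correlation.correlate(mirna_expr, target_expr, pairs)

print("correlation sections:", correlation.bin_records(records))
est, hits, total = correlation.negative_fraction(records)
print(f"strict negative fraction (r < -0.9, p < 0.05): "
      f"{100 * est:.1f}%  ({hits}/{total} pairs; planted 46%)")
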