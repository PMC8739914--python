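"""Quantify miRNA abundance across tissues and classify expression patterns.

Reads mapping inside a precursor with 5' ends within 2 nt of the mature
5' end count toward the locus; abundance is reads-per-million. Tissue
means below 10 RPM everywhere are "overall low", above 500 RPM everywhere
"overall high", above 500 somewhere "tissue-specific high".
"""

from mirnet import discovery, expression, srna, synthio

genome, truth = synthio.generate_genome_with_hairpins(
    n_mirna=15, n_sirna=5, genome_length=500_000, seed=5)

tissues = ("root", "stem", "leaf", "flower")
per_lib, samples = {}, {}
for ti, tissue in enumerate(tissues):
    for rep in (1, 2):
        lib = f"{tissue}.R{rep}"
        samples[lib] = (tissue, f"R{rep}")
        per_lib[lib] = synthio.generate_srna_library(
            truth, genome, depth=40_000, seed=100 * ti + rep,
            library_id=lib, tissue=tissue)

merged: dict[str, object] = {}
for lib, stacks in per_lib.items():
    for st in stacks:
        tgt = merged.setdefault(st.sequence, type(st)(st.sequence, {}))
        tgt.per_library_counts[lib] = st.per_library_counts[lib]
stacks = srna.select_prediction_reads(list(merged.values()))
loci, _ = discovery.discover_loci(stacks, genome)

totals = {lib: sum(s.total_count for s in ss) for lib, ss in per_lib.items()}
rpm, raw = expression.quantify_mirna({lib: stacks for lib in per_lib},
                                     loci, totals, samples)
patterns = expression.classify_patterns(rpm)
print("pattern classes:", patterns.value_counts().to_dict())

labels = expression.cluster_profiles(rpm, k=min(6, len(loci)), seed=0)
print("profile clusters:", labels.value_counts().sort_index().to_dict())

de = expression.differential_expression(raw, samples, totals, "root", "flower")
print(f"\nroot vs flower: {int((de['call'] != 'ns').sum())} DE loci "
      f"of {len(de)} (|log2FC| >= 1, BH p < 0.05)")
print(de[de["call"] != "ns"].head()[["log2fc", "p_adj", "call"]])
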