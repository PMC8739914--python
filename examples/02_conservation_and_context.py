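"""Classify miRNA conservation and scan genomic context.

Conservation compares each mature sequence (with +/-1 nt end variants,
up to 2 mismatches) against a reference catalog with species-to-clade
labels; clusters chain loci within 10 kb; synteny blocks come from
collinear homolog-pair anchors.
"""

from mirnet import conservation, context, discovery, srna, synthio

genome, truth = synthio.generate_genome_with_hairpins(
    n_mirna=20, n_sirna=10, genome_length=600_000, seed=3)
stacks = synthio.generate_srna_library(truth, genome, depth=120_000, seed=103)
loci, _ = discovery.discover_loci(srna.select_prediction_reads(stacks), genome)

catalog = synthio.generate_reference_catalog(truth, seed=3)
conservation.classify_all(loci, catalog)
census = conservation.family_census(loci)
print("conservation census:", census["class_counts"])
print(f"{census['n_loci']} loci in {census['n_families']} families")

clusters = context.find_clusters(loci, max_gap=10_000)
print(f"\nmiRNA clusters (<=10 kb gap): {len(clusters)}")
for i, cl in enumerate(clusters, 1):
    print(f"  cluster {i}: {[l.id for l in cl]}")

anchors, planted_blocks = synthio.generate_anchor_table(seed=3)
blocks = context.detect_blocks(anchors, min_anchors=5)
print(f"\nsynteny blocks detected: {len(blocks)} "
      f"(planted: {len(planted_blocks)})")
for b in blocks:
    print(f"  {b.id}: {len(b.anchors)} anchors, {b.orientation}")
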