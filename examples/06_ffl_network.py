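"""Assemble the TF -> miRNA -> target network and enumerate feed-forward
loops.

TMI edges come from PWM hits on miRNA promoters, TTI edges from hits on
target-gene promoters, MTI edges from the targeting consensus. A cascade
chains a TMI to an MTI; an FFL is a cascade whose TF also hits the same
target's promoter.
"""

from mirnet import network, synthio
from mirnet.types import RegulatoryInteraction

pwms, promoters, planted_sites = synthio.generate_tf_motifs_and_promoters(
    n_tfs=5, n_sites=40, n_promoters=20, seed=13)

# first 8 promoters play the role of miRNA promoters, the rest targets
prom_ids = sorted(promoters)
mir_proms = {f"mir-{i}": promoters[p] for i, p in enumerate(prom_ids[:8])}
tgt_proms = {f"gene-{i}": promoters[p] for i, p in enumerate(prom_ids[8:])}

tmi_hits = network.scan_tfbs(mir_proms, pwms)
tti_hits = network.scan_tfbs(tgt_proms, pwms)
mti_pairs = [(f"mir-{i}", f"gene-{j}") for i in range(8) for j in range(12)
             if (i + j) % 3 == 0]  # a toy miRNA-target map
tmi, tti, mti = network.build_tables(tmi_hits, tti_hits, mti_pairs)
cascades, ffls = network.enumerate_motifs(tmi, mti, tti)

print(f"TMI {len(tmi)}, TTI {len(tti)}, MTI {len(mti)}")
print(f"cascades (TF->miRNA->target): {len(cascades)}")
print(f"feed-forward loops (cascade closed by a TF->target edge): {len(ffls)}")

if ffls:
    hub = ffls[0].mirna
    module = network.module_view(ffls, cascades, hub)
    print(f"\nmodule around hub {hub}: {module.number_of_nodes()} nodes, "
          f"{module.number_of_edges()} edges")

graph = network.build_graph(tmi, mti, tti)
paths = network.export_network(graph, "scratch/example_network")
print("exported:", sorted(paths.values()))
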