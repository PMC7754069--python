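"""Generate a synthetic double-minute dataset with known ground truth.

Builds the default study conditions — two circular DM populations at mean
counts 101 and 107 per cell over eleven sub-amplicons — and prints what each
simulated observable contains.
"""

from dmrecon import (
    make_reference,
    make_truth,
    simulate_cn_profile,
    simulate_fish,
    simulate_junction_reads,
    simulate_snp_depths,
)
from dmrecon.config import SimConfig

cfg = SimConfig(seed=1)
genome = make_reference(cfg)
truth = make_truth(cfg)
reads = simulate_junction_reads(truth, cfg, genome)
profile = simulate_cn_profile(truth, cfg)
fish = simulate_fish(truth, cfg)
snps = simulate_snp_depths(cfg)

print("reference contigs:", {c: genome.length(c) for c in genome.names})
for st in truth.structures:
    print(f"{st.id}: {st.n_segments} segments, {st.n_junctions} junctions, "
          f"{st.total_length} bp circle")
print("junctions:", ", ".join(
    f"{j.id}({j.orientation_class}, mh={j.microhomology}, {j.mechanism})"
    for j in truth.junctions))
print(f"{len(reads)} junction-spanning reads, {len(profile)} CN probes, "
      f"{fish['cell_id'].nunique()} FISH cells, {len(snps)} SNP sites")
# The two circles share the H1b-tail/H2a-head junction; the 5000 bp circle
# is the toy analogue of the ~5 Mb population-one molecule.
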