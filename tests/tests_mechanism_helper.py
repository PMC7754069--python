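"""Simulate one random junction of a known repair mechanism and re-call it."""

from __future__ import annotations

import numpy as np

from dmrecon import call_junctions_from_reads, make_reference, make_truth, simulate_junction_reads
from dmrecon.config import SimConfig
from dmrecon.structures import MECH_BLUNT, MECH_MMEJ


def simulate_one(rng: np.random.Generator, mechanism: str) -> bool:
    """Build a random two-segment circle whose first junction has the given
    mechanism; simulate reads, re-call, and report whether the classified
    mechanism matches."""
    if mechanism == MECH_BLUNT:
        mh, insertions = 0, []
    elif mechanism == MECH_MMEJ:
        mh, insertions = int(rng.integers(1, 11)), []
    else:
        mh = int(rng.integers(0, 4))
        insertions = [
            [int(rng.integers(20, 200)), "non_amplified"]
            for _ in range(int(rng.integers(1, 4)))
        ]
    cfg = SimConfig(seed=int(rng.integers(2**31)))
    cfg.contigs = {"cA": 6000}
    cfg.amplicons = [["X", "cA", 500, 1100], ["Y", "cA", 3000, 3600]]
    cfg.populations = {"pop1": [["X", "+"], ["Y", "+"]]}
    cfg.junctions = [
        {"name": "I", "left": ["X", "tail"], "right": ["Y", "head"],
         "mechanism": mechanism, "microhomology": mh, "insertions": insertions},
        {"name": "II", "left": ["Y", "tail"], "right": ["X", "head"],
         "mechanism": MECH_BLUNT, "microhomology": 0, "insertions": []},
    ]
    cfg.mean_dm_counts = {"pop1": 50.0}
    cfg.fish_probes = {"pX": "X", "pY": "Y"}
    cfg.snp_contig = "cA"
    genome = make_reference(cfg)
    truth = make_truth(cfg)
    reads = simulate_junction_reads(truth, cfg, genome)
    segs = []
    for name, s in truth.segments.items():
        s.tier = truth.multiplicity(name)
        segs.append(s)
    calls = call_junctions_from_reads(reads, genome, segments=segs)
    by_key = {j.coordinate_key(): j for j in calls}
    want = truth.junction_by_id("I")
    got = by_key.get(want.coordinate_key())
    return got is not None and got.mechanism == mechanism
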