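"""Synthetic-data generator: determinism, ground truth, observables."""

import numpy as np
import pandas as pd
import pytest

from dmrecon import (
    make_reference,
    make_truth,
    simulate_cn_profile,
    simulate_fish,
    simulate_junction_reads,
    simulate_snp_depths,
)
from dmrecon.config import ConfigError, SimConfig
from dmrecon.structures import revcomp

from helpers import slide_microhomology


def small_circle_config(mh=0, insertions=()):
    """Two non-adjacent amplicons joined into a single 2-segment circle."""
    cfg = SimConfig(seed=7)
    cfg.contigs = {"cA": 4000}
    cfg.amplicons = [["X", "cA", 500, 1100], ["Y", "cA", 2000, 2600]]
    cfg.populations = {"pop1": [["X", "+"], ["Y", "+"]]}
    cfg.junctions = [
        {"name": "I", "left": ["X", "tail"], "right": ["Y", "head"],
         "mechanism": "MMEJ" if mh else "NHEJ-blunt", "microhomology": mh,
         "insertions": [list(i) for i in insertions]},
        {"name": "II", "left": ["Y", "tail"], "right": ["X", "head"],
         "mechanism": "NHEJ-blunt", "microhomology": 0, "insertions": []},
    ]
    cfg.mean_dm_counts = {"pop1": 50.0}
    cfg.fish_probes = {"pX": "X", "pY": "Y"}
    cfg.snp_contig = "cA"
    return cfg


class TestMakeReference:
    def test_configured_lengths_and_alphabet(self):
        cfg = SimConfig(seed=1)
        cfg.contigs = {"chr8_toy": 10000, "chr10_toy": 8000}
        genome = make_reference(cfg, plant=False)
        assert {k: len(v) for k, v in genome.contigs.items()} == cfg.contigs
        assert set("".join(genome.contigs.values())) <= set("ACGT")

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=11)
        assert make_reference(cfg).contigs == make_reference(cfg).contigs

    def test_gc_fraction_unbiased(self):
        cfg = SimConfig(seed=5)
        cfg.contigs = {"chr8_toy": 100000, "chr10_toy": 6000}
        cfg.amplicons = [a for a in cfg.amplicons]
        seq = make_reference(cfg, plant=False).contigs["chr8_toy"]
        n = len(seq)
        gc = sum(seq.count(b) for b in "GC")
        sd = (n * 0.5 * 0.5) ** 0.5
        assert abs(gc - 0.5 * n) < 3 * sd

    def test_zero_length_contig_rejected(self):
        cfg = SimConfig(seed=1)
        cfg.contigs = {"chr8_toy": 0}
        with pytest.raises(ConfigError):
            make_reference(cfg)


class TestMakeTruth:
    def test_population_one_has_three_blocks(self, truth):
        pop1 = next(s for s in truth.structures if s.id == "pop1")
        assert pop1.n_blocks == 3
        assert pop1.n_junctions == 3

    def test_shared_segment_set(self, truth):
        from dmrecon.structures import shared_segments

        assert shared_segments(truth.structures) == {"H1b", "H2a", "H2c", "H3b"}

    def test_single_two_segment_circle(self):
        truth = make_truth(small_circle_config())
        assert len(truth.structures) == 1
        assert truth.structures[0].n_junctions == 2
        assert len(truth.junctions) == 2

    def test_undefined_segment_rejected(self):
        cfg = small_circle_config()
        cfg.populations["pop1"].append(["Z", "+"])
        with pytest.raises(ConfigError):
            make_truth(cfg)

    def test_shared_junction_multiplicity(self, truth):
        assert truth.junction_by_id("IV").multiplicity == 2
        assert all(
            j.multiplicity == 1 for j in truth.junctions if j.id != "IV"
        )


class TestCNProfile:
    def test_baseline_probes_exactly_zero_noiseless(self, noiseless_config, noiseless_profile):
        amp = [(c, s, e) for _, c, s, e in noiseless_config.amplicons]
        mask = np.ones(len(noiseless_profile), bool)
        for contig, s, e in amp:
            mask &= ~(
                (noiseless_profile["contig"] == contig)
                & (noiseless_profile["pos"] >= s)
                & (noiseless_profile["pos"] < e)
            )
        assert (noiseless_profile.loc[mask, "log2"] == 0.0).all()

    def test_shared_minus_specific_level_near_one(self, noiseless_config, noiseless_profile):
        # shared segments carry 101+107 copies; population-specific ones 101
        # or 107 — the expected tier gap is log2(210/2) − log2(mean(103,109)/2)
        def level(contig, s, e):
            sub = noiseless_profile[
                (noiseless_profile["contig"] == contig)
                & (noiseless_profile["pos"] >= s)
                & (noiseless_profile["pos"] < e)
            ]
            return sub["log2"].mean()

        shared = level("chr8_toy", 1600, 2200)  # H1b
        spec1 = level("chr8_toy", 1000, 1600)  # H1a (pop1 only)
        spec2 = level("chr10_toy", 2000, 2500)  # H4a (pop2 only)
        copies = [2.0 * 2.0 ** lv for lv in (spec1, spec2)]  # totals 103, 109
        observed = shared - np.log2(np.mean(copies) / 2)
        expected = np.log2(210 / 2) - np.log2(np.mean([103, 109]) / 2)
        assert observed == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.0, abs=0.02)

    def test_copy_number_conservation_noiseless(self, noiseless_config, noiseless_profile):
        truth = make_truth(noiseless_config)
        for rec in noiseless_profile.sample(300, random_state=0).itertuples():
            expected = 2.0
            for name, seg in truth.segments.items():
                if seg.contig == rec.contig and seg.start <= rec.pos < seg.end:
                    expected += truth.expected_copies(name)
            assert 2.0 * 2.0 ** rec.log2 == pytest.approx(expected, rel=1e-12)

    def test_doubling_abundance_raises_amplified_levels_sublinearly(self):
        cfg = SimConfig(seed=3)
        cfg.log2_noise_sd = 0.0
        base = simulate_cn_profile(make_truth(cfg), cfg)
        cfg2 = SimConfig(seed=3)
        cfg2.log2_noise_sd = 0.0
        cfg2.mean_dm_counts = {"pop1": 202.0, "pop2": 214.0}
        doubled = simulate_cn_profile(make_truth(cfg2), cfg2)
        delta = doubled["log2"] - base["log2"]
        amplified = base["log2"] > 1
        assert (delta[amplified] > 0).all()
        assert (delta[amplified] < 1).all()


class TestJunctionReads:
    def test_blunt_junction_is_exact_flank_concatenation(self):
        cfg = small_circle_config(mh=0)
        genome = make_reference(cfg)
        truth = make_truth(cfg)
        reads = dict(simulate_junction_reads(truth, cfg, genome))
        seq = reads["I|read0"]
        left = genome.fetch("cA", 1100 - cfg.read_flank, 1100)
        right = genome.fetch("cA", 2000, 2000 + cfg.read_flank)
        assert seq == left + right

    def test_mmej_homology_four_gives_five_placements(self):
        cfg = small_circle_config(mh=4)
        genome = make_reference(cfg)
        truth = make_truth(cfg)
        reads = dict(simulate_junction_reads(truth, cfg, genome))
        f = cfg.read_flank
        left = genome.fetch("cA", 1100 - f, 1100)
        left_ext = genome.fetch("cA", 1100, 1100 + 20)
        right = genome.fetch("cA", 2000, 2000 + f)
        right_pre = genome.fetch("cA", 2000 - 20, 2000)
        assert reads["I|read0"] == left + right
        assert slide_microhomology(left, left_ext, right_pre, right) == 4

    def test_fostes_extreme_insertion_lengths_recovered(self):
        cfg = small_circle_config(
            insertions=[[5, "untemplated_genomic"], [679, "non_amplified"]]
        )
        cfg.junctions[0]["mechanism"] = "FoSTeS/MMBIR"
        genome = make_reference(cfg)
        truth = make_truth(cfg)
        simulate_junction_reads(truth, cfg, genome)
        assert [i.length for i in truth.junction_by_id("I").insertions] == [5, 679]

    def test_read_too_short_names_junction(self):
        cfg = small_circle_config(mh=4)
        cfg.read_flank = 5
        genome = make_reference(cfg)
        truth = make_truth(cfg)
        with pytest.raises(ConfigError, match="I"):
            simulate_junction_reads(truth, cfg, genome)

    def test_every_truth_junction_covered(self, truth, reads):
        covered = {rid.split("|")[0] for rid, _ in reads}
        assert covered == {j.id for j in truth.junctions}

    def test_alternate_reads_are_reverse_complemented(self, reads):
        by_id = dict(reads)
        r0, r1 = by_id["I|read0"], by_id["I|read1"]
        assert revcomp(r1) in r0 or r0 in revcomp(r1) or len(r0) != len(r1)


class TestFish:
    def test_zero_cells_gives_empty_table(self, truth, sim_config):
        cfg = SimConfig(seed=1)
        cfg.n_cells = 0
        table = simulate_fish(truth, cfg)
        assert len(table) == 0

    def test_population_two_pattern(self, truth, sim_config):
        table = simulate_fish(truth, sim_config)
        pop2 = table[(table["BAC-H4b"] == 1)]
        assert len(pop2) > 0
        assert (pop2["BAC-H2d"] == 0).all()
        assert (pop2["BAC-H1b"] == 1).all()

    def test_sample_means_close_at_ten_thousand_cells(self, truth):
        cfg = SimConfig(seed=9)
        cfg.n_cells = 10000
        table = simulate_fish(truth, cfg)
        pop2 = table["BAC-H4b"] == 1
        m2 = pop2.sum() / cfg.n_cells
        m1 = (~pop2).sum() / cfg.n_cells
        assert m1 == pytest.approx(101.0, rel=0.01)
        assert m2 == pytest.approx(107.0, rel=0.01)

    def test_unknown_probe_target_rejected(self, truth):
        cfg = SimConfig(seed=1)
        cfg.fish_probes = {"pZ": "nope"}
        with pytest.raises(ConfigError):
            simulate_fish(truth, cfg)


class TestSNPDepths:
    def test_expected_minor_fraction_matches_copy_ratio(self):
        cfg = SimConfig(seed=2)
        cfg.n_snp_sites = 500
        table = simulate_snp_depths(cfg)
        frac = table["ref_depth"].sum() / (
            table["ref_depth"].sum() + table["alt_depth"].sum()
        )
        assert frac == pytest.approx(10 / 1510, rel=0.15)

    def test_equal_copies_give_half_fraction(self):
        cfg = SimConfig(seed=2)
        cfg.chrom_copies = 100
        cfg.dm_copies = 100
        cfg.n_snp_sites = 200
        table = simulate_snp_depths(cfg)
        frac = table["alt_depth"].sum() / (
            table["ref_depth"].sum() + table["alt_depth"].sum()
        )
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_zero_depth_emits_missing_flag(self):
        cfg = SimConfig(seed=2)
        cfg.snp_depth = 0
        table = simulate_snp_depths(cfg)
        assert table["missing"].all()

    def test_negative_copies_rejected(self):
        cfg = SimConfig(seed=2)
        cfg.dm_copies = -1
        with pytest.raises(ConfigError):
            simulate_snp_depths(cfg)


class TestDeterminism:
    def test_all_simulators_reproduce_byte_identical_output(self):
        outs = []
        for _ in range(2):
            cfg = SimConfig(seed=42)
            genome = make_reference(cfg)
            truth = make_truth(cfg)
            reads = simulate_junction_reads(truth, cfg, genome)
            profile = simulate_cn_profile(truth, cfg)
            fish = simulate_fish(truth, cfg)
            snp = simulate_snp_depths(cfg)
            outs.append((genome.contigs, reads, profile, fish, snp))
        assert outs[0][0] == outs[1][0]
        assert outs[0][1] == outs[1][1]
        pd.testing.assert_frame_equal(outs[0][2], outs[1][2])
        pd.testing.assert_frame_equal(outs[0][3], outs[1][3])
        pd.testing.assert_frame_equal(outs[0][4], outs[1][4])
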