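"""Split alignment, junction calling, microhomology and mechanism forensics."""

import numpy as np
import pytest

from dmrecon import (
    call_junction,
    call_junctions_from_reads,
    classify_insertion_origin,
    classify_mechanism,
    detect_insertions,
    locate_split_alignment,
    make_reference,
    make_truth,
    measure_microhomology,
    simulate_junction_reads,
)
from dmrecon.config import SimConfig
from dmrecon.junctions import JunctionError
from dmrecon.structures import (
    Insertion,
    Junction,
    JunctionSide,
    MECH_BLUNT,
    MECH_FOSTES,
    MECH_MMEJ,
    Segment,
    revcomp,
)
from dmrecon.synth import ReferenceGenome

from helpers import slide_microhomology


def random_genome(rng, length=3000, name="cT"):
    return ReferenceGenome(
        {name: "".join(rng.choice(list("ACGT"), size=length))}
    )


class TestSplitAlignment:
    def test_fully_contained_read_single_plus_block(self, genome):
        read = genome.fetch("chr8_toy", 500, 640)
        blocks = locate_split_alignment(read, genome)
        assert len(blocks) == 1
        assert (blocks[0].contig, blocks[0].gstart, blocks[0].gend, blocks[0].strand) \
            == ("chr8_toy", 500, 640, "+")

    def test_sixty_sixty_chimera_splits_at_offset_sixty(self, genome):
        read = genome.fetch("chr8_toy", 400, 460) + genome.fetch("chr10_toy", 4000, 4060)
        blocks = locate_split_alignment(read, genome)
        assert len(blocks) == 2
        assert blocks[0].rend == 60 or blocks[1].rstart == 60

    def test_reverse_complement_read_single_minus_block(self, genome):
        read = revcomp(genome.fetch("chr8_toy", 500, 640))
        blocks = locate_split_alignment(read, genome)
        assert len(blocks) == 1
        assert blocks[0].strand == "-"
        assert (blocks[0].gstart, blocks[0].gend) == (500, 640)

    def test_short_read_rejected(self, genome):
        with pytest.raises(JunctionError):
            locate_split_alignment("ACGT" * 5, genome, min_anchor=20)

    def test_unalignable_read_gives_no_blocks(self, genome):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=50))
        # 50 random bases with a 25 bp anchor are vanishingly unlikely to
        # contain any anchor-length match in an 18 kb genome
        assert locate_split_alignment(read, genome, min_anchor=25) == []


class TestCallJunction:
    def test_abutting_blocks_no_homology_no_insertion(self, genome):
        read = genome.fetch("chr8_toy", 400, 520) + genome.fetch("chr8_toy", 9000, 9120)
        blocks = locate_split_alignment(read, genome)
        j = call_junction(blocks, genome, read)
        assert j.insertions == []
        # random flanks may share a base or two by chance, never many
        assert j.microhomology <= 4

    def test_read_and_reverse_complement_identical_record(self, genome):
        read = genome.fetch("chr8_toy", 400, 520) + genome.fetch("chr10_toy", 4200, 4320)
        j1 = call_junction(locate_split_alignment(read, genome), genome, read)
        rc = revcomp(read)
        j2 = call_junction(locate_split_alignment(rc, genome), genome, rc)
        assert j1.coordinate_key() == j2.coordinate_key()
        assert j1.orientation_class == j2.orientation_class
        assert j1.microhomology == j2.microhomology

    def test_overlapping_blocks_report_homology(self):
        rng = np.random.default_rng(3)
        seq = list("".join(rng.choice(list("ACGT"), size=2000)))
        # plant 3 bp of homology: bases before the right breakpoint equal the
        # left flank's terminus, with disagreement beyond
        seq[1497:1500] = seq[597:600]
        seq[1496] = "A" if seq[596] != "A" else "C"
        seq[600] = "A" if seq[1500] != "A" else "C"
        genome = ReferenceGenome({"cT": "".join(seq)})
        read = genome.fetch("cT", 480, 600) + genome.fetch("cT", 1500, 1620)
        j = call_junction(locate_split_alignment(read, genome), genome, read)
        assert j.microhomology == 3
        assert (j.side1.pos, j.side2.pos) == (600, 1500)


class TestMicrohomology:
    def test_blunt_constructed_junction_zero(self):
        rng = np.random.default_rng(11)
        genome = random_genome(rng)
        seq = list(genome.contigs["cT"])
        seq[1000] = "A" if seq[500] != "A" else "C"  # left extension disagrees
        seq[999] = "A" if seq[499] != "A" else "C"  # right pre disagrees
        genome = ReferenceGenome({"cT": "".join(seq)})
        j = Junction("x", JunctionSide("cT", 500, "-"), JunctionSide("cT", 1000, "+"))
        mh, degenerate = measure_microhomology(j, genome)
        assert (mh, degenerate) == (0, False)

    def test_planted_cat_across_join_gives_three(self):
        rng = np.random.default_rng(12)
        seq = list(random_genome(rng).contigs["cT"])
        seq[497:500] = list("CAT")
        seq[997:1000] = list("CAT")
        seq[996] = "G" if seq[496] != "G" else "T"
        seq[1000] = "G" if seq[500] != "G" else "T"
        genome = ReferenceGenome({"cT": "".join(seq)})
        j = Junction("x", JunctionSide("cT", 500, "-"), JunctionSide("cT", 1000, "+"))
        mh, _ = measure_microhomology(j, genome)
        left = genome.fetch("cT", 400, 500)
        left_ext = genome.fetch("cT", 500, 560)
        right_pre = genome.fetch("cT", 940, 1000)
        right = genome.fetch("cT", 1000, 1100)
        assert mh == slide_microhomology(left, left_ext, right_pre, right) == 3

    def test_degenerate_cap_flagged(self):
        rng = np.random.default_rng(13)
        seq = list(random_genome(rng).contigs["cT"])
        seq[900:1000] = seq[400:500]  # both flanks identical for ≥ max_scan
        genome = ReferenceGenome({"cT": "".join(seq)})
        j = Junction("x", JunctionSide("cT", 500, "-"), JunctionSide("cT", 1000, "+"))
        mh, degenerate = measure_microhomology(j, genome, max_scan=50)
        assert mh == 50 and degenerate

    def test_matches_slide_oracle_on_1000_random_junctions(self):
        rng = np.random.default_rng(99)
        bases = list("ACGT")
        for _ in range(1000):
            seq = list("".join(rng.choice(bases, size=1200)))
            h = int(rng.integers(0, 12))
            if h:
                seq[400 - h : 400] = seq[800 - h : 800]
            genome = ReferenceGenome({"cT": "".join(seq)})
            j = Junction("x", JunctionSide("cT", 800, "-"), JunctionSide("cT", 400, "+"))
            mh, _ = measure_microhomology(j, genome, max_scan=60)
            left = genome.fetch("cT", 700, 800)
            left_ext = genome.fetch("cT", 800, 860)
            right_pre = genome.fetch("cT", 340, 400)
            right = genome.fetch("cT", 400, 500)
            assert mh == slide_microhomology(left, left_ext, right_pre, right)


class TestInsertions:
    def test_simple_junction_empty_list(self, genome):
        read = genome.fetch("chr8_toy", 400, 520) + genome.fetch("chr8_toy", 9000, 9120)
        j = call_junction(locate_split_alignment(read, genome), genome, read)
        assert detect_insertions(j) == []

    def test_twelve_bp_interior_fragment_recovered(self):
        rng = np.random.default_rng(21)
        genome = random_genome(rng, 4000)
        frag = "".join(rng.choice(list("ACGT"), size=12))
        read = genome.fetch("cT", 300, 420) + frag + genome.fetch("cT", 2000, 2120)
        blocks = locate_split_alignment(read, genome)
        j = call_junction(blocks, genome, read)
        ins = detect_insertions(j)
        assert len(ins) == 1
        assert ins[0].length == 12

    def test_simulated_complex_junction_recovers_configured_lengths(
        self, truth, junction_calls
    ):
        want = sorted(i.length for i in truth.junction_by_id("VII").insertions)
        by_key = {j.coordinate_key(): j for j in junction_calls}
        got = by_key[truth.junction_by_id("VII").coordinate_key()]
        assert sorted(i.length for i in got.insertions) == want
        assert min(want) == 5 and max(want) == 679

    def test_amplified_origin_distance_recorded(self, truth, junction_calls):
        by_key = {j.coordinate_key(): j for j in junction_calls}
        vii = by_key[truth.junction_by_id("VII").coordinate_key()]
        dists = sorted(
            i.distance_to_junction
            for i in vii.insertions
            if i.origin_class == "amplified"
        )
        assert dists[0] == 110


class TestInsertionOrigin:
    def test_copy_from_amplified_segment(self, genome, truth):
        segs = []
        for name, s in truth.segments.items():
            s.tier = truth.multiplicity(name)
            segs.append(s)
        ins = Insertion(genome.fetch("chr8_toy", 3300, 3340))  # inside H2a
        out = classify_insertion_origin(ins, genome, segs)
        assert out.origin_class == "amplified"

    def test_copy_from_baseline_region(self, genome, truth):
        segs = list(truth.segments.values())
        ins = Insertion(genome.fetch("chr8_toy", 9000, 9040))
        out = classify_insertion_origin(ins, genome, segs)
        assert out.origin_class == "non-amplified"

    def test_absent_sequence_uncertain(self, genome, truth):
        rng = np.random.default_rng(5)
        ins = Insertion("".join(rng.choice(list("ACGT"), size=40)))
        out = classify_insertion_origin(ins, genome, list(truth.segments.values()))
        assert out.origin_class == "uncertain"

    def test_near_exact_single_mismatch_located(self, genome, truth):
        segs = list(truth.segments.values())
        raw = genome.fetch("chr8_toy", 9100, 9160)
        mutated = ("A" if raw[30] != "A" else "C").join([raw[:30], raw[31:]])
        out = classify_insertion_origin(Insertion(mutated), genome, segs)
        assert out.origin_class == "non-amplified"
        assert out.origin[1] == 9100


class TestMechanism:
    def test_blunt(self):
        j = Junction("x", JunctionSide("c", 1, "-"), JunctionSide("c", 5, "+"))
        assert classify_mechanism(j) == MECH_BLUNT

    def test_mmej(self):
        j = Junction("x", JunctionSide("c", 1, "-"), JunctionSide("c", 5, "+"),
                     microhomology=4)
        assert classify_mechanism(j) == MECH_MMEJ

    def test_fostes_with_templated_insertion(self):
        j = Junction(
            "x", JunctionSide("c", 1, "-"), JunctionSide("c", 5, "+"),
            microhomology=2,
            insertions=[Insertion("A" * 50, origin=("c", 100, 150, "+"),
                                  origin_class="non-amplified")],
        )
        assert classify_mechanism(j) == MECH_FOSTES

    def test_short_or_uncertain_insertions_do_not_trigger_fostes(self):
        j = Junction(
            "x", JunctionSide("c", 1, "-"), JunctionSide("c", 5, "+"),
            microhomology=2,
            insertions=[Insertion("ACG", origin_class="uncertain"),
                        Insertion("A" * 30, origin_class="uncertain")],
        )
        assert classify_mechanism(j) == MECH_MMEJ

    @pytest.mark.parametrize("mechanism", [MECH_BLUNT, MECH_MMEJ, MECH_FOSTES])
    def test_recovery_on_simulated_junctions(self, mechanism):
        """Mechanism recovery on 100 noise-free simulated junctions each."""
        from tests_mechanism_helper import simulate_one

        rng = np.random.default_rng(
            {MECH_BLUNT: 301, MECH_MMEJ: 302, MECH_FOSTES: 303}[mechanism]
        )
        ok = 0
        for _ in range(100):
            ok += simulate_one(rng, mechanism)
        assert ok == 100


class TestOrientation:
    def test_tail_to_head(self):
        j = Junction("x", JunctionSide("c", 100, "-"), JunctionSide("c", 500, "+"))
        assert j.orientation_class == "-/+"

    def test_head_to_head(self):
        j = Junction("x", JunctionSide("c", 100, "+"), JunctionSide("c", 500, "+"))
        assert j.orientation_class == "+/+"

    def test_swapped_sides_canonicalize_to_same_class(self):
        a = Junction("x", JunctionSide("c", 100, "-"), JunctionSide("c", 500, "+"))
        b = Junction("x", JunctionSide("c", 500, "+"), JunctionSide("c", 100, "-"))
        assert a.orientation_class == b.orientation_class == "-/+"

    def test_default_truth_orientation_counts(self, junction_calls):
        counts = {}
        for j in junction_calls:
            counts[j.orientation_class] = counts.get(j.orientation_class, 0) + 1
        assert counts == {"-/+": 3, "+/-": 1, "+/+": 2, "-/-": 2}


class TestRoundTrip:
    def test_truth_breakpoints_recovered_exactly(self, truth, junction_calls):
        want = {j.coordinate_key() for j in truth.junctions}
        got = {j.coordinate_key() for j in junction_calls}
        assert got == want

    def test_microhomologies_recovered_exactly(self, truth, junction_calls):
        truth_by_key = {j.coordinate_key(): j for j in truth.junctions}
        for call in junction_calls:
            assert call.microhomology == truth_by_key[call.coordinate_key()].microhomology

    def test_mechanisms_recovered(self, truth, junction_calls):
        truth_by_key = {j.coordinate_key(): j for j in truth.junctions}
        for call in junction_calls:
            assert call.mechanism == truth_by_key[call.coordinate_key()].mechanism
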