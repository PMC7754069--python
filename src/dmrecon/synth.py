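"""Synthetic double-minute data with known ground truth.

Everything the reconstruction pipeline consumes can be generated here at
desk scale with a fixed seed: a repeat-free toy reference genome, two
circular DM structures over eleven sub-amplicons, a probe-level log2
copy-number profile, junction-spanning reads with configurable microhomology
and templated insertions, per-cell FISH probe-signal tables, and SNP allele
depths reflecting the extreme DM-versus-chromosome copy imbalance.

Microhomology is *planted into the reference*: for each configured junction
the bases immediately preceding the second (canonically ordered) breakpoint
are overwritten with the first segment's terminal bases, and one disagreeing
base is forced beyond the window on both sides.  A junction-spanning read is
then simply the concatenation of the two reference flanks (plus any
configured insertions), and the exact join point is ambiguous over precisely
the configured number of placements — the same ambiguity the caller must
measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .structures import (
    ADJACENCY,
    DMStructure,
    HEAD,
    Insertion,
    Junction,
    JunctionSide,
    Segment,
    SegmentEnd,
    TAIL,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ReferenceGenome:
    """Ordered mapping of contig name to an A/C/G/T nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.contigs) != len(set(self.contigs)):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def names(self) -> list[str]:
        return list(self.contigs)


@dataclass
class GroundTruth:
    """Known DM structures, junction forensics and abundances."""

    structures: list[DMStructure]
    junctions: list[Junction]
    abundances: dict[str, float]
    segments: dict[str, Segment]
    #: junction id -> configured forensic spec (mechanism, microhomology,
    #: insertion length/origin-pool list)
    junction_specs: dict[str, dict]

    def multiplicity(self, segment: str) -> int:
        return sum(
            1 for st in self.structures for s, _ in st.segments if s == segment
        )

    def junction_by_id(self, jid: str) -> Junction:
        for j in self.junctions:
            if j.id == jid:
                return j
        raise KeyError(jid)

    def expected_copies(self, segment: str) -> float:
        """Expected DM-borne copies of a segment (abundance × multiplicity)."""
        total = 0.0
        for st in self.structures:
            mult = sum(1 for s, _ in st.segments if s == segment)
            total += self.abundances[st.id] * mult
        return total


# --------------------------------------------------------------------------
# seed plumbing: one root seed, fixed child order for every simulator
# --------------------------------------------------------------------------

_CHILDREN = ("genome", "cn", "reads", "fish", "snp")


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_CHILDREN))
    return np.random.default_rng(children[_CHILDREN.index(stage)])


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def _exit_end(seg: str, orient: str) -> SegmentEnd:
    return SegmentEnd(seg, TAIL if orient == "+" else HEAD)


def _entry_end(seg: str, orient: str) -> SegmentEnd:
    return SegmentEnd(seg, HEAD if orient == "+" else TAIL)


def _side(end: SegmentEnd, segments: dict[str, Segment]) -> JunctionSide:
    seg = segments[end.segment]
    return JunctionSide(seg.contig, seg.boundary(end.end), end.sign, end.segment)


_POOL_TO_CLASS = {
    "non_amplified": "non-amplified",
    "amplified": "amplified",
    "untemplated": "uncertain",
    "untemplated_genomic": "uncertain",
}


def make_truth(config: SimConfig) -> GroundTruth:
    """Derive the ground-truth structures and junctions from the config.

    Consecutive population segments that are contiguous in the reference and
    traversed in the same direction are joined by reference adjacency; every
    other consecutive pair requires a junction, which must be present in the
    config's junction spec list (an unmatched pair is a configuration error).
    """
    config.validate()
    segments = {
        name: Segment(name, contig, start, end)
        for name, contig, start, end in config.amplicons
    }
    spec_by_ends: dict[frozenset, dict] = {}
    for spec in config.junctions:
        key = frozenset(
            (SegmentEnd(s, e)) for s, e in (spec["left"], spec["right"])
        )
        spec_by_ends[key] = spec

    structures: list[DMStructure] = []
    used: dict[str, int] = {}
    for pop, segs in config.populations.items():
        connectors: list[str] = []
        n = len(segs)
        for i in range(n):
            a, oa = segs[i]
            b, ob = segs[(i + 1) % n]
            e1, e2 = _exit_end(a, oa), _entry_end(b, ob)
            sa, sb = segments[a], segments[b]
            adjacent = (
                sa.contig == sb.contig
                and sa.boundary(e1.end) == sb.boundary(e2.end)
                and e1.end != e2.end
            )
            if adjacent:
                connectors.append(ADJACENCY)
                continue
            key = frozenset((e1, e2))
            if key not in spec_by_ends:
                raise ConfigError(
                    f"population {pop!r} needs a junction spec joining "
                    f"{e1} and {e2}"
                )
            name = spec_by_ends[key]["name"]
            connectors.append(name)
            used[name] = used.get(name, 0) + 1
        st = DMStructure(pop, tuple((s, o) for s, o in segs), tuple(connectors))
        st.compute_length({s.name: s.length for s in segments.values()})
        structures.append(st)

    junctions: list[Junction] = []
    specs: dict[str, dict] = {}
    for spec in config.junctions:
        name = spec["name"]
        if name not in used:
            raise ConfigError(f"junction spec {name!r} is not used by any population")
        e_left = SegmentEnd(*spec["left"])
        e_right = SegmentEnd(*spec["right"])
        ins = [
            Insertion("N" * int(length), origin_class=_POOL_TO_CLASS.get(
                pool if isinstance(pool, str) else "amplified", "uncertain"))
            for length, pool in spec["insertions"]
        ]
        junctions.append(
            Junction(
                id=name,
                side1=_side(e_left, segments),
                side2=_side(e_right, segments),
                microhomology=int(spec["microhomology"]),
                insertions=ins,
                mechanism=spec["mechanism"],
                multiplicity=used[name],
            )
        )
        specs[name] = spec

    abundances = {
        pop: float(config.mean_dm_counts.get(pop, 0.0)) for pop in config.populations
    }
    return GroundTruth(structures, junctions, abundances, segments, specs)


# --------------------------------------------------------------------------
# reference genome with planted junction homology
# --------------------------------------------------------------------------

class _FlankCursor:
    """Base-level access to the reference around a junction side.

    Offsets are measured along the junction product: negative offsets walk
    away from the join into (or before) the segment, positive offsets walk
    beyond it.  ``exiting`` sides supply the sequence *ending* at the join,
    ``entering`` sides the sequence starting after it.
    """

    def __init__(self, genome: dict[str, list[str]], side: JunctionSide, exiting: bool):
        self.seq = genome[side.contig]
        self.side = side
        self.exiting = exiting

    def _coord(self, offset: int) -> tuple[int, bool]:
        """Return (position, complement?) for a product offset (≠ 0)."""
        b, kind = self.side.pos, self.side.end
        if offset == 0:
            raise ValueError("offset 0 is undefined")
        j = abs(offset)
        if self.exiting:
            before = offset < 0  # inside the flank
            if kind == TAIL:
                return (b - j, False) if before else (b + j - 1, False)
            return (b + j - 1, True) if before else (b - j, True)
        before = offset < 0  # pre-region, outside the flank
        if kind == HEAD:
            return (b - j, False) if before else (b + j - 1, False)
        return (b + j - 1, True) if before else (b - j, True)

    def get(self, offset: int) -> str:
        pos, comp = self._coord(offset)
        base = self.seq[pos]
        return _COMP[base] if comp else base

    def set(self, offset: int, base: str) -> None:
        pos, comp = self._coord(offset)
        self.seq[pos] = _COMP[base] if comp else base


def _different_base(avoid: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != avoid]
    return options[int(rng.integers(len(options)))]


def _plant_junction(genome: dict[str, list[str]], junction: Junction,
                    rng: np.random.Generator) -> None:
    h = junction.microhomology
    left = _FlankCursor(genome, junction.side1, exiting=True)
    right = _FlankCursor(genome, junction.side2, exiting=False)
    for j in range(1, h + 1):
        right.set(-j, left.get(-j))
    if right.get(-(h + 1)) == left.get(-(h + 1)):
        right.set(-(h + 1), _different_base(left.get(-(h + 1)), rng))
    if left.get(1) == right.get(1):
        left.set(1, _different_base(right.get(1), rng))


def _measure_planted(genome: dict[str, list[str]], junction: Junction,
                     limit: int = 64) -> int:
    left = _FlankCursor(genome, junction.side1, exiting=True)
    right = _FlankCursor(genome, junction.side2, exiting=False)
    m = 0
    while m < limit and right.get(-(m + 1)) == left.get(-(m + 1)):
        m += 1
    k = 0
    while k < limit and left.get(k + 1) == right.get(k + 1):
        k += 1
    return m + k


def make_reference(config: SimConfig, plant: bool = True) -> ReferenceGenome:
    """Generate the toy reference: i.i.d. uniform bases, junction homology planted.

    Deterministic given the config seed.  With ``plant=False`` the raw random
    genome is returned (useful for null experiments).
    """
    config.validate()
    rng = _rng(config, "genome")
    contigs: dict[str, list[str]] = {}
    for name, length in config.contigs.items():
        if length <= 0:
            raise ConfigError(f"contig {name!r} has non-positive length")
        draw = rng.integers(0, 4, size=int(length))
        contigs[name] = list(_BASES[draw].tobytes().decode())
    if plant and config.junctions:
        truth = make_truth(config)
        # junctions may share reference bases near a common segment end
        # (e.g. two junctions flanking the same boundary): plant to fixpoint
        for _ in range(8):
            for j in truth.junctions:
                _plant_junction(contigs, j, rng)
            if all(
                _measure_planted(contigs, j) == j.microhomology
                for j in truth.junctions
            ):
                break
        else:
            bad = [
                j.id for j in truth.junctions
                if _measure_planted(contigs, j) != j.microhomology
            ]
            raise ConfigError(
                f"could not plant consistent microhomology for junctions {bad}"
            )
    return ReferenceGenome({name: "".join(seq) for name, seq in contigs.items()})


# --------------------------------------------------------------------------
# copy-number profile
# --------------------------------------------------------------------------

def simulate_cn_profile(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Probe-level log2 ratios: log2((2 + Σ abundance×multiplicity)/2) + noise.

    Probes sit on a half-spacing offset grid (spacing/2, 3·spacing/2, …) so
    that true change positions fall midway between flanking probes.
    """
    if config.probe_spacing <= 0:
        raise ConfigError("probe_spacing must be positive")
    rng = _rng(config, "cn")
    rows = []
    for contig, length in config.contigs.items():
        pos = np.arange(config.probe_spacing // 2, length, config.probe_spacing)
        copies = np.full(pos.shape, 2.0)
        for st in truth.structures:
            ab = truth.abundances[st.id]
            for name, _ in st.segments:
                seg = truth.segments[name]
                if seg.contig != contig:
                    continue
                copies[(pos >= seg.start) & (pos < seg.end)] += ab
        log2 = np.log2(copies / 2.0)
        if config.log2_noise_sd > 0:
            log2 = log2 + rng.normal(0.0, config.log2_noise_sd, size=pos.shape)
        rows.append(pd.DataFrame({"contig": contig, "pos": pos, "log2": log2}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# junction-spanning reads
# --------------------------------------------------------------------------

def _flank_sequence(genome: ReferenceGenome, side: JunctionSide, length: int,
                    exiting: bool) -> str:
    b = side.pos
    if exiting:
        if side.end == TAIL:
            return genome.fetch(side.contig, b - length, b)
        return revcomp(genome.fetch(side.contig, b, b + length))
    if side.end == HEAD:
        return genome.fetch(side.contig, b, b + length)
    return revcomp(genome.fetch(side.contig, b - length, b))


def _amplified_intervals(truth: GroundTruth) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for seg in truth.segments.values():
        out.setdefault(seg.contig, []).append((seg.start, seg.end))
    for ivs in out.values():
        ivs.sort()
    return out


def _in_amplified(amp: dict, contig: str, start: int, end: int) -> bool:
    return any(start >= s and end <= e for s, e in amp.get(contig, []))


def _overlaps_amplified(amp: dict, contig: str, start: int, end: int) -> bool:
    return any(start < e and end > s for s, e in amp.get(contig, []))


def _sample_origin(rng: np.random.Generator, genome: ReferenceGenome,
                   amp: dict, length: int, pool) -> tuple[str, int, str]:
    """Pick (contig, start, strand) for a templated fragment."""
    if isinstance(pool, (list, tuple)):
        contig, start = pool
        return contig, int(start), "+"
    names = genome.names
    for _ in range(1000):
        contig = names[int(rng.integers(len(names)))]
        limit = genome.length(contig) - length
        if limit <= 0:
            continue
        start = int(rng.integers(limit))
        inside = _in_amplified(amp, contig, start, start + length)
        touches = _overlaps_amplified(amp, contig, start, start + length)
        if pool == "amplified" and not inside:
            continue
        if pool in ("non_amplified", "untemplated_genomic") and touches:
            continue
        strand = "+" if rng.integers(2) == 0 else "-"
        return contig, start, strand
    raise ConfigError(f"could not sample an insertion origin from pool {pool!r}")


class _Element:
    """One piece of a junction read: a flank, or an inserted fragment."""

    def __init__(self, seq: str, origin=None, mutable=False, pinned=False,
                 pre_base: Optional[str] = None, cont_base: Optional[str] = None):
        self.seq = seq
        self.origin = origin  # (contig, start, end, strand) or None
        self.mutable = mutable  # untemplated: bases may be adjusted
        self.pinned = pinned  # origin fixed by configuration
        self.pre_base = pre_base  # reference base preceding this element
        self.cont_base = cont_base  # reference base continuing past it


def _element_for_origin(genome: ReferenceGenome, contig: str, start: int,
                        length: int, strand: str) -> _Element:
    raw = genome.fetch(contig, start, start + length)
    seq = raw if strand == "+" else revcomp(raw)
    glen = genome.length(contig)
    if strand == "+":
        pre = genome.fetch(contig, start - 1, start) if start > 0 else None
        cont = (genome.fetch(contig, start + length, start + length + 1)
                if start + length < glen else None)
    else:
        pre = (_COMP[genome.fetch(contig, start + length, start + length + 1)]
               if start + length < glen else None)
        cont = _COMP[genome.fetch(contig, start - 1, start)] if start > 0 else None
    return _Element(seq, (contig, start, start + length, strand),
                    pre_base=pre, cont_base=cont)


def _fix_boundaries(elements: list[_Element], rng: np.random.Generator) -> list[int]:
    """Stop exact-match blocks from sliding across element boundaries.

    For adjacent elements X→Y, the reference continuation of X must differ
    from Y's first base and X's last base must differ from the reference
    base preceding Y — otherwise a maximal-match aligner would extend one
    block into the other and the recovered insertion lengths would be
    ill-defined.  Untemplated fragments are edited in place; templated
    fragments that violate the property are reported for resampling.
    """
    if len(elements) == 2:
        # flank-to-flank joins carry planted (dis)agreement already; any
        # flank overlap there IS the microhomology and must survive
        return []
    bad: set[int] = set()
    n = len(elements)

    def blame(k1: int, k2: int) -> None:
        # pick a resampleable insertion (not a flank, not pinned)
        for k in (k1, k2):
            if 0 < k < n - 1 and not elements[k].pinned:
                bad.add(k)
                return
        raise ConfigError(
            "pinned insertion origin abuts matching reference sequence; "
            "choose another locus"
        )

    for k, (x, y) in enumerate(zip(elements, elements[1:])):
        if x.cont_base is not None and x.cont_base == y.seq[0]:
            if y.mutable:
                y.seq = _different_base_pair(y.seq, 0, x.cont_base, rng)
            else:
                blame(k + 1, k)
        if y.pre_base is not None and x.seq[-1] == y.pre_base:
            if x.mutable:
                x.seq = _different_base_pair(x.seq, len(x.seq) - 1, y.pre_base, rng)
            else:
                blame(k, k + 1)
    return sorted(bad)


def _different_base_pair(seq: str, idx: int, avoid: str, rng: np.random.Generator) -> str:
    new = _different_base(avoid, rng)
    return seq[:idx] + new + seq[idx + 1:]


def simulate_junction_reads(
    truth: GroundTruth, config: SimConfig, genome: ReferenceGenome
) -> list[tuple[str, str]]:
    """Simulate junction-spanning reads for every truth junction.

    Each read is left flank + configured insertions + right flank, in the
    junction's canonical orientation; alternate copies are emitted
    reverse-complemented.  Truth junction records are updated in place with
    the sampled insertion sequences and origins.  Returns ``(read_id,
    sequence)`` pairs with the truth junction id embedded in the read id.
    """
    rng = _rng(config, "reads")
    amp = _amplified_intervals(truth)
    reads: list[tuple[str, str]] = []
    for junction in truth.junctions:
        spec = truth.junction_specs[junction.id]
        h = junction.microhomology
        longest = max((int(l) for l, _ in spec["insertions"]), default=0)
        total_ins = sum(int(l) for l, _ in spec["insertions"])
        flank = config.read_flank
        read_len = 2 * flank + total_ins
        if read_len <= 2 * h + longest or flank <= h + 1:
            raise ConfigError(
                f"read length too short for junction {junction.id!r}: "
                f"flank {flank} vs microhomology {h} and insertion {longest}"
            )
        left = _FlankCursor(
            {c: list(s) for c, s in genome.contigs.items()}, junction.side1, True
        )
        right = _FlankCursor(
            {c: list(s) for c, s in genome.contigs.items()}, junction.side2, False
        )
        elements: list[_Element] = []
        f1 = _flank_sequence(genome, junction.side1, flank, exiting=True)
        elements.append(_Element(f1, cont_base=left.get(1)))
        sampled: list[Insertion] = []
        for length, pool in spec["insertions"]:
            length = int(length)
            if isinstance(pool, str) and pool == "untemplated":
                draw = rng.integers(0, 4, size=length)
                elements.append(
                    _Element(_BASES[draw].tobytes().decode(), mutable=True)
                )
            else:
                contig, start, strand = _sample_origin(rng, genome, amp, length, pool)
                el = _element_for_origin(genome, contig, start, length, strand)
                el.pinned = isinstance(pool, (list, tuple))
                elements.append(el)
        f2 = _flank_sequence(genome, junction.side2, flank, exiting=False)
        elements.append(_Element(f2, pre_base=right.get(-1)))
        specs = list(spec["insertions"])
        for _ in range(60):
            bad = _fix_boundaries(elements, rng)
            if not bad:
                break
            for idx in bad:
                length, pool = specs[idx - 1]
                if isinstance(pool, (list, tuple)):
                    raise ConfigError(
                        f"pinned insertion origin at junction {junction.id!r} "
                        "abuts matching reference sequence; choose another locus"
                    )
                contig, start, strand = _sample_origin(
                    rng, genome, amp, int(length), pool
                )
                elements[idx] = _element_for_origin(
                    genome, contig, start, int(length), strand
                )
        else:
            raise ConfigError(
                f"could not sample boundary-clean insertions for junction {junction.id!r}"
            )
        for el, (length, pool) in zip(elements[1:-1], spec["insertions"]):
            pool_name = pool if isinstance(pool, str) else "amplified"
            sampled.append(
                Insertion(el.seq, origin=el.origin,
                          origin_class=_POOL_TO_CLASS.get(pool_name, "amplified"))
            )
        junction.insertions = sampled
        body = "".join(el.seq for el in elements[1:-1])
        for k in range(config.reads_per_junction):
            lf = elements[0].seq[min(7 * k, flank - 2 * h - 40):] if k else elements[0].seq
            rf = elements[-1].seq[: flank - min(3 * k, flank - 2 * h - 40)] if k else elements[-1].seq
            seq = lf + body + rf
            if k % 2 == 1:
                seq = revcomp(seq)
            reads.append((f"{junction.id}|read{k}", seq))
    return reads


# --------------------------------------------------------------------------
# FISH tables
# --------------------------------------------------------------------------

def simulate_fish(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Per-cell, per-DM boolean probe signals.

    DM counts per cell are Poisson with the configured population means;
    each simulated DM is positive exactly for probes whose target segment
    belongs to its structure.
    """
    probes = dict(config.fish_probes)
    known = set(truth.segments)
    for probe, seg in probes.items():
        if seg not in known:
            raise ConfigError(f"FISH probe {probe!r} maps to unknown segment {seg!r}")
    rng = _rng(config, "fish")
    probe_names = list(probes)
    patterns = {
        st.id: [int(probes[p] in {s for s, _ in st.segments}) for p in probe_names]
        for st in truth.structures
    }
    n_cells = int(config.n_cells)
    cell_ids: list[str] = []
    dm_ids: list[str] = []
    pattern_rows: list[list[int]] = []
    counts = {
        st.id: rng.poisson(truth.abundances[st.id], size=n_cells)
        for st in truth.structures
    }
    for c in range(n_cells):
        k = 0
        for st in truth.structures:
            for _ in range(int(counts[st.id][c])):
                cell_ids.append(f"cell{c}")
                dm_ids.append(f"cell{c}_dm{k}")
                pattern_rows.append(patterns[st.id])
                k += 1
    table = pd.DataFrame(pattern_rows, columns=probe_names, dtype=int)
    table.insert(0, "dm_id", dm_ids)
    table.insert(0, "cell_id", cell_ids)
    return table


# --------------------------------------------------------------------------
# SNP allele depths
# --------------------------------------------------------------------------

def simulate_snp_depths(config: SimConfig) -> pd.DataFrame:
    """Allele depths at germline-heterozygous sites inside amplified regions.

    Each site carries one allele on the chromosomes (``chrom_copies``) and
    the other on the DMs (``dm_copies``); read depth splits binomially with
    DM-allele probability dm/(dm+chrom).  A depth of zero yields a row with
    the missing-data flag set.
    """
    config.validate()
    if config.snp_depth < 0:
        raise ConfigError("snp_depth must be non-negative")
    total = config.dm_copies + config.chrom_copies
    if total <= 0:
        raise ConfigError("at least one allele copy is required")
    rng = _rng(config, "snp")
    intervals = [
        (start, end)
        for name, contig, start, end in config.amplicons
        if contig == config.snp_contig
    ]
    if not intervals:
        raise ConfigError(f"no amplicons on SNP contig {config.snp_contig!r}")
    lengths = np.array([e - s for s, e in intervals], dtype=float)
    p_dm = config.dm_copies / total
    rows = []
    positions: set[int] = set()
    alleles = "ACGT"
    for _ in range(int(config.n_snp_sites)):
        for _ in range(1000):
            which = rng.choice(len(intervals), p=lengths / lengths.sum())
            s, e = intervals[which]
            pos = int(rng.integers(s, e))
            if pos not in positions:
                positions.add(pos)
                break
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
        depth = int(config.snp_depth)
        if depth == 0:
            rows.append((config.snp_contig, pos, alleles[ref_i], alleles[alt_i],
                         0, 0, True))
            continue
        dm_depth = int(rng.binomial(depth, p_dm))
        rows.append((config.snp_contig, pos, alleles[ref_i], alleles[alt_i],
                     depth - dm_depth, dm_depth, False))
    frame = pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "ref_depth", "alt_depth", "missing"],
    )
    return frame.sort_values(["contig", "pos"], ignore_index=True)
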