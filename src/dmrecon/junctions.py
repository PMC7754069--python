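"""Rearrangement-junction calling and repair-mechanism forensics.

Junction-spanning reads are split-aligned against the repeat-free toy
reference by maximal exact matching (both strands), adjacent aligned blocks
define junctions, and each junction is characterised by:

* **microhomology** — the length of the window over which the join point can
  slide while reproducing the same joined sequence (number of valid
  placements minus one), measured on the reference flanks;
* **insertions** — read intervals between the two flank blocks, with a
  templated origin where the sequence maps uniquely (exactly or near-exactly)
  back to the reference;
* **mechanism** — templated insertions ≥ 5 bp indicate replication-based
  repair (FoSTeS/MMBIR); otherwise microhomology ≥ 1 bp indicates MMEJ and
  a clean join indicates blunt-end NHEJ;
* **orientation class** — −/+ (tail-to-head), +/− (head-to-tail),
  +/+ (head-to-head) or −/− (tail-to-tail), read off the canonicalized
  record so a read and its reverse complement agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .structures import (
    HEAD,
    Insertion,
    Junction,
    JunctionSide,
    MECH_BLUNT,
    MECH_FOSTES,
    MECH_MMEJ,
    Segment,
    TAIL,
    natural_key,
    revcomp,
)
from .synth import ReferenceGenome


class JunctionError(ValueError):
    pass


class UnalignedReadError(JunctionError):
    pass


@dataclass
class AlignedBlock:
    """A maximal exact match between a read interval and the reference."""

    contig: str
    gstart: int
    gend: int
    strand: str
    rstart: int
    rend: int
    ambiguous: bool = False  # the matched sequence occurs more than once

    @property
    def length(self) -> int:
        return self.rend - self.rstart


# --------------------------------------------------------------------------
# split alignment by maximal exact matching
# --------------------------------------------------------------------------

def _occurrences(genome: ReferenceGenome, pattern: str, limit: int = 2):
    """Up to ``limit`` occurrences of pattern on either strand."""
    hits = []
    rc = revcomp(pattern)
    for contig, seq in genome.contigs.items():
        for pat, strand in ((pattern, "+"), (rc, "-")):
            at = seq.find(pat)
            while at != -1:
                hits.append((contig, at, strand))
                if len(hits) >= limit:
                    return hits
                at = seq.find(pat, at + 1)
    return hits


def _max_match_length(genome: ReferenceGenome, read: str, i: int) -> int:
    """Longest L such that read[i:i+L] occurs somewhere in the genome."""
    lo, hi = 0, len(read) - i
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _occurrences(genome, read[i : i + mid], limit=1):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _extend_left(genome: ReferenceGenome, read: str, block: AlignedBlock) -> AlignedBlock:
    seq = genome.contigs[block.contig]
    if block.strand == "+":
        while block.rstart > 0 and block.gstart > 0 and read[block.rstart - 1] == seq[block.gstart - 1]:
            block.rstart -= 1
            block.gstart -= 1
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        glen = len(seq)
        while block.rstart > 0 and block.gend < glen and read[block.rstart - 1] == comp[seq[block.gend]]:
            block.rstart -= 1
            block.gend += 1
    return block


def locate_split_alignment(
    read: str, genome: ReferenceGenome, min_anchor: int = 20
) -> list[AlignedBlock]:
    """Maximal exact-match blocks covering the read, ordered by read offset.

    Blocks shorter than ``min_anchor`` are not seeded (unmatched read
    stretches become insertion candidates downstream), but every block is
    extended leftwards to its maximal extent so that microhomologous
    overlaps between adjacent blocks are preserved.
    """
    read = read.upper()
    if len(read) < 2 * min_anchor:
        raise JunctionError(
            f"read of length {len(read)} is shorter than 2×min_anchor ({2 * min_anchor})"
        )
    blocks: list[AlignedBlock] = []
    i = 0
    n = len(read)
    while i <= n - min_anchor:
        length = _max_match_length(genome, read, i)
        if length < min_anchor:
            i += 1
            continue
        hits = _occurrences(genome, read[i : i + length], limit=3)
        hits.sort(key=lambda h: (natural_key(h[0]), h[1], h[2]))
        contig, at, strand = hits[0]
        block = AlignedBlock(
            contig=contig,
            gstart=at,
            gend=at + length,
            strand=strand,
            rstart=i,
            rend=i + length,
            ambiguous=len(hits) > 1,
        )
        _extend_left(genome, read, block)
        blocks.append(block)
        i = block.rend
    return blocks


# --------------------------------------------------------------------------
# junction calling
# --------------------------------------------------------------------------

def _exit_side(block: AlignedBlock) -> JunctionSide:
    """The segment end a left flank exits through."""
    if block.strand == "+":
        return JunctionSide(block.contig, block.gend, "-")
    return JunctionSide(block.contig, block.gstart, "+")


def _entry_side(block: AlignedBlock) -> JunctionSide:
    """The segment end a right flank enters through."""
    if block.strand == "+":
        return JunctionSide(block.contig, block.gstart, "+")
    return JunctionSide(block.contig, block.gend, "-")


def _flip_blocks(blocks: Sequence[AlignedBlock], read_len: int) -> list[AlignedBlock]:
    flipped = [
        AlignedBlock(
            contig=b.contig,
            gstart=b.gstart,
            gend=b.gend,
            strand="-" if b.strand == "+" else "+",
            rstart=read_len - b.rend,
            rend=read_len - b.rstart,
            ambiguous=b.ambiguous,
        )
        for b in reversed(blocks)
    ]
    return flipped


def call_junction(
    blocks: Sequence[AlignedBlock],
    genome: ReferenceGenome,
    read: str,
    read_id: Optional[str] = None,
    max_scan: int = 50,
) -> Junction:
    """Build a canonical junction record from a split-aligned read.

    The first and last blocks are the junction flanks; interior read
    intervals (aligned or not) become ordered insertion candidates, as in
    complex replication-mediated junctions.  The record is canonicalized so
    that the read and its reverse complement give identical output, and the
    join point is placed at the maximal extension of the canonically first
    flank.
    """
    if len(blocks) < 2:
        raise JunctionError("at least two aligned blocks are required")
    read = read.upper()
    left_side = _exit_side(blocks[0])
    right_side = _entry_side(blocks[-1])
    if right_side.sort_key() < left_side.sort_key():
        blocks = _flip_blocks(blocks, len(read))
        read = revcomp(read)
        left_side = _exit_side(blocks[0])
        right_side = _entry_side(blocks[-1])

    # assign any read overlap between the flanks to the first flank
    ov = max(0, blocks[-2].rend - blocks[-1].rstart)
    last = blocks[-1]
    if last.strand == "+":
        right_side = replace(right_side, pos=last.gstart + ov)
    else:
        right_side = replace(right_side, pos=last.gend - ov)

    insertions: list[Insertion] = []
    cursor = blocks[0].rend
    for b in blocks[1:-1]:
        if b.rstart > cursor:
            insertions.append(Insertion(read[cursor : b.rstart]))
        origin = None if b.ambiguous else (b.contig, b.gstart, b.gend, b.strand)
        insertions.append(Insertion(read[b.rstart : b.rend], origin=origin))
        cursor = max(cursor, b.rend)
    if blocks[-1].rstart > cursor:
        insertions.append(Insertion(read[cursor : blocks[-1].rstart]))

    junction = Junction(
        id="",
        side1=left_side,
        side2=right_side,
        insertions=insertions,
        supporting_reads=[read_id] if read_id else [],
    )
    mh, degenerate = measure_microhomology(junction, genome, max_scan=max_scan)
    junction.microhomology = mh
    junction.mh_degenerate = degenerate
    return junction


# --------------------------------------------------------------------------
# microhomology on the reference flanks
# --------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _flank_base(genome: ReferenceGenome, side: JunctionSide, exiting: bool,
                offset: int) -> Optional[str]:
    """Reference base at a product offset around a junction side.

    Negative offsets walk into the flank (exiting side) or its pre-region
    (entering side); positive offsets walk beyond the join.  Returns None
    outside contig bounds.
    """
    seq = genome.contigs[side.contig]
    b, kind = side.pos, side.end
    j = abs(offset)
    before = offset < 0
    if exiting:
        pos, comp = ((b - j, False) if kind == TAIL else (b + j - 1, True)) if before \
            else ((b + j - 1, False) if kind == TAIL else (b - j, True))
    else:
        pos, comp = ((b - j, False) if kind == HEAD else (b + j - 1, True)) if before \
            else ((b + j - 1, False) if kind == HEAD else (b - j, True))
    if pos < 0 or pos >= len(seq):
        return None
    base = seq[pos]
    return _COMP[base] if comp else base


def measure_microhomology(
    junction: Junction, genome: ReferenceGenome, max_scan: int = 50
) -> tuple[int, bool]:
    """Length of the maximal join-slide window at a junction.

    Counts how far the two reference flanks agree across the join in each
    direction; the total equals the number of valid join-point placements
    minus one.  Capped at ``max_scan`` with a degenerate flag.
    """
    m = 0
    while m < max_scan:
        a = _flank_base(genome, junction.side1, True, -(m + 1))
        b = _flank_base(genome, junction.side2, False, -(m + 1))
        if a is None or b is None or a != b:
            break
        m += 1
    k = 0
    while m + k < max_scan:
        a = _flank_base(genome, junction.side1, True, k + 1)
        b = _flank_base(genome, junction.side2, False, k + 1)
        if a is None or b is None or a != b:
            break
        k += 1
    total = m + k
    return min(total, max_scan), total >= max_scan


# --------------------------------------------------------------------------
# insertion origin and mechanism
# --------------------------------------------------------------------------

def detect_insertions(junction: Junction) -> list[Insertion]:
    """Ordered read intervals between the two flank blocks of a junction."""
    return list(junction.insertions)


def _near_exact_hits(genome: ReferenceGenome, pattern: str, allowed: int):
    """Loci matching pattern with at most ``allowed`` mismatches, both strands."""
    hits = []
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(pattern).encode(), dtype=np.uint8)
    m = len(pattern)
    for contig, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        if n < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        for p, strand in ((pat, "+"), (rc, "-")):
            mism = (windows != p).sum(axis=1)
            for at in np.nonzero(mism <= allowed)[0]:
                hits.append((int(mism[at]), contig, int(at), strand))
    return hits


def classify_insertion_origin(
    insertion: Insertion,
    genome: ReferenceGenome,
    segments: Sequence[Segment],
    junction: Optional[Junction] = None,
    mismatch_per_50bp: int = 1,
    min_length: int = 5,
) -> Insertion:
    """Assign an origin class to an inserted fragment.

    A unique exact or near-exact hit (≤ ``mismatch_per_50bp`` mismatches per
    50 bp) inside a tier≥1 segment is ``amplified``; a unique hit elsewhere
    is ``non-amplified``; no hit, multiple equally good hits, or a fragment
    shorter than ``min_length`` is ``uncertain``.
    """
    m = insertion.length
    if insertion.origin is None:
        if m < min_length:
            insertion.origin_class = "uncertain"
            return insertion
        allowed = (mismatch_per_50bp * m) // 50
        hits = _near_exact_hits(genome, insertion.sequence, allowed)
        if not hits:
            insertion.origin_class = "uncertain"
            return insertion
        best = min(h[0] for h in hits)
        top = [h for h in hits if h[0] == best]
        if len(top) > 1:
            insertion.origin_class = "uncertain"
            insertion.origin = None
            return insertion
        _, contig, at, strand = top[0]
        insertion.origin = (contig, at, at + m, strand)
    contig, ostart, oend, _ = insertion.origin
    amplified = any(
        s.contig == contig and ostart < s.end and oend > s.start
        for s in segments
        if s.tier is not None and s.tier >= 1
    )
    insertion.origin_class = "amplified" if amplified else "non-amplified"
    if junction is not None:
        dists = [
            max(0, ostart - side.pos, side.pos - oend)
            for side in (junction.side1, junction.side2)
            if side.contig == contig
        ]
        insertion.distance_to_junction = min(dists) if dists else None
    return insertion


def classify_mechanism(
    junction: Junction,
    fostes_min_insertion: int = 5,
    mmej_min_homology: int = 1,
) -> str:
    """Infer the repair mechanism from microhomology and insertions.

    Any templated insertion of ≥ ``fostes_min_insertion`` bp with a
    determinate origin indicates replication-based repair (FoSTeS/MMBIR);
    otherwise flank microhomology of at least ``mmej_min_homology`` bp
    indicates MMEJ, and a clean join blunt-end NHEJ.
    """
    templated = any(
        ins.length >= fostes_min_insertion
        and ins.origin_class in ("amplified", "non-amplified")
        for ins in junction.insertions
    )
    if templated:
        junction.mechanism = MECH_FOSTES
    elif junction.microhomology >= mmej_min_homology:
        junction.mechanism = MECH_MMEJ
    else:
        junction.mechanism = MECH_BLUNT
    return junction.mechanism


def orientation_class(junction: Junction) -> str:
    """The canonical end-sign pair: −/+, +/−, +/+ or −/−."""
    return junction.orientation_class


# --------------------------------------------------------------------------
# read sets → grouped junction calls
# --------------------------------------------------------------------------

def _roman(n: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def call_junctions_from_reads(
    reads: Iterable[tuple[str, str]],
    genome: ReferenceGenome,
    segments: Optional[Sequence[Segment]] = None,
    min_anchor: int = 20,
    max_scan: int = 50,
    fostes_min_insertion: int = 5,
    mmej_min_homology: int = 1,
    mismatch_per_50bp: int = 1,
) -> list[Junction]:
    """Call, deduplicate, and classify junctions from a read set.

    Reads aligning in a single block carry no rearrangement and are
    dropped; reads with no anchor-length match raise
    :class:`UnalignedReadError`.  Calls sharing breakpoint coordinates are
    merged; ids are Roman numerals assigned in genomic order.
    """
    grouped: dict[tuple, Junction] = {}
    for read_id, seq in reads:
        blocks = locate_split_alignment(seq, genome, min_anchor=min_anchor)
        if not blocks:
            raise UnalignedReadError(f"read {read_id!r} has no {min_anchor} bp anchor")
        if len(blocks) == 1:
            continue
        call = call_junction(blocks, genome, seq, read_id=read_id, max_scan=max_scan)
        key = call.coordinate_key()
        if key in grouped:
            kept = grouped[key]
            kept.supporting_reads.extend(call.supporting_reads)
            if sum(i.length for i in call.insertions) > sum(
                i.length for i in kept.insertions
            ):
                kept.insertions = call.insertions
        else:
            grouped[key] = call
    calls = [grouped[k] for k in sorted(grouped)]
    for k, junction in enumerate(calls):
        junction.id = _roman(k + 1)
        for ins in junction.insertions:
            if segments is not None:
                classify_insertion_origin(
                    ins, genome, segments, junction=junction,
                    mismatch_per_50bp=mismatch_per_50bp,
                    min_length=fostes_min_insertion,
                )
        classify_mechanism(
            junction,
            fostes_min_insertion=fostes_min_insertion,
            mmej_min_homology=mmej_min_homology,
        )
    return calls


def attach_segments(
    junctions: Iterable[Junction], segments: Sequence[Segment]
) -> list[Junction]:
    """Resolve each junction side to a segment end.

    A '−' side attaches to the segment ending at its position, a '+' side to
    the segment starting there; a mismatch within the microhomology window
    is tolerated (the join point is ambiguous over that window).
    """
    out = []
    for junction in junctions:
        sides = []
        for side in (junction.side1, junction.side2):
            match = None
            for seg in segments:
                if seg.tier is not None and seg.tier < 1:
                    continue
                boundary = seg.end if side.sign == "-" else seg.start
                if seg.contig == side.contig and abs(boundary - side.pos) <= (
                    0 if boundary == side.pos else junction.microhomology
                ):
                    match = seg.name
                    if boundary == side.pos:
                        break
            if match is None:
                raise JunctionError(
                    f"no amplified segment end at {side} (junction {junction.id or '?'})"
                )
            sides.append(replace(side, segment=match))
        junction.side1, junction.side2 = sides
        out.append(junction)
    return out
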