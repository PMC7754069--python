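"""Core domain objects shared by every pipeline stage.

The vocabulary mirrors how double-minute (DM / ecDNA) architecture studies
describe their data:

* a :class:`Segment` is a sub-amplicon — a genomic interval amplified at a
  discrete copy-number tier;
* a :class:`Junction` is the fusion point joining two segment ends in a
  rearranged circular molecule, characterised by its orientation class,
  microhomology and any inserted sequence;
* a :class:`DMStructure` is an ordered cyclic sequence of oriented segments —
  the circular molecule the pipeline reconstructs.

Coordinates are 0-based half-open throughout.  Segment ends are named
``head`` (the lower-coordinate end, drawn '+') and ``tail`` (the
higher-coordinate end, drawn '−'), following the left-to-right convention of
rejoin diagrams.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

HEAD = "head"
TAIL = "tail"

#: sign drawn for a segment end in an orientation-class label
END_SIGN = {HEAD: "+", TAIL: "-"}

MECH_BLUNT = "NHEJ-blunt"
MECH_MMEJ = "MMEJ"
MECH_FOSTES = "FoSTeS/MMBIR"

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Digit-aware sort key so that chr8 orders before chr10."""
    return tuple(int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(name))


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class SegmentEnd:
    """One end of a named segment: ``head`` ('+') or ``tail`` ('−')."""

    segment: str
    end: str

    def __post_init__(self) -> None:
        if self.end not in (HEAD, TAIL):
            raise ValueError(f"segment end must be 'head' or 'tail', got {self.end!r}")

    @property
    def sign(self) -> str:
        return END_SIGN[self.end]

    def __str__(self) -> str:  # e.g. "H1b.tail"
        return f"{self.segment}.{self.end}"


@dataclass
class Segment:
    """A sub-amplicon interval with an optional copy-number tier.

    ``tier`` is the discrete amplification level: 0 = baseline (diploid),
    1 = base amplified level (≈2^6 copies in the motivating data),
    2 = doubled (≈2^7), and so on — each tier adds one log2 unit.
    ``copy_number`` is the estimated DM-borne copy count (total minus the
    diploid chromosomal background of 2).
    """

    name: str
    contig: str
    start: int
    end: int
    mean_log2: Optional[float] = None
    tier: Optional[int] = None
    copy_number: Optional[float] = None
    flagged: bool = False  # level above the highest modelled tier

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    def boundary(self, end: str) -> int:
        return self.start if end == HEAD else self.end


@dataclass(frozen=True)
class Breakpoint:
    """A copy-number breakpoint named J1…Jn in genomic order."""

    id: str
    contig: str
    pos: int
    flanking: tuple = ()


@dataclass(frozen=True)
class JunctionSide:
    """One side of a junction: a genomic breakpoint plus its end sign.

    ``sign`` '+' means the segment participates via its head (the junction
    continues into increasing coordinates on that segment); '−' means it
    participates via its tail.
    """

    contig: str
    pos: int
    sign: str
    segment: Optional[str] = None

    @property
    def end(self) -> str:
        return HEAD if self.sign == "+" else TAIL

    def sort_key(self) -> tuple:
        return (natural_key(self.contig), self.pos, self.sign)

    def __str__(self) -> str:
        seg = f"[{self.segment}]" if self.segment else ""
        return f"{self.contig}:{self.pos}({self.sign}){seg}"


@dataclass
class Insertion:
    """Sequence inserted at a junction, with its templated origin if unique.

    ``origin_class`` is ``amplified`` / ``non-amplified`` when the sequence
    maps uniquely to the reference (inside / outside a tier≥1 segment) and
    ``uncertain`` when it maps nowhere or to multiple equally good loci.
    """

    sequence: str
    origin: Optional[tuple[str, int, int, str]] = None  # contig, start, end, strand
    origin_class: str = "uncertain"
    distance_to_junction: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Junction:
    """A canonicalized join of two segment ends.

    ``side1`` orders before ``side2`` under (natural contig key, position,
    sign) so a read and its reverse complement yield the identical record.
    ``microhomology`` is the length of the maximal window over which the join
    point can slide (number of valid placements minus one), measured on the
    reference flanks.  ``breakpoint_count`` counts the individual joins the
    junction comprises: 1 for a simple two-flank join, plus one per interior
    inserted fragment.
    """

    id: str
    side1: JunctionSide
    side2: JunctionSide
    microhomology: int = 0
    insertions: list[Insertion] = field(default_factory=list)
    mechanism: Optional[str] = None
    supporting_reads: list[str] = field(default_factory=list)
    mh_degenerate: bool = False
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.side2.sort_key() < self.side1.sort_key():
            self.side1, self.side2 = self.side2, self.side1

    @property
    def orientation_class(self) -> str:
        return f"{self.side1.sign}/{self.side2.sign}"

    @property
    def breakpoint_count(self) -> int:
        return 1 + len(self.insertions)

    @property
    def ends(self) -> tuple[SegmentEnd, SegmentEnd]:
        if self.side1.segment is None or self.side2.segment is None:
            raise ValueError(f"junction {self.id} has unresolved segment ends")
        return (
            SegmentEnd(self.side1.segment, self.side1.end),
            SegmentEnd(self.side2.segment, self.side2.end),
        )

    def coordinate_key(self) -> tuple:
        return (self.side1.sort_key(), self.side2.sort_key())


ADJACENCY = "adjacency"  # connector label for a reference-contiguous join


@dataclass
class DMStructure:
    """An ordered cyclic sequence of oriented segments.

    ``segments`` lists ``(segment name, orientation)`` in cycle order;
    ``connectors`` lists, for each position i, the label of the connection
    from segment i to segment i+1 (cyclically): a junction id, or
    :data:`ADJACENCY` when the two segments are simply contiguous in the
    reference.  Rotations and reflections denote the same molecule; the
    canonical rotation is available from :meth:`canonical_form`.
    """

    id: str
    segments: tuple[tuple[str, str], ...]
    connectors: tuple[str, ...]
    total_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.segments = tuple((s, o) for s, o in self.segments)
        self.connectors = tuple(self.connectors)
        if len(self.segments) != len(self.connectors):
            raise ValueError("one connector is required per cyclic adjacency")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def junction_ids(self) -> tuple[str, ...]:
        return tuple(c for c in self.connectors if c != ADJACENCY)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_ids)

    @property
    def n_blocks(self) -> int:
        """Number of maximal reference-contiguous runs (amplicon blocks).

        In a cycle every block terminates at a junction, so the block count
        equals the junction count.
        """
        return self.n_junctions

    def blocks(self) -> list[list[tuple[str, str]]]:
        """Split the cycle into maximal runs linked by reference adjacency."""
        n = self.n_segments
        if n == 0:
            return []
        if all(c == ADJACENCY for c in self.connectors):
            return [list(self.segments)]
        # rotate so that position 0 starts a block (connector n-1 is a junction)
        start = next(i for i in range(n) if self.connectors[i - 1] != ADJACENCY)
        out: list[list[tuple[str, str]]] = [[]]
        for k in range(n):
            i = (start + k) % n
            out[-1].append(self.segments[i])
            if self.connectors[i] != ADJACENCY and k < n - 1:
                out.append([])
        return out

    def canonical_form(self) -> tuple:
        """Smallest representation over all rotations and both directions."""
        n = self.n_segments
        if n == 0:
            return ()
        variants = []
        seg, con = list(self.segments), list(self.connectors)
        for s, c in ((seg, con), _reflect(seg, con)):
            for r in range(n):
                variants.append(
                    tuple(
                        (s[(r + i) % n], c[(r + i) % n]) for i in range(n)
                    )
                )
        return min(variants)

    def same_molecule(self, other: "DMStructure") -> bool:
        return self.canonical_form() == other.canonical_form()

    def compute_length(self, segment_lengths: Mapping[str, int]) -> int:
        self.total_length = sum(segment_lengths[s] for s, _ in self.segments)
        return self.total_length


def _reflect(segments: Sequence[tuple[str, str]], connectors: Sequence[str]):
    """Reverse traversal direction: reverse order, flip orientations.

    Connector i joins segment i to i+1; after reversal the connector between
    reversed positions j and j+1 is the original connector between the
    corresponding original pair.
    """
    n = len(segments)
    flip = {"+": "-", "-": "+"}
    rseg = [(s, flip[o]) for s, o in reversed(segments)]
    # original connector k joins orig[k] -> orig[k+1]; in the reversed list
    # orig[k+1] sits at n-2-k and orig[k] at n-1-k, so connector at n-2-k.
    rcon = [connectors[(n - 2 - j) % n] for j in range(n)]
    return rseg, rcon


def shared_segments(structures: Iterable[DMStructure]) -> set[str]:
    """Segment names present in two or more structures."""
    seen: dict[str, int] = {}
    for st in structures:
        for name in {s for s, _ in st.segments}:
            seen[name] = seen.get(name, 0) + 1
    return {name for name, k in seen.items() if k >= 2}


def shared_junction_ids(structures: Iterable[DMStructure]) -> set[str]:
    seen: dict[str, int] = {}
    for st in structures:
        for jid in set(st.junction_ids):
            seen[jid] = seen.get(jid, 0) + 1
    return {jid for jid, k in seen.items() if k >= 2}
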