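"""Reconstruction of circular DM structures on a breakpoint graph.

Nodes are segment ends; edges are segment bodies (multiplicity = the
copy ratio implied by the amplification tier), rearrangement junctions, and
reference adjacencies between abutting amplified segments.  Circular DM
molecules are edge-disjoint cycles that alternate segment traversals with
connectors and consume every edge exactly its multiplicity.  M-FISH
co-localization constrains the decomposition: probed segments seen together
on a DM must share a cycle, probes never co-observed must not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .structures import (
    ADJACENCY,
    DMStructure,
    HEAD,
    Junction,
    Segment,
    SegmentEnd,
    TAIL,
    natural_key,
    shared_junction_ids,
    shared_segments,
)


class GraphError(ValueError):
    pass


class DecompositionError(ValueError):
    pass


def tier_multiplicity(tier: int) -> int:
    """Copy multiplicity implied by an amplification tier (2^(tier−1))."""
    if tier < 1:
        raise GraphError(f"amplified segments must have tier ≥ 1, got {tier}")
    return int(round(2.0 ** (tier - 1)))


@dataclass
class JunctionEdge:
    id: str
    end1: SegmentEnd
    end2: SegmentEnd
    multiplicity: int

    def other(self, end: SegmentEnd) -> SegmentEnd:
        return self.end2 if end == self.end1 else self.end1


@dataclass
class AdjacencyEdge:
    end1: SegmentEnd  # tail of the left segment
    end2: SegmentEnd  # head of the right segment
    multiplicity: int

    @property
    def id(self) -> str:
        return ADJACENCY

    def other(self, end: SegmentEnd) -> SegmentEnd:
        return self.end2 if end == self.end1 else self.end1


@dataclass
class BreakpointGraph:
    """Segment ends joined by segment bodies, junctions and adjacencies."""

    segments: dict[str, Segment]
    multiplicities: dict[str, int]
    junction_edges: list[JunctionEdge]
    adjacency_edges: list[AdjacencyEdge]

    def edges_at(self, end: SegmentEnd) -> list:
        out: list = [e for e in self.junction_edges if end in (e.end1, e.end2)]
        out += [
            e
            for e in self.adjacency_edges
            if e.multiplicity > 0 and end in (e.end1, e.end2)
        ]
        return out


def _end_key(end: SegmentEnd, segments: Mapping[str, Segment]) -> tuple:
    seg = segments[end.segment]
    return (natural_key(seg.contig), seg.boundary(end.end), end.sign)


def _edge_key(edge: JunctionEdge, segments: Mapping[str, Segment]) -> tuple:
    return tuple(sorted((_end_key(edge.end1, segments), _end_key(edge.end2, segments))))


def build_graph(
    segments: Sequence[Segment],
    junctions: Sequence[Junction],
    infer_multiplicity: bool = True,
) -> BreakpointGraph:
    """Assemble the breakpoint graph from tiered segments and junction calls.

    Segment-edge multiplicity comes from the tier (1 or 2 by default).
    Junction multiplicity is taken from the calls when set; with
    ``infer_multiplicity`` a junction is promoted to the full segment
    multiplicity at any endpoint whose node has no other incident connector
    — the copy-doubling signature of a junction shared between populations.
    Adjacency edges absorb the remaining balance at each node; an
    unbalanceable node is an error.
    """
    amplified = {s.name: s for s in segments if s.tier is not None and s.tier >= 1}
    mult = {name: tier_multiplicity(s.tier) for name, s in amplified.items()}

    jedges: list[JunctionEdge] = []
    for j in junctions:
        e1, e2 = j.ends
        for e in (e1, e2):
            if e.segment not in amplified:
                raise GraphError(
                    f"junction {j.id!r} references baseline or unknown segment {e.segment!r}"
                )
        jedges.append(JunctionEdge(j.id, e1, e2, max(1, j.multiplicity)))

    by_pos: dict[tuple[str, int], dict[str, str]] = {}
    for name, seg in amplified.items():
        by_pos.setdefault((seg.contig, seg.start), {})[HEAD] = name
        by_pos.setdefault((seg.contig, seg.end), {})[TAIL] = name
    adjacency_pairs = [
        (SegmentEnd(ends[TAIL], TAIL), SegmentEnd(ends[HEAD], HEAD))
        for ends in by_pos.values()
        if TAIL in ends and HEAD in ends and ends[TAIL] != ends[HEAD]
    ]

    incident_j: dict[SegmentEnd, list[JunctionEdge]] = {}
    for e in jedges:
        incident_j.setdefault(e.end1, []).append(e)
        incident_j.setdefault(e.end2, []).append(e)
    has_adj = {end for pair in adjacency_pairs for end in pair}

    if infer_multiplicity:
        for e in jedges:
            for end in (e.end1, e.end2):
                m = mult[end.segment]
                alone = len(incident_j.get(end, [])) == 1 and end not in has_adj
                if alone and m > e.multiplicity:
                    e.multiplicity = m

    # node balance: junction load never exceeds the segment multiplicity,
    # and adjacency edges absorb exactly the residual on both sides
    def jload(end: SegmentEnd) -> int:
        return sum(e.multiplicity for e in incident_j.get(end, []))

    for end in incident_j:
        if jload(end) > mult[end.segment]:
            raise GraphError(
                f"node balance violated at {end}: junction multiplicity "
                f"{jload(end)} exceeds segment multiplicity {mult[end.segment]}"
            )

    aedges: list[AdjacencyEdge] = []
    for e1, e2 in adjacency_pairs:
        r1 = mult[e1.segment] - jload(e1)
        r2 = mult[e2.segment] - jload(e2)
        if r1 != r2:
            raise GraphError(
                f"inconsistent adjacency balance between {e1} ({r1}) and {e2} ({r2})"
            )
        aedges.append(AdjacencyEdge(e1, e2, r1))

    for name in amplified:
        for kind in (HEAD, TAIL):
            end = SegmentEnd(name, kind)
            if end in has_adj:
                continue
            if jload(end) != mult[name]:
                raise GraphError(
                    f"dangling segment end {end}: multiplicity {mult[name]} "
                    f"but junction load {jload(end)}"
                )

    segs = dict(amplified)
    jedges.sort(key=lambda e: _edge_key(e, segs))
    return BreakpointGraph(segs, mult, jedges, aedges)


# --------------------------------------------------------------------------
# FISH partition
# --------------------------------------------------------------------------

@dataclass
class FishConstraints:
    """Segment co-assignment constraints derived from per-DM probe signals."""

    must_cooccur: set[frozenset] = field(default_factory=set)
    must_separate: set[frozenset] = field(default_factory=set)

    def check(self, cycles: Sequence[set]) -> list[str]:
        violations = []
        for pair in sorted(self.must_cooccur, key=sorted):
            a, b = sorted(pair)
            if not any(a in c and b in c for c in cycles):
                violations.append(f"co-localized segments {a} and {b} share no cycle")
        for pair in sorted(self.must_separate, key=sorted):
            a, b = sorted(pair)
            if any(a in c and b in c for c in cycles):
                violations.append(
                    f"never co-observed segments {a} and {b} share a cycle"
                )
        return violations


@dataclass
class FishPartition:
    """DM populations grouped by identical probe-signal pattern."""

    patterns: dict[str, dict[str, int]]  # population -> probe -> 0/1
    mean_counts: dict[str, float]
    per_cell_counts: pd.DataFrame  # columns: cell_id, population, count
    n_unassigned: int
    constraints: FishConstraints


def partition_populations_by_fish(
    table: pd.DataFrame,
    probe_map: Optional[Mapping[str, str]] = None,
    subset_merge: bool = False,
) -> FishPartition:
    """Group DMs by probe-signal pattern and estimate per-population counts.

    All-negative DMs are reported unassigned.  With ``subset_merge`` a
    pattern that is a strict subset of exactly one other pattern is folded
    into it (probe dropout).  When ``probe_map`` (probe → segment) is given,
    co-localization constraints are emitted in segment terms.
    """
    if table.empty or table["cell_id"].nunique() < 1:
        raise GraphError("FISH table must contain at least one cell")
    probes = [c for c in table.columns if c not in ("cell_id", "dm_id")]
    sig = table[probes].to_numpy(dtype=int)
    keys = [tuple(row) for row in sig]
    assigned = [k for k in keys if any(k)]
    n_unassigned = len(keys) - len(assigned)

    uniq = sorted(set(assigned), key=lambda k: (-sum(k), k))
    if subset_merge:
        merged: dict[tuple, tuple] = {}
        for k in uniq:
            supersets = [
                u
                for u in uniq
                if u != k and all(b >= a for a, b in zip(k, u)) and sum(u) > sum(k)
            ]
            if len(supersets) == 1:
                merged[k] = supersets[0]
        uniq = [k for k in uniq if k not in merged]
        keys = [merged.get(k, k) for k in keys]

    names = {k: f"P{i + 1}" for i, k in enumerate(uniq)}
    rows = []
    cells = table["cell_id"].tolist()
    for cell, key in zip(cells, keys):
        if any(key) and key in names:
            rows.append((cell, names[key]))
    counts = pd.DataFrame(rows, columns=["cell_id", "population"])
    all_cells = pd.Index(table["cell_id"].unique(), name="cell_id")
    per_cell = (
        counts.groupby(["cell_id", "population"]).size().unstack(fill_value=0)
        .reindex(all_cells, fill_value=0)
        .reindex(columns=list(names.values()), fill_value=0)
    )
    means = {pop: float(per_cell[pop].mean()) for pop in per_cell.columns}
    patterns = {
        names[k]: {p: int(v) for p, v in zip(probes, k)} for k in uniq
    }

    translate = (lambda p: probe_map.get(p, p)) if probe_map else (lambda p: p)
    cooccur: set[frozenset] = set()
    ever_together: set[frozenset] = set()
    for k in set(assigned):
        positive = [translate(p) for p, v in zip(probes, k) if v]
        for a, b in itertools.combinations(sorted(set(positive)), 2):
            ever_together.add(frozenset((a, b)))
    for k in uniq:
        positive = [translate(p) for p, v in zip(probes, k) if v]
        for a, b in itertools.combinations(sorted(set(positive)), 2):
            cooccur.add(frozenset((a, b)))
    all_targets = sorted({translate(p) for p in probes})
    separate = {
        frozenset((a, b))
        for a, b in itertools.combinations(all_targets, 2)
        if frozenset((a, b)) not in ever_together
    }
    per_cell_long = per_cell.reset_index().melt(
        id_vars="cell_id", var_name="population", value_name="count"
    )
    return FishPartition(
        patterns=patterns,
        mean_counts=means,
        per_cell_counts=per_cell_long,
        n_unassigned=n_unassigned,
        constraints=FishConstraints(cooccur, separate),
    )


# --------------------------------------------------------------------------
# cycle decomposition
# --------------------------------------------------------------------------

def _traverse(entry: SegmentEnd) -> tuple[str, SegmentEnd]:
    """Traverse a segment from its entry end; returns (orientation, exit end)."""
    if entry.end == HEAD:
        return "+", SegmentEnd(entry.segment, TAIL)
    return "-", SegmentEnd(entry.segment, HEAD)


def _all_decompositions(graph: BreakpointGraph, limit: int) -> list[list[list]]:
    """Enumerate decompositions; each cycle is [(connector, entry end), ...]."""
    jrem = {id(e): e.multiplicity for e in graph.junction_edges}
    arem = {id(e): e.multiplicity for e in graph.adjacency_edges}
    srem = dict(graph.multiplicities)
    solutions: list[list[list]] = []
    max_steps = sum(graph.multiplicities.values())

    def connectors_at(end: SegmentEnd):
        out = []
        for e in graph.edges_at(end):
            rem = jrem if isinstance(e, JunctionEdge) else arem
            if rem[id(e)] > 0:
                out.append(e)
        out.sort(
            key=lambda e: (
                isinstance(e, AdjacencyEdge),
                _end_key(e.other(end), graph.segments),
                getattr(e, "id", ""),
            )
        )
        return out

    def consume(edge, delta):
        (jrem if isinstance(edge, JunctionEdge) else arem)[id(edge)] += delta

    def search(cycles: list):
        seed = next((e for e in graph.junction_edges if jrem[id(e)] > 0), None)
        if seed is None:
            if all(v == 0 for v in arem.values()) and all(v == 0 for v in srem.values()):
                solutions.append([list(c) for c in cycles])
                if len(solutions) > limit:
                    raise DecompositionError(
                        f"decomposition search exceeded {limit} solutions"
                    )
            return

        def grow(steps, incoming, position):
            if srem[position.segment] <= 0:
                return
            srem[position.segment] -= 1
            new_steps = steps + [(incoming, position)]
            _, exit_end = _traverse(position)
            if exit_end == seed.end1:
                cycles.append(new_steps)
                search(cycles)
                cycles.pop()
            if len(new_steps) < max_steps:
                for edge in connectors_at(exit_end):
                    consume(edge, -1)
                    grow(new_steps, edge, edge.other(exit_end))
                    consume(edge, +1)
            srem[position.segment] += 1

        consume(seed, -1)
        grow([], seed, seed.end2)
        consume(seed, +1)

    search([])
    return solutions


def _cycle_to_structure(cycle: list, idx: int) -> DMStructure:
    segments = []
    connectors = []
    for incoming, entry in cycle:
        orient, _ = _traverse(entry)
        segments.append((entry.segment, orient))
        connectors.append(incoming.id)
    # incoming edge of step i joins step i-1's segment to step i's; shift so
    # connectors[i] joins segments[i] -> segments[i+1]
    connectors = connectors[1:] + connectors[:1]
    return DMStructure(f"dm{idx + 1}", tuple(segments), tuple(connectors))


def copy_fit_residual(
    structures: Sequence[DMStructure], copies: Mapping[str, float]
) -> float:
    """Residual of the best non-negative abundance fit to segment copies."""
    segs = sorted(copies)
    design = np.zeros((len(segs), len(structures)))
    for j, st in enumerate(structures):
        for name, _ in st.segments:
            if name in copies:
                design[segs.index(name), j] += 1.0
    y = np.array([float(copies[s]) for s in segs])
    _, rnorm = nnls(design, y)
    return float(rnorm)


def decompose_cycles(
    graph: BreakpointGraph,
    constraints: Optional[FishConstraints] = None,
    max_decompositions: int = 200000,
    copies: Optional[Mapping[str, float]] = None,
) -> list[DMStructure]:
    """Edge-disjoint cycle decomposition constrained by FISH co-localization.

    Every junction edge is used exactly its multiplicity (segment bodies and
    adjacencies likewise).  Among decompositions satisfying the constraints,
    preference goes to the best fit of segment copy numbers by non-negative
    population abundances (when ``copies`` is supplied — unprobed segments
    can otherwise drift between cycles that FISH cannot distinguish), then
    to fewest cycles, then lexicographically on the canonical cycle forms;
    the result is therefore deterministic.
    """
    if not graph.junction_edges:
        return []
    solutions = _all_decompositions(graph, max_decompositions)
    if not solutions:
        raise DecompositionError("no cycle decomposition consumes every edge")
    best = None
    best_key = None
    all_violations: list[str] = []
    for sol in solutions:
        structures = [_cycle_to_structure(c, i) for i, c in enumerate(sol)]
        if constraints is not None:
            content = [{s for s, _ in st.segments} for st in structures]
            violations = constraints.check(content)
            if violations:
                all_violations = violations
                continue
        residual = (
            round(copy_fit_residual(structures, copies), 6) if copies else 0.0
        )
        key = (
            residual,
            len(structures),
            sorted(st.canonical_form() for st in structures),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = structures
    if best is None:
        raise DecompositionError(
            "no decomposition satisfies the FISH constraints: "
            + "; ".join(all_violations)
        )
    best = [
        DMStructure(f"dm{i + 1}", st.segments, st.connectors)
        for i, st in enumerate(
            sorted(best, key=lambda s: s.canonical_form())
        )
    ]
    for st in best:
        st.compute_length({n: s.length for n, s in graph.segments.items()})
    return best


# --------------------------------------------------------------------------
# abundances and summaries
# --------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Reconstructed structures with per-population abundances."""

    structures: list[DMStructure]
    abundances: dict[str, float]
    shared_segments: set[str]
    shared_junctions: set[str]
    copy_ratio: Optional[float]  # shared to mean population-specific copies
    residual: float


def estimate_abundances(
    structures: Sequence[DMStructure], copies: Mapping[str, float]
) -> PopulationModel:
    """Solve copies(seg) ≈ Σ abundance × multiplicity by non-negative least squares.

    ``copies`` maps segment name to DM-borne copy number (total minus the
    diploid background).  Structures indistinguishable by segment content
    make the design rank-deficient and raise an error.
    """
    if not structures:
        raise GraphError("at least one structure is required")
    segs = sorted(copies)
    design = np.zeros((len(segs), len(structures)))
    for j, st in enumerate(structures):
        for name, _ in st.segments:
            if name in copies:
                design[segs.index(name), j] += 1.0
    if np.linalg.matrix_rank(design) < len(structures):
        raise GraphError(
            "structures are indistinguishable by segment content; "
            "abundances are not identifiable"
        )
    y = np.array([float(copies[s]) for s in segs])
    x, rnorm = nnls(design, y)
    abundances = {st.id: float(a) for st, a in zip(structures, x)}
    shared = shared_segments(structures)
    shared_j = shared_junction_ids(structures)
    specific_means = []
    for st in structures:
        own = [copies[s] for s, _ in st.segments if s in copies and s not in shared]
        if own:
            specific_means.append(float(np.mean(own)))
    shared_copies = [copies[s] for s in shared if s in copies]
    ratio = None
    if shared_copies and specific_means:
        ratio = float(np.mean(shared_copies) / np.mean(specific_means))
    return PopulationModel(
        structures=list(structures),
        abundances=abundances,
        shared_segments=shared,
        shared_junctions=shared_j,
        copy_ratio=ratio,
        residual=float(rnorm),
    )


def structure_summary(
    structure: DMStructure,
    junctions: Optional[Mapping[str, Junction]] = None,
    shared_ids: Optional[set[str]] = None,
    segment_lengths: Optional[Mapping[str, int]] = None,
) -> dict:
    """Length, composition and junction statistics of one circular structure."""
    if segment_lengths is not None:
        structure.compute_length(segment_lengths)
    orientation_counts: dict[str, int] = {}
    if junctions:
        for jid in structure.junction_ids:
            cls = junctions[jid].orientation_class
            orientation_counts[cls] = orientation_counts.get(cls, 0) + 1
    return {
        "id": structure.id,
        "total_length": structure.total_length,
        "n_segments": structure.n_segments,
        "n_junctions": structure.n_junctions,
        "n_blocks": structure.n_blocks,
        "segments": [list(s) for s in structure.segments],
        "junction_ids": list(structure.junction_ids),
        "orientation_class_counts": orientation_counts,
        "shared_junctions": sorted(
            set(structure.junction_ids) & (shared_ids or set())
        ),
    }
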