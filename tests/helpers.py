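"""Independent oracles and random-instance generators for the test suite.

Everything here is deliberately written by a different route than the
implementation it checks: exhaustive slides, brute-force window scans, and
a cycle-cover enumerator built from a pre-listed cycle catalogue.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np

from dmrecon.assembly import BreakpointGraph, FishConstraints
from dmrecon.structures import (
    DMStructure,
    HEAD,
    Junction,
    JunctionSide,
    Segment,
    SegmentEnd,
    TAIL,
)


# --------------------------------------------------------------------------
# microhomology oracle: exhaustive join-point slide
# --------------------------------------------------------------------------

def slide_microhomology(left_flank: str, left_ext: str, right_pre: str,
                        right_flank: str) -> int:
    """Number of valid join placements minus one, by exhaustive slide.

    The junction product is left_flank + right_flank.  A placement shifted
    k bases left moves the last k bases of the left flank onto the right
    side (they must equal the k bases of right_pre before the right flank);
    shifted right, the first k bases of the right flank must equal the
    reference continuation of the left flank.
    """
    placements = 1
    k = 1
    while k <= min(len(left_flank), len(right_pre)):
        if left_flank[-k:] == right_pre[-k:]:
            placements += 1
            k += 1
        else:
            break
    k = 1
    while k <= min(len(right_flank), len(left_ext)):
        if right_flank[:k] == left_ext[:k]:
            placements += 1
            k += 1
        else:
            break
    return placements - 1


# --------------------------------------------------------------------------
# chromothripsis cluster oracle: all-pairs window check
# --------------------------------------------------------------------------

def brute_force_clusters(positions: Sequence[int], window: int, min_bp: int):
    """All maximal runs of sorted positions spanning ≤ window with ≥ min_bp."""
    pos = sorted(positions)
    n = len(pos)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if pos[j] - pos[i] <= window:
                count = j - i + 1
                left_ext = i > 0 and pos[j] - pos[i - 1] <= window
                right_ext = j + 1 < n and pos[j + 1] - pos[i] <= window
                if count >= min_bp and not left_ext and not right_ext:
                    runs.append((pos[i], pos[j], count))
    return runs


# --------------------------------------------------------------------------
# exact multinomial oracle: full enumeration
# --------------------------------------------------------------------------

def multinomial_p_enumerate(counts: Sequence[int]) -> float:
    from math import factorial

    n, k = sum(counts), len(counts)

    def pmf(c):
        coef = factorial(n)
        for x in c:
            coef //= factorial(x)
        return coef / k ** n

    p_obs = pmf(counts)
    total = 0.0
    for outcome in itertools.product(range(n + 1), repeat=k - 1):
        rest = n - sum(outcome)
        if rest < 0:
            continue
        c = (*outcome, rest)
        p = pmf(c)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


# --------------------------------------------------------------------------
# random breakpoint-graph instances with known truth
# --------------------------------------------------------------------------

def random_graph_instance(rng: np.random.Generator, max_segments: int = 8):
    """A random two-cycle instance: segments, junctions, constraints, truth.

    Shared segments are separated by cycle-private segments except for an
    optionally engineered shared junction, so the decomposition is pinned
    by the co-occurrence constraints.
    """
    n_shared = int(rng.integers(1, 3))
    shared_junction = n_shared == 2 and rng.integers(2) == 1
    budget = max_segments - n_shared
    n_p1 = int(rng.integers(2, max(3, budget - 1)))
    n_p1 = min(n_p1, budget - 2)
    n_p2 = min(int(rng.integers(2, 4)), budget - n_p1)
    shared = [f"S{i}" for i in range(n_shared)]
    priv1 = [f"A{i}" for i in range(n_p1)]
    priv2 = [f"B{i}" for i in range(n_p2)]

    def orient():
        return "+" if rng.integers(2) == 0 else "-"

    shared_orient = {s: orient() for s in shared}

    def build_cycle(privates):
        order: list[tuple[str, str]] = []
        priv = list(privates)
        if shared_junction:
            order += [(shared[0], shared_orient[shared[0]]),
                      (shared[1], shared_orient[shared[1]])]
            for p in priv:
                order.append((p, orient()))
        else:
            pieces = [[(s, orient())] for s in shared]
            for k, p in enumerate(priv):
                pieces[k % len(pieces)].append((p, orient()))
            for piece in pieces:
                order += piece
        return order

    cyc1 = build_cycle(priv1)
    cyc2 = build_cycle(priv2)

    names = shared + priv1 + priv2
    segments = {}
    for i, name in enumerate(names):
        seg = Segment(name, "cT", 200 * i, 200 * i + 100)
        seg.tier = 2 if name in shared else 1
        segments[name] = seg

    def ends_for(cycle):
        pairs = []
        n = len(cycle)
        for i in range(n):
            a, oa = cycle[i]
            b, ob = cycle[(i + 1) % n]
            e1 = SegmentEnd(a, TAIL if oa == "+" else HEAD)
            e2 = SegmentEnd(b, HEAD if ob == "+" else TAIL)
            pairs.append((e1, e2))
        return pairs

    edge_mult: dict[frozenset, int] = {}
    for cycle in (cyc1, cyc2):
        for e1, e2 in ends_for(cycle):
            key = frozenset((e1, e2))
            edge_mult[key] = edge_mult.get(key, 0) + 1

    junctions = []
    for k, (key, mult) in enumerate(sorted(edge_mult.items(),
                                           key=lambda kv: sorted(map(str, kv[0])))):
        e1, e2 = sorted(key, key=str)
        s1, s2 = segments[e1.segment], segments[e2.segment]
        junctions.append(
            Junction(
                id=f"e{k + 1}",
                side1=JunctionSide(s1.contig, s1.boundary(e1.end), e1.sign, e1.segment),
                side2=JunctionSide(s2.contig, s2.boundary(e2.end), e2.sign, e2.segment),
                multiplicity=mult,
            )
        )

    content1 = {s for s, _ in cyc1}
    content2 = {s for s, _ in cyc2}
    cooccur = {
        frozenset(p)
        for content in (content1, content2)
        for p in itertools.combinations(sorted(content), 2)
    }
    separate = {
        frozenset((a, b))
        for a, b in itertools.combinations(sorted(names), 2)
        if not ({a, b} <= content1 or {a, b} <= content2)
    }
    constraints = FishConstraints(cooccur, separate)
    truth = [
        DMStructure("t1", tuple(cyc1), tuple("junction" for _ in cyc1)),
        DMStructure("t2", tuple(cyc2), tuple("junction" for _ in cyc2)),
    ]
    return list(segments.values()), junctions, constraints, truth


# --------------------------------------------------------------------------
# exhaustive decomposition oracle: cycle catalogue + exact cover
# --------------------------------------------------------------------------

def _simple_cycles(graph: BreakpointGraph):
    """All distinct alternating simple cycles, as step lists."""
    cycles = []
    seen = set()
    edges = list(graph.junction_edges) + [
        e for e in graph.adjacency_edges if e.multiplicity > 0
    ]

    def connectors_at(end):
        return [e for e in edges if end in (e.end1, e.end2)]

    max_len = sum(graph.multiplicities.values())
    for seed in graph.junction_edges:
        for start, nxt in ((seed.end1, seed.end2), (seed.end2, seed.end1)):

            def walk(steps, position, used_counts):
                _, exit_end = _traverse(position)
                if exit_end == start and steps:
                    key = _cycle_key(steps)
                    if key not in seen:
                        seen.add(key)
                        cycles.append(list(steps))
                if len(steps) >= max_len:
                    return
                for edge in connectors_at(exit_end):
                    if used_counts.get(id(edge), 0) >= edge.multiplicity:
                        continue
                    used_counts[id(edge)] = used_counts.get(id(edge), 0) + 1
                    walk(steps + [(edge, edge.other(exit_end))],
                         edge.other(exit_end), used_counts)
                    used_counts[id(edge)] -= 1

            walk([(seed, nxt)], nxt, {id(seed): 1})
    return cycles


def _traverse(entry: SegmentEnd):
    if entry.end == HEAD:
        return "+", SegmentEnd(entry.segment, TAIL)
    return "-", SegmentEnd(entry.segment, HEAD)


def _cycle_key(steps):
    """Rotation/reflection-invariant label sequence for an alternating cycle.

    A step is (incoming edge, entered segment with orientation).  Under
    reversal, segment order reverses with flipped orientations, and the
    incoming edge of reversed step j is the outgoing edge of the original
    segment, i.e. the incoming edge of the following original step.
    """
    labels = []
    for edge, entry in steps:
        orient, _ = _traverse(entry)
        labels.append((getattr(edge, "id", "?"), entry.segment, orient))
    n = len(labels)
    flip = {"+": "-", "-": "+"}
    rev = [
        (labels[(n - j) % n][0], labels[n - 1 - j][1], flip[labels[n - 1 - j][2]])
        for j in range(n)
    ]
    variants = [tuple(labels[(r + i) % n] for i in range(n)) for r in range(n)]
    variants += [tuple(rev[(r + i) % n] for i in range(n)) for r in range(n)]
    return min(variants)


def oracle_decompose(
    graph: BreakpointGraph,
    constraints: Optional[FishConstraints] = None,
    copies=None,
) -> list[DMStructure]:
    """Exhaustive decomposition by exact cover over the cycle catalogue."""
    catalogue = _simple_cycles(graph)

    def edge_usage(steps):
        usage: dict[int, int] = {}
        segs: dict[str, int] = {}
        for edge, entry in steps:
            usage[id(edge)] = usage.get(id(edge), 0) + 1
            segs[entry.segment] = segs.get(entry.segment, 0) + 1
        return usage, segs

    targets_e = {
        id(e): e.multiplicity
        for e in list(graph.junction_edges) + list(graph.adjacency_edges)
    }
    targets_s = dict(graph.multiplicities)
    solutions = []

    def search(idx, chosen, acc_e, acc_s):
        if all(acc_e.get(k, 0) == v for k, v in targets_e.items()) and all(
            acc_s.get(k, 0) == v for k, v in targets_s.items()
        ):
            solutions.append(list(chosen))
        if idx >= len(catalogue):
            return
        for nxt in range(idx, len(catalogue)):
            ue, us = edge_usage(catalogue[nxt])
            if any(acc_e.get(k, 0) + v > targets_e.get(k, 0) for k, v in ue.items()):
                continue
            if any(acc_s.get(k, 0) + v > targets_s.get(k, 0) for k, v in us.items()):
                continue
            new_e = dict(acc_e)
            new_s = dict(acc_s)
            for k, v in ue.items():
                new_e[k] = new_e.get(k, 0) + v
            for k, v in us.items():
                new_s[k] = new_s.get(k, 0) + v
            search(nxt, chosen + [catalogue[nxt]], new_e, new_s)

    search(0, [], {}, {})

    best = None
    best_key = None
    for sol in solutions:
        structures = []
        for i, steps in enumerate(sol):
            segs = []
            cons = []
            for edge, entry in steps:
                orient, _ = _traverse(entry)
                segs.append((entry.segment, orient))
                cons.append(edge.id)
            cons = cons[1:] + cons[:1]
            structures.append(DMStructure(f"dm{i + 1}", tuple(segs), tuple(cons)))
        if constraints is not None:
            content = [{s for s, _ in st.segments} for st in structures]
            if constraints.check(content):
                continue
        from dmrecon.assembly import copy_fit_residual

        residual = round(copy_fit_residual(structures, copies), 6) if copies else 0.0
        key = (residual, len(structures),
               sorted(st.canonical_form() for st in structures))
        if best_key is None or key < best_key:
            best_key = key
            best = structures
    if best is None:
        return []
    return sorted(best, key=lambda s: s.canonical_form())


def cycles_equal_up_to_symmetry(a: Sequence[DMStructure], b: Sequence[DMStructure],
                                segments_only: bool = True) -> bool:
    def canon(st):
        if segments_only:
            st = DMStructure(st.id, st.segments, tuple("x" for _ in st.connectors))
        return st.canonical_form()

    return sorted(canon(s) for s in a) == sorted(canon(s) for s in b)
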