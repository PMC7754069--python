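"""Evolutionary inference: chromothripsis criteria, join randomness,
DM-borne SNP zygosity, and the stepwise-formation verdict.

Two chromothripsis criteria are formalised: clustering of breakpoints
(≥ ``min_bp`` breakpoints within a sliding genomic window, 50 kb by
default) and randomness of fragment joins (an exact multinomial
goodness-of-fit of the four rejoin orientation classes against the uniform
¼,¼,¼,¼ expectation — at a handful of junctions the chi-square
approximation is invalid, so the test enumerates outcomes exactly).

The stepwise-formation verdict combines three lines of evidence that one DM
population derived from another rather than arising independently: nesting
of one population's genomic footprint inside the other's, a junction shared
by both circles (a sequence that does not exist on chromosomes), and
germline-heterozygous SNPs rendered effectively homozygous on the DMs of
both populations by the extreme DM copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import PopulationModel
from .structures import Breakpoint, Junction, natural_key

ORIENTATION_CLASSES = ("-/+", "+/-", "+/+", "-/-")


# --------------------------------------------------------------------------
# breakpoint clustering
# --------------------------------------------------------------------------

@dataclass
class ChromothripsisReport:
    clusters: list[dict]
    criterion_met: bool
    window: int
    min_breakpoints: int


def chromothripsis_cluster_test(
    breakpoints: Sequence[Breakpoint] | Sequence[tuple[str, int]],
    window: int = 50000,
    min_bp: int = 5,
) -> ChromothripsisReport:
    """Scan for breakpoint clusters: ≥ ``min_bp`` breakpoints within ``window`` bp.

    Windows are anchored at each breakpoint; a maximal cluster is a run of
    consecutive breakpoints spanning ≤ ``window`` bp that cannot be extended
    on either side.  The criterion is met when at least one cluster exists.
    """
    pos_by_contig: dict[str, list[int]] = {}
    for b in breakpoints:
        contig, pos = (b.contig, b.pos) if isinstance(b, Breakpoint) else b
        pos_by_contig.setdefault(contig, []).append(int(pos))
    clusters = []
    for contig in sorted(pos_by_contig, key=natural_key):
        pos = sorted(pos_by_contig[contig])
        n = len(pos)
        j = 0
        prev_j = -1
        for i in range(n):
            while j + 1 < n and pos[j + 1] - pos[i] <= window:
                j += 1
            count = j - i + 1
            if count >= min_bp and j > prev_j:
                # maximal: cannot extend left (i==0 or previous window ends
                # earlier) nor right (loop condition)
                if i == 0 or pos[j] - pos[i - 1] > window:
                    clusters.append(
                        {
                            "contig": contig,
                            "start": pos[i],
                            "end": pos[j],
                            "count": count,
                        }
                    )
                    prev_j = j
    return ChromothripsisReport(
        clusters=clusters,
        criterion_met=bool(clusters),
        window=window,
        min_breakpoints=min_bp,
    )


# --------------------------------------------------------------------------
# join-orientation randomness
# --------------------------------------------------------------------------

@dataclass
class JoinRandomnessReport:
    counts: dict[str, int]
    total: int
    p_value: float
    consistent_with_random: bool


def _exact_multinomial_p(counts: Sequence[int]) -> float:
    """Exact multinomial goodness-of-fit p against uniform cell probabilities.

    The p-value sums the probabilities of all outcomes whose probability
    does not exceed that of the observed table.
    """
    counts = [int(c) for c in counts]
    n, k = sum(counts), len(counts)
    if n == 0:
        raise ValueError("at least one observation is required")
    dist = stats.multinomial(n, [1.0 / k] * k)
    p_obs = dist.pmf(counts)
    total = 0.0
    for outcome in _compositions(n, k):
        p = dist.pmf(outcome)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(min(1.0, total))


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def join_randomness_test(
    junctions: Iterable[Junction] | Mapping[str, int], alpha: float = 0.05
) -> JoinRandomnessReport:
    """Tabulate rejoin orientation classes and test uniformity exactly.

    Accepts junction records or a precomputed class→count mapping.  Random
    end joining predicts the four classes (tail-to-head −/+, head-to-tail
    +/−, head-to-head +/+, tail-to-tail −/−) to be equally likely.
    """
    counts = {c: 0 for c in ORIENTATION_CLASSES}
    if isinstance(junctions, Mapping):
        for cls, c in junctions.items():
            if cls not in counts:
                raise ValueError(f"unknown orientation class {cls!r}")
            counts[cls] = int(c)
    else:
        for j in junctions:
            counts[j.orientation_class] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no junctions with orientation classes")
    p = _exact_multinomial_p([counts[c] for c in ORIENTATION_CLASSES])
    return JoinRandomnessReport(
        counts=counts, total=total, p_value=p, consistent_with_random=p > alpha
    )


# --------------------------------------------------------------------------
# SNP zygosity on DMs
# --------------------------------------------------------------------------

@dataclass
class SNPZygosityReport:
    sites: pd.DataFrame
    n_sites: int
    n_dm_homozygous: int
    n_heterozygous: int
    n_missing: int
    threshold: float


def snp_zygosity_test(
    depths: pd.DataFrame,
    minor_fraction_threshold: float = 0.05,
    confidence: float = 0.95,
) -> SNPZygosityReport:
    """Call each site DM-homozygous, heterozygous or missing.

    A germline-heterozygous site is effectively homozygous on DMs when the
    chromosomal allele is a negligible minority of reads: the call compares
    the minor-allele fraction with the threshold, and the one-sided
    Clopper–Pearson upper bound (at the given confidence) is reported as a
    per-site ``confident`` flag — true when even the upper bound clears the
    threshold.
    """
    rows = []
    for rec in depths.itertuples(index=False):
        ref_d, alt_d = int(rec.ref_depth), int(rec.alt_depth)
        total = ref_d + alt_d
        if total == 0 or bool(getattr(rec, "missing", False)):
            call, frac, upper, confident = "missing", np.nan, np.nan, False
        else:
            minor = min(ref_d, alt_d)
            frac = minor / total
            upper = float(stats.beta.ppf(confidence, minor + 1, total - minor)) \
                if minor < total else 1.0
            call = "DM-homozygous" if frac < minor_fraction_threshold else "heterozygous"
            confident = (
                upper < minor_fraction_threshold
                if call == "DM-homozygous"
                else frac >= minor_fraction_threshold
            )
        rows.append((rec.contig, rec.pos, ref_d, alt_d, frac, upper, call, confident))
    sites = pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref_depth", "alt_depth",
                 "minor_fraction", "minor_fraction_upper", "call", "confident"],
    )
    calls = sites["call"].value_counts()
    return SNPZygosityReport(
        sites=sites,
        n_sites=len(sites),
        n_dm_homozygous=int(calls.get("DM-homozygous", 0)),
        n_heterozygous=int(calls.get("heterozygous", 0)),
        n_missing=int(calls.get("missing", 0)),
        threshold=minor_fraction_threshold,
    )


# --------------------------------------------------------------------------
# stepwise-evolution verdict
# --------------------------------------------------------------------------

@dataclass
class StepwiseVerdict:
    evidence: dict[str, Optional[bool]]
    verdict: str
    min_evidence: int


def _footprint(structure, segments) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for name, _ in structure.segments:
        seg = segments[name]
        out.setdefault(seg.contig, []).append((seg.start, seg.end))
    return {c: _merge_intervals(v) for c, v in out.items()}


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _covered(inner, outer) -> bool:
    return all(
        any(s >= os and e <= oe for os, oe in outer) for s, e in inner
    )


def _footprint_nested(model: PopulationModel, segments) -> bool:
    """True when one structure's footprint on shared contigs sits inside
    the other's amplicon content (and they do overlap at all)."""
    for a, b in combinations(model.structures, 2):
        fa, fb = _footprint(a, segments), _footprint(b, segments)
        common = set(fa) & set(fb)
        if not common:
            continue
        b_inside_a = all(_covered(fb[c], fa[c]) for c in common)
        a_inside_b = all(_covered(fa[c], fb[c]) for c in common)
        overlap = any(
            s1 < e2 and s2 < e1
            for c in common
            for s1, e1 in fa[c]
            for s2, e2 in fb[c]
        )
        if overlap and (b_inside_a != a_inside_b):
            return True
    return False


def stepwise_evidence(
    model: PopulationModel,
    zygosity: Optional[SNPZygosityReport] = None,
    segments: Optional[Mapping] = None,
    min_evidence: int = 2,
) -> StepwiseVerdict:
    """Assemble the stepwise-formation checklist and verdict.

    Evidence items: (a) one population's amplified content is nested inside
    the other's; (b) at least one junction is shared by both circles;
    (c) DM-borne SNPs are homozygous in both populations.  ``stepwise``
    requires ``min_evidence`` items true; all-false (with zygosity data
    absent counting as undetermined) yields ``independent``; anything else
    is ``inconclusive``.
    """
    if len(model.structures) < 2:
        return StepwiseVerdict(
            evidence={"nested_amplicons": None, "shared_junction": None,
                      "dm_homozygous_snps": None},
            verdict="inconclusive",
            min_evidence=min_evidence,
        )
    seg_map = segments if segments is not None else {}
    nested: Optional[bool]
    if seg_map:
        nested = _footprint_nested(model, seg_map)
    else:
        # fall back to name-level subset on shared contigs when no segment
        # coordinates are supplied
        sets = [{s for s, _ in st.segments} for st in model.structures]
        nested = any(
            (a & b) and (a < b or b < a) for a, b in combinations(sets, 2)
        )
    shared = bool(model.shared_junctions)
    homozygous: Optional[bool] = None
    if zygosity is not None and zygosity.n_sites > 0:
        determinate = zygosity.n_sites - zygosity.n_missing
        homozygous = determinate > 0 and zygosity.n_dm_homozygous == determinate
    evidence = {
        "nested_amplicons": nested,
        "shared_junction": shared,
        "dm_homozygous_snps": homozygous,
    }
    n_true = sum(1 for v in evidence.values() if v)
    n_false = sum(1 for v in evidence.values() if v is False)
    if n_true >= min_evidence:
        verdict = "stepwise"
    elif n_true == 0 and n_false >= 2 and shared is False:
        verdict = "independent"
    else:
        verdict = "inconclusive"
    return StepwiseVerdict(evidence=evidence, verdict=verdict, min_evidence=min_evidence)
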