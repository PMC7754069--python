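"""Minimal figures: a copy-number profile track and a circle diagram."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .structures import ADJACENCY, DMStructure, Segment


def plot_cn_profile(profile, segments: Optional[Sequence[Segment]] = None, ax=None):
    """Scatter the probe-level log2 ratios, one panel per contig row,
    with optional segment-mean overlays."""
    import matplotlib.pyplot as plt

    contigs = list(profile["contig"].unique())
    if ax is None:
        _, axes = plt.subplots(len(contigs), 1, figsize=(9, 2.2 * len(contigs)),
                               squeeze=False)
        axes = [a for row in axes for a in row]
    else:
        axes = [ax] * len(contigs)
    for contig, a in zip(contigs, axes):
        sub = profile[profile["contig"] == contig]
        a.plot(sub["pos"], sub["log2"], ".", ms=2, color="0.6")
        if segments:
            for s in segments:
                if s.contig == contig and s.mean_log2 is not None:
                    a.hlines(s.mean_log2, s.start, s.end, color="C3", lw=2)
        a.set_ylabel("log2 ratio")
        a.set_title(contig, fontsize=9)
    axes[-1].set_xlabel("position (bp)")
    return axes


def plot_structure(structure: DMStructure, segment_lengths: dict, ax=None):
    """Draw a circular DM structure as labelled arcs; junctions as gaps."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    total = sum(segment_lengths[s] for s, _ in structure.segments)
    theta = 90.0
    cmap = plt.get_cmap("tab20")
    for k, ((name, orient), conn) in enumerate(
        zip(structure.segments, structure.connectors)
    ):
        span = 360.0 * segment_lengths[name] / total
        gap = 1.5 if conn != ADJACENCY else 0.2
        arc = np.radians(np.linspace(theta, theta - span + gap, 60))
        ax.plot(np.cos(arc), np.sin(arc), lw=8, color=cmap(k % 20),
                solid_capstyle="butt")
        mid = np.radians(theta - span / 2)
        ax.text(1.22 * np.cos(mid), 1.22 * np.sin(mid), f"{name}{orient}",
                ha="center", va="center", fontsize=8)
        theta -= span
    ax.set_aspect("equal")
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.axis("off")
    ax.set_title(f"{structure.id}: {structure.n_junctions} junctions, "
                 f"{total} bp", fontsize=9)
    return ax
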