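"""Configuration for every pipeline stage.

A single :class:`PipelineConfig` holds one nested section per stage; every
tunable named in the documentation lives here exactly once.  Configs load
from YAML with strict key checking (a misspelled key is an error naming the
offender), and an empty file yields the full default configuration.

The synthetic-data defaults encode the study conditions of the motivating
system: two DM populations at mean counts 101 and 107 per cell, eleven
sub-amplicons over two contigs at amplification tiers 2^6 and 2^7, eight
junctions with engineered repair-mechanism signatures, and 34 heterozygous
SNP sites carried at 10 chromosomal versus 1500 DM-borne copies.  Genomic
scale is ~1/1000 of the real loci so the whole chain runs at desk scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .structures import HEAD, TAIL, MECH_BLUNT, MECH_FOSTES, MECH_MMEJ


class ConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# synth defaults: the toy genome and the two-population ground truth
# --------------------------------------------------------------------------

DEFAULT_CONTIGS = {"chr8_toy": 12000, "chr10_toy": 6000}

#: (name, contig, start, end) — eleven sub-amplicons in four amplified
#: regions (2 + 4 + 3 + 2), proportioned after the source loci at ~1/1000.
DEFAULT_AMPLICONS = [
    ("H1a", "chr8_toy", 1000, 1600),
    ("H1b", "chr8_toy", 1600, 2200),
    ("H2a", "chr8_toy", 3200, 3800),
    ("H2b", "chr8_toy", 3800, 4300),
    ("H2c", "chr8_toy", 4300, 4900),
    ("H2d", "chr8_toy", 4900, 5400),
    ("H3a", "chr8_toy", 6400, 6900),
    ("H3b", "chr8_toy", 6900, 7500),
    ("H3c", "chr8_toy", 7500, 8000),
    ("H4a", "chr10_toy", 2000, 2500),
    ("H4b", "chr10_toy", 2500, 3100),
]

#: cyclic oriented segment lists.  Population one rejoins the complete
#: amplicons H1, H2 and H3; Population two circularises H1b, H2a, H2c, H3b,
#: H4a and H4b, sharing the H1b-tail/H2a-head junction with Population one.
DEFAULT_POPULATIONS = {
    "pop1": [
        ["H1a", "+"], ["H1b", "+"],
        ["H2a", "+"], ["H2b", "+"], ["H2c", "+"], ["H2d", "+"],
        ["H3a", "+"], ["H3b", "+"], ["H3c", "+"],
    ],
    "pop2": [
        ["H1b", "+"], ["H2a", "+"], ["H2c", "+"],
        ["H3b", "-"], ["H4a", "+"], ["H4b", "-"],
    ],
}

#: Per-junction forensic signature: repair mechanism, flank microhomology,
#: and inserted fragments.  Insertion specs are (length, origin_pool) with
#: origin_pool one of "non_amplified", "amplified", "untemplated", or
#: (contig, start) pinning an exact origin.  The roman numerals echo figure
#: junction naming; "V" is a four-join composite (three tiny untemplated
#: interior fragments), "VII"/"VIII" carry templated insertions diagnostic of
#: replication-based (FoSTeS/MMBIR) repair, with VII's drawn mostly from
#: non-amplified sequence (18 of the 20 locatable fragments) and one 5 bp
#: fragment too short to place uniquely.
DEFAULT_JUNCTIONS = [
    {"name": "I", "left": ["H3c", TAIL], "right": ["H1a", HEAD],
     "mechanism": MECH_MMEJ, "microhomology": 3, "insertions": []},
    {"name": "II", "left": ["H2d", TAIL], "right": ["H3a", HEAD],
     "mechanism": MECH_MMEJ, "microhomology": 2, "insertions": []},
    {"name": "III", "left": ["H4b", HEAD], "right": ["H1b", HEAD],
     "mechanism": MECH_MMEJ, "microhomology": 4, "insertions": []},
    {"name": "IV", "left": ["H1b", TAIL], "right": ["H2a", HEAD],
     "mechanism": MECH_MMEJ, "microhomology": 5, "insertions": []},
    {"name": "V", "left": ["H2a", TAIL], "right": ["H2c", HEAD],
     "mechanism": MECH_MMEJ, "microhomology": 2,
     "insertions": [[1, "untemplated"], [2, "untemplated"], [1, "untemplated"]]},
    {"name": "VI", "left": ["H2c", TAIL], "right": ["H3b", TAIL],
     "mechanism": MECH_BLUNT, "microhomology": 0, "insertions": []},
    {"name": "VII", "left": ["H3b", HEAD], "right": ["H4a", HEAD],
     "mechanism": MECH_FOSTES, "microhomology": 1,
     "insertions": (
         # fragments shorter than the split-alignment anchor are interleaved
         # with longer ones so each read interval is individually resolvable
         [[5, "untemplated_genomic"]]
         + [[n, "non_amplified"] for n in [22, 12, 26, 15, 30, 18, 35, 40]]
         + [[25, ["chr8_toy", 7010]]]   # amplified, 110 bp from the junction
         + [[n, "non_amplified"] for n in [46, 52, 60, 70, 82]]
         + [[33, ["chr8_toy", 1900]]]   # amplified, ~5 kb away (in H1b)
         + [[n, "non_amplified"] for n in [95, 120, 160, 240, 679]]
     )},
    {"name": "VIII", "left": ["H4a", TAIL], "right": ["H4b", TAIL],
     "mechanism": MECH_FOSTES, "microhomology": 1,
     "insertions": [[14, "amplified"], [131, "amplified"],
                    [27, "amplified"], [58, "amplified"]]},
]


def _dc(cls, **kw):
    return field(default_factory=lambda: cls(**kw))


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator."""

    seed: int = 0
    contigs: dict = field(default_factory=lambda: dict(DEFAULT_CONTIGS))
    amplicons: list = field(default_factory=lambda: [list(a) for a in DEFAULT_AMPLICONS])
    populations: dict = field(default_factory=lambda: {k: [list(x) for x in v]
                                                       for k, v in DEFAULT_POPULATIONS.items()})
    junctions: list = field(default_factory=lambda: [dict(j) for j in DEFAULT_JUNCTIONS])
    #: mean DMs per cell for each population, in population order
    mean_dm_counts: dict = field(default_factory=lambda: {"pop1": 101.0, "pop2": 107.0})
    probe_spacing: int = 10
    log2_noise_sd: float = 0.1
    n_cells: int = 40
    #: FISH probe name -> segment (the six BAC analogues)
    fish_probes: dict = field(default_factory=lambda: {
        "BAC-H1a": "H1a", "BAC-H1b": "H1b", "BAC-H2d": "H2d",
        "BAC-H3a": "H3a", "BAC-H3c": "H3c", "BAC-H4b": "H4b"})
    n_snp_sites: int = 34
    chrom_copies: int = 10
    dm_copies: int = 1500
    snp_depth: int = 1000
    snp_contig: str = "chr8_toy"
    reads_per_junction: int = 3
    read_flank: int = 150

    def validate(self) -> "SimConfig":
        for name, length in self.contigs.items():
            if length <= 0:
                raise ConfigError(f"contig {name!r} has non-positive length {length}")
        if self.probe_spacing <= 0:
            raise ConfigError("probe_spacing must be positive")
        if self.chrom_copies < 0 or self.dm_copies < 0:
            raise ConfigError("allele copy counts must be non-negative")
        if any(m < 0 for m in self.mean_dm_counts.values()):
            raise ConfigError("mean DM counts must be non-negative")
        defined = set()
        by_contig: dict[str, list[tuple[int, int, str]]] = {}
        for name, contig, start, end in self.amplicons:
            if contig not in self.contigs:
                raise ConfigError(f"amplicon {name!r} on undefined contig {contig!r}")
            if not 0 <= start < end <= self.contigs[contig]:
                raise ConfigError(f"amplicon {name!r} outside contig bounds")
            by_contig.setdefault(contig, []).append((start, end, name))
            defined.add(name)
        for contig, ivs in by_contig.items():
            ivs.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ConfigError(f"amplicons {n1!r} and {n2!r} overlap on {contig}")
        for pop, segs in self.populations.items():
            for seg, orient in segs:
                if seg not in defined:
                    raise ConfigError(f"population {pop!r} references undefined segment {seg!r}")
                if orient not in ("+", "-"):
                    raise ConfigError(f"bad orientation {orient!r} in population {pop!r}")
        for spec in self.junctions:
            for side in ("left", "right"):
                seg, end = spec[side]
                if seg not in defined:
                    raise ConfigError(f"junction {spec['name']!r} references undefined segment {seg!r}")
                if end not in (HEAD, TAIL):
                    raise ConfigError(f"junction {spec['name']!r}: bad end {end!r}")
        return self


@dataclass
class SegmentationConfig:
    min_probes: int = 5
    level_tol: float = 0.3  # log2 units
    max_tier: int = 2
    #: regions excluded from baseline estimation; None = use global median
    baseline_regions: Optional[list] = None


@dataclass
class JunctionConfig:
    min_anchor: int = 20
    max_scan: int = 50
    mmej_min_homology: int = 1
    fostes_min_insertion: int = 5
    #: near-exact origin search: allowed mismatches per 50 bp
    origin_mismatch_per_50bp: int = 1


@dataclass
class AssemblyConfig:
    fish_subset_merge: bool = False
    max_decompositions: int = 200000


@dataclass
class EvolutionConfig:
    ct_window: int = 50000
    ct_min_breakpoints: int = 5
    minor_fraction_threshold: float = 0.05
    binomial_confidence: float = 0.95
    stepwise_min_evidence: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "dmrecon_out"
    synth: SimConfig = field(default_factory=SimConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    junctions: JunctionConfig = field(default_factory=JunctionConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)

    def __post_init__(self) -> None:
        # the global seed feeds every stage unless synth overrides it
        if self.synth.seed == 0 and self.seed != 0:
            self.synth.seed = self.seed

    def validate(self) -> "PipelineConfig":
        self.synth.validate()
        return self


def _update_dataclass(obj: Any, data: dict, path: str) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown configuration key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"section {path}{key!r} must be a mapping")
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            if current is not None and value is not None:
                if isinstance(current, bool) != isinstance(value, bool):
                    raise ConfigError(f"type mismatch for {path}{key!r}")
                if isinstance(current, (int, float)) and not isinstance(value, (int, float)):
                    raise ConfigError(f"type mismatch for {path}{key!r}: expected a number")
                if isinstance(current, (dict, list, str)) and not isinstance(value, type(current)):
                    raise ConfigError(
                        f"type mismatch for {path}{key!r}: expected {type(current).__name__}")
            setattr(obj, key, value)


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a pipeline configuration from YAML, filling defaults.

    An empty (or absent) file yields the default configuration.  Unknown or
    mistyped keys raise :class:`ConfigError` naming the offending key path.
    ``overrides`` applies a final nested update (CLI flags beat the file).
    """
    cfg = PipelineConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("top-level configuration must be a mapping")
        data = loaded
    _update_dataclass(cfg, data, "")
    if overrides:
        _update_dataclass(cfg, overrides, "")
    cfg.__post_init__()
    return cfg.validate()


def config_to_dict(cfg: Any) -> dict:
    return dataclasses.asdict(cfg)


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
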