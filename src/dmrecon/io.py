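"""Readers and writers for the pipeline's interchange formats.

Plain-text, field-standard formats throughout: FASTA for sequences (via
Biopython), BED for segments and breakpoints, BEDPE (+ JSON sidecar) for
junctions, TSV for tabular observables, JSON for structures and reports.
Every writer has a matching reader that reproduces the in-memory objects.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import Breakpoint, DMStructure, Insertion, Junction, JunctionSide, Segment
from .synth import GroundTruth, ReferenceGenome


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def write_genome_fasta(genome: ReferenceGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> ReferenceGenome:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceGenome(contigs)


def write_reads_fasta(reads: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

def write_segments_bed(segments: Sequence[Segment], path) -> None:
    """BED6+2: name = segment label, score = tier, then mean log2 and copies."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                "\t".join(
                    [
                        s.contig,
                        str(s.start),
                        str(s.end),
                        s.name,
                        str(s.tier if s.tier is not None else "."),
                        ".",
                        f"{s.mean_log2:.6g}" if s.mean_log2 is not None else ".",
                        f"{s.copy_number:.6g}" if s.copy_number is not None else ".",
                    ]
                )
                + "\n"
            )


def read_segments_bed(path) -> list[Segment]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out.append(
            Segment(
                name=f[3],
                contig=f[0],
                start=int(f[1]),
                end=int(f[2]),
                tier=None if f[4] == "." else int(f[4]),
                mean_log2=None if len(f) < 7 or f[6] == "." else float(f[6]),
                copy_number=None if len(f) < 8 or f[7] == "." else float(f[7]),
            )
        )
    return out


def write_breakpoints_bed(breakpoints: Sequence[Breakpoint], path) -> None:
    with open(path, "w") as fh:
        for b in breakpoints:
            fh.write(
                f"{b.contig}\t{b.pos}\t{b.pos + 1}\t{b.id}\t.\t.\t"
                f"{','.join(b.flanking) if b.flanking else '.'}\n"
            )


def read_breakpoints_bed(path) -> list[Breakpoint]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        flank = tuple(f[6].split(",")) if len(f) > 6 and f[6] != "." else ()
        out.append(Breakpoint(f[3], f[0], int(f[1]), flank))
    return out


# --------------------------------------------------------------------------
# junctions: BEDPE + JSON sidecar
# --------------------------------------------------------------------------

def _side_dict(side: JunctionSide) -> dict:
    return {"contig": side.contig, "pos": side.pos, "sign": side.sign,
            "segment": side.segment}


def _side_from(d: dict) -> JunctionSide:
    return JunctionSide(d["contig"], int(d["pos"]), d["sign"], d.get("segment"))


def junction_to_dict(j: Junction) -> dict:
    return {
        "id": j.id,
        "side1": _side_dict(j.side1),
        "side2": _side_dict(j.side2),
        "orientation_class": j.orientation_class,
        "microhomology": j.microhomology,
        "mh_degenerate": j.mh_degenerate,
        "mechanism": j.mechanism,
        "multiplicity": j.multiplicity,
        "breakpoint_count": j.breakpoint_count,
        "supporting_reads": list(j.supporting_reads),
        "insertions": [
            {
                "sequence": ins.sequence,
                "length": ins.length,
                "origin": list(ins.origin) if ins.origin else None,
                "origin_class": ins.origin_class,
                "distance_to_junction": ins.distance_to_junction,
            }
            for ins in j.insertions
        ],
    }


def junction_from_dict(d: dict) -> Junction:
    return Junction(
        id=d["id"],
        side1=_side_from(d["side1"]),
        side2=_side_from(d["side2"]),
        microhomology=int(d["microhomology"]),
        mh_degenerate=bool(d.get("mh_degenerate", False)),
        mechanism=d.get("mechanism"),
        multiplicity=int(d.get("multiplicity", 1)),
        supporting_reads=list(d.get("supporting_reads", [])),
        insertions=[
            Insertion(
                sequence=i["sequence"],
                origin=tuple(i["origin"]) if i.get("origin") else None,
                origin_class=i.get("origin_class", "uncertain"),
                distance_to_junction=i.get("distance_to_junction"),
            )
            for i in d.get("insertions", [])
        ],
    )


def write_junctions(junctions: Sequence[Junction], bedpe_path, sidecar_path=None) -> None:
    """BEDPE rows (one per junction) plus a JSON sidecar with forensics."""
    with open(bedpe_path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    [
                        j.side1.contig, str(j.side1.pos), str(j.side1.pos + 1),
                        j.side2.contig, str(j.side2.pos), str(j.side2.pos + 1),
                        j.id, str(j.microhomology),
                        j.side1.sign, j.side2.sign,
                    ]
                )
                + "\n"
            )
    if sidecar_path is not None:
        payload = [junction_to_dict(j) for j in junctions]
        Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def read_junctions(sidecar_path) -> list[Junction]:
    payload = json.loads(Path(sidecar_path).read_text())
    return [junction_from_dict(d) for d in payload]


# --------------------------------------------------------------------------
# structures and ground truth: JSON
# --------------------------------------------------------------------------

def structure_to_dict(st: DMStructure) -> dict:
    return {
        "id": st.id,
        "segments": [list(s) for s in st.segments],
        "connectors": list(st.connectors),
        "total_length": st.total_length,
    }


def structure_from_dict(d: dict) -> DMStructure:
    return DMStructure(
        id=d["id"],
        segments=tuple((s, o) for s, o in d["segments"]),
        connectors=tuple(d["connectors"]),
        total_length=d.get("total_length"),
    )


def write_structures(structures: Sequence[DMStructure], path) -> None:
    Path(path).write_text(
        json.dumps([structure_to_dict(s) for s in structures], indent=1)
    )


def read_structures(path) -> list[DMStructure]:
    return [structure_from_dict(d) for d in json.loads(Path(path).read_text())]


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "structures": [structure_to_dict(s) for s in truth.structures],
        "junctions": [junction_to_dict(j) for j in truth.junctions],
        "abundances": truth.abundances,
        "segments": [
            {"name": s.name, "contig": s.contig, "start": s.start, "end": s.end}
            for s in truth.segments.values()
        ],
        "junction_specs": truth.junction_specs,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        structures=[structure_from_dict(s) for s in d["structures"]],
        junctions=[junction_from_dict(j) for j in d["junctions"]],
        abundances={k: float(v) for k, v in d["abundances"].items()},
        segments={
            s["name"]: Segment(s["name"], s["contig"], int(s["start"]), int(s["end"]))
            for s in d["segments"]
        },
        junction_specs=d.get("junction_specs", {}),
    )


def write_json(payload, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj).__name__}")
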