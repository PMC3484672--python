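"""Standard-format readers and writers.

FASTA carries sequences (amplicons embed their primer anchors in the
description line as ``key=value`` pairs), a GFF3 subset carries gene/exon
models, BED and TSV carry intervals and reports, and JSON carries scenario
configs and run summaries.  Internally everything is 0-based half-open;
the breakpoint TSV additionally reports 1-based inclusive positions, and
every writer states its coordinate convention in a header line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .breakcall import BreakpointReport
from .cghval import LossCall, ProbeTrack
from .errors import ConfigError, DataError
from .screensim import ScreenResult, ScreenScenario
from .seqmodel import Amplicon, GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_amplicons",
    "write_amplicons",
    "read_gene_models",
    "write_breakpoint_tsv",
    "write_breakpoint_bed",
    "write_breakpoint_vcf",
    "write_probe_track",
    "read_probe_track",
    "write_loss_calls",
    "scenario_from_json",
    "scenario_to_json",
    "screen_result_to_dict",
]

PathLike = Union[str, Path]

_COORD_NOTE = "coordinates: 0-based, half-open"

_ANCHOR_KEYS = ("ext_left", "int_left", "int_right", "ext_right")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: PathLike, records: Dict[str, str]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_amplicons(path: PathLike, amplicons: Iterable[Amplicon]) -> None:
    """Write amplicons as FASTA, primer anchors in the description line."""
    records = []
    for amp in amplicons:
        desc = " ".join(
            f"{k}={getattr(amp, k)}" for k in _ANCHOR_KEYS
        ) + f" {_COORD_NOTE}"
        records.append(SeqRecord(Seq(amp.seq), id=amp.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_amplicons(path: PathLike) -> List[Amplicon]:
    """Read amplicons back from FASTA written by :func:`write_amplicons`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = {}
        for token in rec.description.split():
            if "=" in token:
                key, _, value = token.partition("=")
                if key in _ANCHOR_KEYS:
                    fields[key] = int(value)
        missing = [k for k in _ANCHOR_KEYS if k not in fields]
        if missing:
            raise DataError(
                f"amplicon {rec.id}: description lacks primer anchors {missing}"
            )
        out.append(Amplicon(id=rec.id, seq=str(rec.seq).upper(), **fields))
    return out


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Read gene models from a GFF3 subset with gene and exon features.

    Exons are attached to their gene via the Parent attribute (directly or
    through an intermediate transcript feature).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end)  # GFF3 is 1-based inclusive
            for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            raise DataError(f"gene {gene.id}: no exon features")
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(exons),
            )
        )
    return models


def _flank(seq: str, n: int, side: str) -> str:
    return seq[-n:] if side == "left" else seq[:n]


def write_breakpoint_tsv(
    reports: Sequence[BreakpointReport], path: PathLike, flank_len: int = 30
) -> None:
    """Breakpoint report TSV: 1-based inclusive display coordinates.

    ``left_1based``/``right_1based`` are the first and last deleted bases
    in 1-based inclusive convention; flanks are the retained sequence
    nearest the break (at least ``flank_len`` bp when available).
    """
    rows = []
    for rep in reports:
        a = rep.allele
        rows.append(
            {
                "allele_id": a.allele_id,
                "amplicon_id": a.amplicon_id,
                "left_1based": a.left + 1,
                "right_1based": a.right,
                "deletion_size": a.deletion_size,
                "break_class": a.break_class,
                "ambiguity_width": a.ambiguity_width,
                "insert": a.insert or ".",
                "flank_left": _flank(rep.flank_left, flank_len, "left"),
                "flank_right": _flank(rep.flank_right, flank_len, "right"),
                "merge_conflicts": rep.merge_conflicts,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# breakpoint report; coordinates: 1-based, inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def write_breakpoint_bed(
    reports: Sequence[BreakpointReport], path: PathLike
) -> None:
    """BED track of deletion intervals (0-based half-open, as BED demands)."""
    with open(path, "w") as fh:
        fh.write(f"# deletion intervals; {_COORD_NOTE}\n")
        for rep in reports:
            a = rep.allele
            fh.write(f"{a.amplicon_id}\t{a.left}\t{a.right}\t{a.allele_id}\n")


def write_breakpoint_vcf(
    reports: Sequence[BreakpointReport], path: PathLike
) -> None:
    """Minimal VCF 4.2 with explicit REF/ALT deletion records.

    Each record uses the base before the deletion as anchor; inserted
    material appears in the ALT allele.  INFO carries SVTYPE/END and the
    ambiguity width of the canonical placement.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end (1-based inclusive)">',
        '##INFO=<ID=AMBIG,Number=1,Type=Integer,Description="Equivalent breakpoint placements">',
    ]
    for rep in reports:
        lines.append(
            f"##contig=<ID={rep.amplicon.id},length={len(rep.amplicon)}>"
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rep in reports:
        a = rep.allele
        seq = rep.amplicon.seq
        if a.left == 0:
            raise ConfigError(
                f"allele {a.allele_id}: deletion at position 0 has no VCF anchor base"
            )
        ref = seq[a.left - 1 : a.right]
        alt = seq[a.left - 1] + a.insert
        info = f"SVTYPE=DEL;END={a.right};AMBIG={a.ambiguity_width}"
        lines.append(
            f"{a.amplicon_id}\t{a.left}\t{a.allele_id}\t{ref}\t{alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_probe_track(track: ProbeTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# CGH probe track; {_COORD_NOTE}; noise_sd={track.noise_sd}\n")
        track.probes.to_csv(fh, sep="\t", index=False)


def read_probe_track(path: PathLike) -> ProbeTrack:
    noise_sd = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.strip("#\n").split(";"):
                token = token.strip()
                if token.startswith("noise_sd="):
                    noise_sd = float(token.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    df = df[["chrom", "start", "end", "log2"]]
    return ProbeTrack(probes=df, noise_sd=noise_sd)


def write_loss_calls(calls: Sequence[LossCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# CGH loss calls; {_COORD_NOTE}\n")
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            fh, sep="\t", index=False
        )


def scenario_from_json(path: PathLike) -> ScreenScenario:
    """Load a screen scenario from a flat JSON key/value file."""
    raw = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(ScreenScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    if "sib_plan" in raw:
        raw["sib_plan"] = tuple(raw["sib_plan"])
    return ScreenScenario(**raw)


def scenario_to_json(sc: ScreenScenario, path: PathLike) -> None:
    data = dataclasses.asdict(sc)
    data["sib_plan"] = list(data["sib_plan"])
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def screen_result_to_dict(result: ScreenResult) -> dict:
    """JSON-ready summary of a screen run."""
    return {
        "detected": result.detected,
        "addressed_well": result.addressed_well,
        "recovered": result.recovered,
        "reactions_used": result.reactions_used,
        "pool_reactions": result.pool_reactions,
        "addressing_reactions": result.addressing_reactions,
        "sib_reactions": result.sib_reactions,
        "lost_at_addressing": result.lost_at_addressing,
        "rounds": [
            {
                "round": r.round_index,
                "wells_tested": r.wells_tested,
                "positives": r.positives,
                "allele_frequency": r.allele_frequency,
            }
            for r in result.rounds
        ],
    }
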