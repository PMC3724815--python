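"""External representations: FASTA, duplex alignment reports, feature tables.

The alignment report is a miRanda-style plain-text format, one hit block per
site.  The canonical dialect written by this package shows the miRNA (Query)
5'->3' on top and the target site (Ref) 3'->5' underneath; the classic
miRanda display (Query 3'->5') is also understood and normalized on input.
Pairing categories are always re-derived from the two residue rows, never
from the decoration row.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import joblib
import pandas as pd
from Bio import SeqIO

from .duplex import DuplexAlignment, PairCategory
from .features import FEATURE_NAMES, ID_COLUMN, LABEL_COLUMN, FeatureTable
from .seqs import RNASequence, Role

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, role: Role = Role.TARGET) -> list[RNASequence]:
    """Read a multi-record FASTA file into validated RNA sequences.

    The full header line (without '>') is kept as the identifier; T is
    normalized to U.  A record with residues outside the normalizable
    alphabet raises an error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.description or rec.id
        records.append(RNASequence(ident, str(rec.seq), role))
    return records


def write_fasta(sequences: Iterable[RNASequence], path: str | Path) -> None:
    # headers written verbatim so read_fasta round-trips the identifier
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.identifier}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# Alignment reports
# ---------------------------------------------------------------------------

_FORWARD_RE = re.compile(
    r"Forward:\s+Score:\s*(?P<score>-?[\d.]+).*?"
    r"R:\s*(?P<rstart>\d+)\s+to\s+(?P<rend>\d+)"
)
_ROW_RE = re.compile(
    r"(Query|Ref):\s+(?:(?P<left>[53])'\s+)?(?P<row>[ACGUTacgut-]+)(?:\s+[53]')?"
)
_ENERGY_RE = re.compile(r"Energy:\s*(?P<dg>-?[\d.]+)")
_PAIR_HEADER_RE = re.compile(r">>\s*(?P<mirna>\S+)\s+vs\s+(?P<target>\S+)")

_PAIR_SYMBOL = {
    PairCategory.GC_MATCH: "|",
    PairCategory.AU_MATCH: "|",
    PairCategory.GU_WOBBLE: ":",
    PairCategory.MISMATCH: " ",
    PairCategory.GAP: " ",
}


def parse_miranda_output(text: str) -> list[DuplexAlignment]:
    """Parse hit blocks from a miRanda-style report.

    Unknown banner lines are skipped.  A truncated block raises an error with
    its index; residue rows of unequal length raise an error.
    """
    lines = text.splitlines()
    alignments: list[DuplexAlignment] = []
    mirna_id = target_id = ""
    i, block = 0, 0
    while i < len(lines):
        header = _PAIR_HEADER_RE.search(lines[i])
        if header:
            mirna_id, target_id = header["mirna"], header["target"]
            i += 1
            continue
        fwd = _FORWARD_RE.search(lines[i])
        if not fwd:
            i += 1
            continue
        block += 1
        rows: dict[str, tuple[str, str | None]] = {}
        energy = None
        j = i + 1
        while j < len(lines):
            line = lines[j]
            if _FORWARD_RE.search(line) or _PAIR_HEADER_RE.search(line):
                break
            me = _ENERGY_RE.search(line)
            if me:
                energy = float(me["dg"])
                j += 1
                break
            mrow = _ROW_RE.search(line)
            if mrow and mrow.group(1) not in rows:
                rows[mrow.group(1)] = (mrow["row"], mrow["left"])
            j += 1
        if "Query" not in rows or "Ref" not in rows:
            raise ValueError(f"truncated hit block {block}: missing residue rows")
        qrow, qleft = rows["Query"]
        rrow, _ = rows["Ref"]
        if len(qrow) != len(rrow):
            raise ValueError(
                f"hit block {block}: residue rows of unequal length "
                f"({len(qrow)} vs {len(rrow)})"
            )
        qrow = qrow.upper().replace("T", "U")
        rrow = rrow.upper().replace("T", "U")
        if qleft == "3":  # classic display: miRNA 3'->5'; normalize
            qrow, rrow = qrow[::-1], rrow[::-1]
        alignments.append(
            DuplexAlignment(
                mirna_row=qrow,
                target_row=rrow,
                score=float(fwd["score"]),
                target_start=int(fwd["rstart"]),
                target_end=int(fwd["rend"]),
                mirna_id=mirna_id,
                target_id=target_id,
                mfe=energy,
            )
        )
        i = j
    return alignments


def format_miranda_report(alignments: Iterable[DuplexAlignment]) -> str:
    """Render alignments in the canonical hit-block dialect."""
    out = ["# mirforest duplex report"]
    for aln in alignments:
        pipes = "".join(_PAIR_SYMBOL[c] for c in aln.categories)
        out.append(f">>{aln.mirna_id or 'query'} vs {aln.target_id or 'ref'}")
        out.append(
            f"   Forward:  Score: {aln.score:.2f}  "
            f"R:{aln.target_start} to {aln.target_end}  "
            f"Align Len ({aln.length})"
        )
        out.append(f"   Query:    5' {aln.mirna_row} 3'")
        out.append(f"                {pipes}")
        out.append(f"   Ref:      3' {aln.target_row} 5'")
        if aln.mfe is not None:
            out.append(f"   Energy:  {aln.mfe:.2f} kCal/Mol")
        out.append("")
    return "\n".join(out) + "\n"


def write_miranda_report(alignments: Iterable[DuplexAlignment], path: str | Path) -> None:
    Path(path).write_text(format_miranda_report(alignments))


# ---------------------------------------------------------------------------
# Feature tables (TSV)
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    known = {ID_COLUMN, LABEL_COLUMN, *FEATURE_NAMES}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown feature table columns: {unknown}")
    return FeatureTable(frame)


# ---------------------------------------------------------------------------
# JSON config and model serialization
# ---------------------------------------------------------------------------

def read_json_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a JSON object")
    return cfg


def save_model(model, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version: {payload.get('format_version')}"
        )
    return payload["model"]
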