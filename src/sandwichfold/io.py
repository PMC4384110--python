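"""FASTA reading/writing, truth tables and report serialization.

Reports use 1-based inclusive coordinates; internal code is 0-based
half-open throughout.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
import sys
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import DataError
from .search import ClassifiedRecord
from .synth import AnnotatedSequence

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "id", "decision", "witness_strand_starts", "n_satisfying",
    "violated_rules", "error",
)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record with empty id")
        if not self.residues:
            raise DataError(f"record {self.id!r} has an empty sequence")


def read_fasta(source: Union[str, TextIO]) -> list[SequenceRecord]:
    """Parse FASTA into records (order preserved, residues uppercased)."""
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source, "r", encoding="utf-8")
        close = True
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    stripped = text.lstrip()
    if not stripped:
        logger.warning("empty FASTA input")
        return []
    if not stripped.startswith(">"):
        raise DataError("not a FASTA file: first non-blank character is not '>'")
    records = []
    for title, seq in SimpleFastaParser(_io.StringIO(text)):
        parts = title.split(None, 1)
        rid = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        residues = "".join(seq.split()).upper()
        if not residues:
            raise DataError(f"record {rid or title!r} has an empty sequence")
        records.append(SequenceRecord(id=rid, description=desc, residues=residues))
    return records


def write_fasta(records: Sequence, path: Union[str, TextIO], width: int = 60) -> None:
    """Write records (anything with .id and a sequence attribute) as FASTA."""
    if hasattr(path, "write"):
        handle, close = path, False
    else:
        handle, close = open(path, "w", encoding="utf-8"), True
    try:
        for rec in records:
            seq = getattr(rec, "residues", None) or getattr(rec, "sequence")
            handle.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


def write_truth_table(records: Sequence[AnnotatedSequence],
                      path: Union[str, TextIO]) -> None:
    """TSV ground truth: id, label, violated_group, strand starts (1-based)."""
    if hasattr(path, "write"):
        handle, close = path, False
    else:
        handle, close = open(path, "w", encoding="utf-8", newline=""), True
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "label", "violated_group", "strand_starts"])
        for rec in records:
            starts = (
                ";".join(str(s) for s in rec.true_assignment.strand_starts_1based())
                if rec.true_assignment is not None
                else ""
            )
            writer.writerow([rec.id, rec.label, rec.violated_group or "", starts])
    finally:
        if close:
            handle.close()


def read_truth_table(path: Union[str, TextIO]) -> dict[str, dict]:
    """Parse the truth TSV back into a mapping id -> row fields."""
    if hasattr(path, "read"):
        handle, close = path, False
    else:
        handle, close = open(path, "r", encoding="utf-8"), True
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise DataError("truth table needs a header with an 'id' column")
        if "label" not in reader.fieldnames:
            raise DataError("truth table needs a 'label' column")
        out: dict[str, dict] = {}
        for row in reader:
            out[row["id"]] = dict(row)
        return out
    finally:
        if close:
            handle.close()


def _decision_row(result: ClassifiedRecord) -> dict:
    if result.error is not None:
        return {
            "id": result.id, "decision": "error",
            "witness_strand_starts": "", "n_satisfying": "",
            "violated_rules": "", "error": result.error,
        }
    d = result.decision
    witness = ""
    if d.witness is not None:
        witness = ";".join(str(s) for s in d.witness.strand_starts_1based())
    violated = ""
    if d.best_failing is not None:
        violated = ";".join(d.best_failing[1].rule_ids())
    return {
        "id": result.id,
        "decision": "accepted" if d.accepted else "rejected",
        "witness_strand_starts": witness,
        "n_satisfying": "" if d.n_satisfying is None else d.n_satisfying,
        "violated_rules": violated,
        "error": "",
    }


def write_report(results: Sequence[ClassifiedRecord], format: str = "tsv",
                 path: Optional[Union[str, TextIO]] = None) -> None:
    """Serialize classification results as TSV or JSON.

    JSON schema: a list of objects with the same keys as the TSV columns
    (``n_satisfying`` is an integer or null).
    """
    if format not in ("tsv", "json"):
        raise DataError(f"unknown report format {format!r}")
    if path is None:
        handle, close = sys.stdout, False
    elif hasattr(path, "write"):
        handle, close = path, False
    else:
        handle, close = open(path, "w", encoding="utf-8", newline=""), True
    try:
        rows = [_decision_row(r) for r in results]
        if format == "tsv":
            writer = csv.DictWriter(
                handle, fieldnames=REPORT_COLUMNS, delimiter="\t",
                lineterminator="\n",
            )
            writer.writeheader()
            writer.writerows(rows)
        else:
            for row in rows:
                if row["n_satisfying"] == "":
                    row["n_satisfying"] = None
            json.dump(rows, handle, indent=2)
            handle.write("\n")
    finally:
        if close:
            handle.close()
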