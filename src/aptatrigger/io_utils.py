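"""FASTA / TSV / CSV input-output with deterministic formatting."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import NucleicSequence, SequenceError

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_report",
    "ReportSchemaError",
    "read_dose_csv",
    "write_dose_csv",
]

FLOAT_FORMAT = "%.4f"


class ReportSchemaError(ValueError):
    """A report row does not conform to the declared schema."""


def read_fasta(path: str | Path) -> list[NucleicSequence]:
    """Read RNA/DNA sequences from FASTA (T transliterated to U).

    Rejects duplicate ids, empty records and non-nucleotide characters,
    naming the offending record and position.
    """
    out: list[NucleicSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise SequenceError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        if len(record.seq) == 0:
            raise SequenceError(f"empty FASTA record {record.id!r} in {path}")
        try:
            out.append(NucleicSequence(record.id, str(record.seq)))
        except SequenceError as exc:
            raise SequenceError(f"record {record.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: list[NucleicSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _format_cell(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return FLOAT_FORMAT % value
    return str(value)


def write_report(
    rows: list[dict],
    schema: list[str],
    path: str | Path,
    config=None,
) -> None:
    """Write a TSV report with deterministic columns and float precision.

    ``schema`` fixes the column order; every row must supply exactly those
    fields. Metadata lines are '#'-prefixed; a config hash line is added
    when a :class:`~aptatrigger.config.RunConfig` is given. Identical
    inputs produce byte-identical files.
    """
    for idx, row in enumerate(rows):
        missing = [c for c in schema if c not in row]
        extra = [c for c in row if c not in schema]
        if missing or extra:
            raise ReportSchemaError(
                f"row {idx} violates schema: missing={missing} extra={extra}"
            )
    lines = ["# aptatrigger report"]
    if config is not None:
        lines.append(f"# config_hash={config.config_hash}")
    lines.append("\t".join(schema))
    for row in rows:
        lines.append("\t".join(_format_cell(row[c]) for c in schema))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dose_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read dose-response points from CSV (columns conc_molar, response)."""
    points = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or \
                {"conc_molar", "response"} - set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns conc_molar,response, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            points.append((float(row["conc_molar"]), float(row["response"])))
    return points


def write_dose_csv(points: list[tuple[float, float]], path: str | Path) -> None:
    lines = ["conc_molar,response"]
    for conc, resp in points:
        lines.append(f"{conc:.6e},{resp:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
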