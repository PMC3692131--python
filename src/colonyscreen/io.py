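"""Readers and writers for the tabular formats of the pipeline.

Three formats are handled:

* colony files (``.dat``): tab-delimited ``row  col  size  [circularity]``,
  one line per colony, no header — the output of image quantification and
  the input to normalization;
* score files: the nine-column tab-delimited table (row, col, raw size,
  plate id, query, array gene, normalized size, score, kvp) written per
  plate and as a combined replicate-averaged file;
* array definitions: a headered TSV mapping (plate_number, row, col) to
  the array gene and optionally its chromosomal locus, used for gene
  annotation and the linkage filter.
"""

from __future__ import annotations

import math
from typing import IO, Iterable, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    ArrayDefinition,
    ArrayEntry,
    ColonyMeasurement,
    PlateFormat,
    PlateMeasurements,
    ScoreRecord,
)

__all__ = [
    "read_colony_file",
    "write_colony_file",
    "write_score_records",
    "read_score_records",
    "load_array_definition",
    "SCORE_COLUMNS",
]

PathOrStream = Union[str, IO[str]]

SCORE_COLUMNS = [
    "row", "col", "raw_size", "plate_id", "query", "array_gene",
    "normalized_size", "score", "kvp",
]


def _open(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, bytes)):
        return open(source, mode), True
    return source, False


def read_colony_file(source: PathOrStream, fmt: PlateFormat,
                     plate_id: Optional[str] = None) -> PlateMeasurements:
    """Read a tab-delimited colony file into :class:`PlateMeasurements`.

    The first three columns must be row, column and colony size; a
    fourth column, when present, is taken as circularity and any further
    columns are ignored.  All occupied positions of ``fmt`` must be
    present exactly once.
    """
    stream, close = _open(source)
    try:
        measurements = []
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 tab-separated fields")
            if lineno == 1 and not parts[0].strip().lstrip("-").isdigit():
                continue  # tolerated header line
            try:
                row, col = int(parts[0]), int(parts[1])
                size = int(round(float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed numeric field") from exc
            if size < 0:
                raise ValueError(f"line {lineno}: negative colony size {size}")
            circ: Optional[float] = None
            if len(parts) >= 4 and parts[3].strip() not in ("", "NA"):
                circ = float(parts[3])
            nr, nc = fmt.physical_shape
            if not (1 <= row <= nr and 1 <= col <= nc):
                raise ValueError(
                    f"line {lineno}: position ({row},{col}) out of bounds for {nr}x{nc} grid"
                )
            measurements.append(ColonyMeasurement(row, col, size, circ if size else None))
        if plate_id is None:
            plate_id = getattr(stream, "name", "plate")
        return PlateMeasurements.from_measurements(plate_id, fmt, measurements)
    finally:
        if close:
            stream.close()


def write_colony_file(plate: PlateMeasurements, target: PathOrStream) -> None:
    """Write a plate back to the tab-delimited colony format."""
    stream, close = _open(target, "w")
    try:
        for m in plate.measurements():
            circ = "NA" if m.circularity is None else f"{m.circularity:.4f}"
            stream.write(f"{m.row}\t{m.col}\t{m.size}\t{circ}\n")
    finally:
        if close:
            stream.close()


def _fmt_value(value: Optional[float], digits: int = 3) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{digits}f}"


def _fmt_kvp(kvp: dict[str, str]) -> str:
    if not kvp:
        return "NA"
    return ";".join(f"{k}={v}" for k, v in kvp.items())


def write_score_records(records: Iterable[ScoreRecord], target: PathOrStream,
                        header: bool = False) -> None:
    """Serialize score records as the nine-column tab-delimited table.

    ``NA`` is written literally for missing normalized sizes and scores;
    numeric results carry three decimal places; an empty kvp renders as
    ``NA``.
    """
    stream, close = _open(target, "w")
    try:
        if header:
            stream.write("\t".join(SCORE_COLUMNS) + "\n")
        for r in records:
            fields = [
                str(r.row), str(r.col), str(r.raw_size), r.plate_id, r.query,
                r.array_gene, _fmt_value(r.normalized_size), _fmt_value(r.score),
                _fmt_kvp(r.kvp),
            ]
            stream.write("\t".join(fields) + "\n")
    finally:
        if close:
            stream.close()


def read_score_records(source: PathOrStream) -> list[ScoreRecord]:
    """Read a nine-column score file back into :class:`ScoreRecord` objects."""
    stream, close = _open(source)
    try:
        records = []
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(parts)}")
            if lineno == 1 and parts[0] == "row":
                continue
            kvp: dict[str, str] = {}
            if parts[8] != "NA":
                for pair in parts[8].split(";"):
                    k, _, v = pair.partition("=")
                    kvp[k] = v
            records.append(ScoreRecord(
                row=int(parts[0]), col=int(parts[1]), raw_size=int(parts[2]),
                plate_id=parts[3], query=parts[4], array_gene=parts[5],
                normalized_size=None if parts[6] == "NA" else float(parts[6]),
                score=None if parts[7] == "NA" else float(parts[7]),
                kvp=kvp,
            ))
        return records
    finally:
        if close:
            stream.close()


def load_array_definition(source: PathOrStream) -> ArrayDefinition:
    """Load an array definition from a headered TSV.

    Required columns: ``plate_number``, ``row``, ``col``, ``gene``;
    optional: ``chromosome`` and ``position_kb``.  ``BLANK`` genes may
    (and normally do) omit the locus columns.
    """
    stream, close = _open(source)
    try:
        df = pd.read_csv(stream, sep="\t", dtype={"gene": str, "chromosome": str})
    finally:
        if close:
            stream.close()
    required = {"plate_number", "row", "col", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"array definition missing columns: {sorted(missing)}")
    entries: dict[tuple[int, int, int], ArrayEntry] = {}
    for rec in df.itertuples(index=False):
        key = (int(rec.plate_number), int(rec.row), int(rec.col))
        if key in entries:
            raise ValueError(f"duplicate array-definition key {key}")
        chrom = getattr(rec, "chromosome", None)
        if isinstance(chrom, float) and math.isnan(chrom):
            chrom = None
        pos = getattr(rec, "position_kb", None)
        if pos is not None:
            pos = float(pos)
            if math.isnan(pos):
                pos = None
            elif pos < 0:
                raise ValueError(f"negative chromosomal position at {key}")
        entries[key] = ArrayEntry(str(rec.gene), chrom, pos)
    return ArrayDefinition(entries)


def records_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    """View score records as a DataFrame (kvp rendered as text)."""
    rows = []
    for r in records:
        rows.append({
            "row": r.row, "col": r.col, "raw_size": r.raw_size,
            "plate_id": r.plate_id, "query": r.query, "array_gene": r.array_gene,
            "normalized_size": np.nan if r.normalized_size is None else r.normalized_size,
            "score": np.nan if r.score is None else r.score,
            "kvp": _fmt_kvp(r.kvp),
        })
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
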