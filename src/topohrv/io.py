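"""Reading and writing RR series and persistence diagrams.

RR input files are plain text or CSV, one beat per row: the first
column is the RR interval in ms (decimals allowed), an optional second
column carries the annotation character (``N`` = normal, anything else
= non-normal).  A header row is detected automatically (a first row
whose first field is not numeric).  Diagram files are CSV with a
``birth,death`` header, one pair per row, repetitions preserved.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .persistence import PersistenceDiagram, PersistencePair
from .series import RRSeries

__all__ = [
    "read_rr_file",
    "write_rr_file",
    "read_diagram_csv",
    "write_diagram_csv",
]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _split_row(line: str) -> list[str]:
    for sep in (",", ";", "\t"):
        if sep in line:
            return [t.strip() for t in line.split(sep)]
    return line.split()


def read_rr_file(path: str | Path, subject_id: str | None = None) -> RRSeries:
    """Read an RR series from a plain-text or CSV file."""
    path = Path(path)
    values: list[float] = []
    annotations: list[str] = []
    has_ann = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _split_row(line)
            if not _is_number(tokens[0]):
                if lineno == 1 or not values:
                    continue  # header row
                raise ValueError(f"{path}: malformed row {lineno}: {line!r}")
            values.append(float(tokens[0]))
            if len(tokens) > 1 and tokens[1]:
                annotations.append(tokens[1])
                has_ann = True
            else:
                annotations.append("N")
    if not values:
        raise ValueError(f"{path}: no RR values found")
    return RRSeries(
        values,
        annotations if has_ann else None,
        subject_id=subject_id or path.stem,
    )


def write_rr_file(series: RRSeries, path: str | Path) -> None:
    """Write a series in the same two-column text format."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rr_ms", "annotation"])
        ann = (
            series.annotations
            if series.annotations is not None
            else ["N"] * len(series)
        )
        for v, a in zip(series.values, ann):
            writer.writerow([f"{v:.6g}", a])


def write_diagram_csv(diagram: PersistenceDiagram, path: str | Path) -> None:
    """Write a diagram as ``birth,death`` CSV, repetitions preserved."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["birth", "death"])
        for p in diagram.pairs:
            writer.writerow([f"{p.birth:.10g}", f"{p.death:.10g}"])


def read_diagram_csv(path: str | Path) -> PersistenceDiagram:
    """Read a diagram written by :func:`write_diagram_csv`."""
    pairs: list[PersistencePair] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or not _is_number(row[0]):
                continue
            pairs.append(PersistencePair(float(row[0]), float(row[1])))
    return PersistenceDiagram(tuple(pairs))
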