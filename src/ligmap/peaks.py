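"""2D amide peak lists: the Peak record and TSV / Sparky-dialect I/O.

A TROSY-HSQC of a protein gives one peak per non-proline backbone amide,
located by its 1H and 15N chemical shifts (ppm) with an intensity (height).
Assigned peaks carry a residue label such as ``F112`` or ``112`` (mature
numbering, optional one-letter code).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Peak:
    """One 2D amide resonance."""

    id: str
    shift_h: float  # 1H chemical shift, ppm
    shift_n: float  # 15N chemical shift, ppm
    height: float = 1.0
    assignment: str | None = None  # e.g. "F112", "112F" or "112"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shift_h) and np.isfinite(self.shift_n)):
            raise ValueError(f"peak {self.id}: non-finite chemical shift")
        if self.height < 0:
            raise ValueError(f"peak {self.id}: negative height")

    @property
    def residue_number(self) -> int | None:
        """Mature residue number parsed from the assignment, if any."""
        if self.assignment is None:
            return None
        m = re.search(r"-?\d+", self.assignment)
        return int(m.group()) if m else None


_TSV_COLUMNS = ["id", "assignment", "shift_h", "shift_n", "height"]


def read_peaklist_tsv(path: str | Path) -> list[Peak]:
    """Read a peak list TSV (columns: id, assignment?, shift_h, shift_n, height)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    missing = {"id", "shift_h", "shift_n"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        assignment = getattr(row, "assignment", None)
        if assignment is not None and (pd.isna(assignment) or assignment == ""):
            assignment = None
        height = float(getattr(row, "height", 1.0))
        peaks.append(
            Peak(
                id=str(row.id),
                shift_h=float(row.shift_h),
                shift_n=float(row.shift_n),
                height=height,
                assignment=None if assignment is None else str(assignment),
            )
        )
    return peaks


def write_peaklist_tsv(path: str | Path, peaks: list[Peak], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for p in peaks:
            fh.write(
                f"{p.id}\t{p.assignment or ''}\t{p.shift_h:.4f}\t"
                f"{p.shift_n:.4f}\t{p.height:.6g}\n"
            )


_SPARKY_ASSIGN_RE = re.compile(r"^([A-Za-z]?)(-?\d+)(?:[A-Za-z0-9]*)?(?:-|$)")


def read_peaklist_sparky(path: str | Path) -> list[Peak]:
    """Read a Sparky-style peak list.

    Expected layout per data line: ``assignment  w1(15N)  w2(1H)  [height]``
    with an optional ``Assignment w1 w2 ...`` header line.  Unassigned peaks
    use ``?-?`` in the assignment column.  Sparky lists put the 15N
    dimension first for an N-HSQC.
    """
    peaks: list[Peak] = []
    counter = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        fields = line.split()
        if len(fields) < 3:
            continue
        label, w1, w2 = fields[0], float(fields[1]), float(fields[2])
        height = float(fields[3]) if len(fields) > 3 else 1.0
        counter += 1
        assignment = None
        if not label.startswith("?"):
            m = _SPARKY_ASSIGN_RE.match(label)
            if m:
                assignment = f"{m.group(1).upper()}{m.group(2)}"
        peaks.append(
            Peak(
                id=f"pk{counter}",
                shift_h=w2,
                shift_n=w1,
                height=abs(height),
                assignment=assignment,
            )
        )
    return peaks


def read_peaklist(path: str | Path) -> list[Peak]:
    """Dispatch on content: tab-separated with header -> TSV, else Sparky."""
    first = ""
    for line in Path(path).read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            first = line
            break
    if "\t" in first and "id" in first.split("\t"):
        return read_peaklist_tsv(path)
    return read_peaklist_sparky(path)
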