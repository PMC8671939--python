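"""Expression-construct bookkeeping and sequence feature scanning.

Recombinant constructs carry a cleavable N-terminal tag, may leave a short
extension ("GP" scar) ahead of mature residue 1 after protease cleavage, and
may be truncated by an engineered stop codon.  All residue references here
use *mature* 1-based numbering so that positions quoted for the native
protein (Cys5, Glu64, Arg90, ...) line up; extension residues get
non-positive labels (e.g. -1 and 0 for a "GP" scar).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: N-glycosylation sequon: Asn-X-Ser/Thr with X != Pro.  Lookahead so that
#: overlapping candidates are all reported.
_SEQUON_RE = re.compile(r"(?=N[^P](?:S|T))")


class SequenceError(ValueError):
    """Invalid sequence content or out-of-bounds residue arithmetic."""


def _validate_sequence(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - CANONICAL_AA
    if bad:
        raise SequenceError(
            f"{what} contains non-canonical letters: {sorted(bad)}"
        )


@dataclass(frozen=True)
class Construct:
    """An expression construct in raw (pre-cleavage) coordinates.

    Parameters
    ----------
    raw_sequence
        One-letter amino-acid string of the full translated product.
    tag_region
        1-based inclusive interval of the cleavable N-terminal segment,
        or ``None`` for an untagged construct.
    extension
        Residues left after cleavage but before mature position 1
        (e.g. ``"GP"``); empty string if none.
    mature_offset
        1-based index in ``raw_sequence`` of mature residue 1.
    stop_position
        Optional mature position of an engineered stop codon; the residue
        at this position and all later ones are absent from the product.
    """

    raw_sequence: str
    tag_region: tuple[int, int] | None = None
    extension: str = ""
    mature_offset: int = 1
    stop_position: int | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.raw_sequence, "raw_sequence")
        n = len(self.raw_sequence)
        if self.tag_region is not None:
            lo, hi = self.tag_region
            if not (1 <= lo <= hi <= n):
                raise SequenceError(
                    f"tag_region {self.tag_region} outside sequence of length {n}"
                )
            expected_offset = hi + len(self.extension) + 1
        else:
            expected_offset = len(self.extension) + 1
        if self.mature_offset != expected_offset:
            raise SequenceError(
                f"mature_offset {self.mature_offset} inconsistent with tag "
                f"({self.tag_region}) + extension ({self.extension!r}); "
                f"expected {expected_offset}"
            )
        if self.mature_offset > n + 1:
            raise SequenceError("mature_offset beyond end of raw_sequence")
        ext_start = self.mature_offset - len(self.extension)
        actual_ext = self.raw_sequence[ext_start - 1 : self.mature_offset - 1]
        if actual_ext != self.extension:
            raise SequenceError(
                f"extension {self.extension!r} does not match raw sequence "
                f"segment {actual_ext!r}"
            )


@dataclass(frozen=True)
class Sequon:
    """A potential N-glycosylation site (N-X-S/T, X != P)."""

    position: int  # mature 1-based index of the Asn
    triplet: str

    def __post_init__(self) -> None:
        if not _SEQUON_RE.match(self.triplet) or len(self.triplet) != 3:
            raise SequenceError(f"{self.triplet!r} is not a valid sequon")


@dataclass(frozen=True)
class CleavageResult:
    """Mature product of tag cleavage plus its numbering bookkeeping."""

    mature_sequence: str
    #: extension residues with their non-positive mature labels, N->C order
    extension_residues: tuple[tuple[int, str], ...]
    #: mature position -> 1-based index in the construct's raw sequence
    numbering_map: dict[int, int] = field(repr=False)


def cleave_construct(construct: Construct) -> CleavageResult:
    """Remove the cleavable tag and return the mature-numbered product.

    The mature sequence starts at mature position 1.  Extension residues
    retained after cleavage (e.g. a "GP" protease scar) are reported
    separately with labels ..., -1, 0 so mature numbering is unshifted.
    The numbering map is a bijection from mature position (including the
    non-positive extension labels) to raw-sequence index.
    """
    raw = construct.raw_sequence
    off = construct.mature_offset
    ext = construct.extension
    mature = raw[off - 1 :]
    ext_labels = range(1 - len(ext), 1)  # e.g. (-1, 0) for "GP", 0-length ok
    extension_residues = tuple(
        (label, ext[i]) for i, label in enumerate(ext_labels)
    )
    numbering = {label: off - len(ext) + i for i, label in enumerate(ext_labels)}
    numbering.update({i + 1: off + i for i in range(len(mature))})
    return CleavageResult(mature, extension_residues, numbering)


def apply_truncation(mature_seq: str, stop_position: int) -> tuple[str, int]:
    """Truncate at an engineered stop codon in mature numbering.

    The residue at ``stop_position`` and everything after it are removed.
    Returns the truncated sequence and the number of residues removed.
    """
    n = len(mature_seq)
    if not 1 <= stop_position <= n + 1:
        raise SequenceError(
            f"stop_position {stop_position} out of range 1..{n + 1}"
        )
    truncated = mature_seq[: stop_position - 1]
    return truncated, n - len(truncated)


def scan_sequons(mature_seq: str) -> list[Sequon]:
    """Exhaustively scan for N-X-S/T sequons (X != P), ascending order."""
    if not mature_seq:
        raise SequenceError("empty sequence")
    _validate_sequence(mature_seq)
    return [
        Sequon(m.start() + 1, mature_seq[m.start() : m.start() + 3])
        for m in _SEQUON_RE.finditer(mature_seq)
    ]


def find_residue_positions(mature_seq: str, residue_letter: str) -> list[int]:
    """All mature 1-based positions of one residue type, ascending."""
    if residue_letter not in CANONICAL_AA:
        raise SequenceError(f"{residue_letter!r} is not a canonical residue")
    return [i + 1 for i, aa in enumerate(mature_seq) if aa == residue_letter]


def count_differences(seq_a: str, seq_b: str) -> int:
    """Hamming distance between two pre-aligned equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise SequenceError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)}); "
            "inputs must be pre-aligned"
        )
    return sum(a != b for a, b in zip(seq_a, seq_b))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from a FASTA file as {record id: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def load_construct_config(path: str | Path) -> Construct:
    """Load a construct from a plain-text key = value config.

    Recognised keys: ``raw_sequence`` (required), ``tag_region`` (as
    ``start-end``), ``extension``, ``mature_offset``, ``stop_position``.
    Lines starting with ``#`` are comments.
    """
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    if "raw_sequence" not in values:
        raise SequenceError(f"{path}: missing raw_sequence")
    tag = None
    if values.get("tag_region"):
        lo, _, hi = values["tag_region"].partition("-")
        tag = (int(lo), int(hi))
    extension = values.get("extension", "")
    if "mature_offset" in values:
        mature_offset = int(values["mature_offset"])
    else:
        mature_offset = (tag[1] if tag else 0) + len(extension) + 1
    stop = int(values["stop_position"]) if values.get("stop_position") else None
    return Construct(
        raw_sequence=values["raw_sequence"].upper().replace(" ", ""),
        tag_region=tag,
        extension=extension,
        mature_offset=mature_offset,
        stop_position=stop,
    )


def construct_report(construct: Construct) -> dict:
    """Full bookkeeping report: cleavage, truncation, sequons, cysteines."""
    cleaved = cleave_construct(construct)
    mature = cleaved.mature_sequence
    report: dict = {
        "mature_length": len(mature),
        "mature_sequence": mature,
        "extension": "".join(aa for _, aa in cleaved.extension_residues),
        "sequons": scan_sequons(mature),
        "cysteines": find_residue_positions(mature, "C"),
    }
    if construct.stop_position is not None:
        truncated, removed = apply_truncation(mature, construct.stop_position)
        report["truncated_length"] = len(truncated)
        report["residues_removed"] = removed
        report["truncated_sequence"] = truncated
    return report
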