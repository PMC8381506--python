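"""Reading and writing the annotation formats around the pipeline.

Internally every interval is 0-based, half-open (the BED convention).
RepeatMasker ``.out`` coordinates (1-based, inclusive) are converted on
read.  Gold-standard labels are represented as a per-position integer
track over the five labels (0 = no repeat, 1..4 = repeat classes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RepeatClass",
    "ClassMapping",
    "AnnotationRecord",
    "FormatError",
    "read_fasta",
    "read_class_mapping",
    "parse_repeatmasker_out",
    "records_to_label_track",
    "read_bed",
    "write_bed",
]


class FormatError(ValueError):
    """A file did not conform to its expected dialect."""


class RepeatClass(IntEnum):
    """The four repeat classes plus the no-repeat label (id 0)."""

    NOREP = 0
    HSAT23 = 1
    ALPHOID = 2
    ALU = 3
    LINE1 = 4


#: The set C of true repeat classes (excludes the no-repeat label).
REPEAT_CLASSES: tuple[RepeatClass, ...] = (
    RepeatClass.HSAT23,
    RepeatClass.ALPHOID,
    RepeatClass.ALU,
    RepeatClass.LINE1,
)

N_CLASSES = 5


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated repeat interval on a named sequence.

    Coordinates are 0-based half-open; ``repeat_class`` is never NOREP.
    """

    sequence_name: str
    start: int
    end: int
    repeat_class: RepeatClass
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.sequence_name}"
            )
        if self.repeat_class == RepeatClass.NOREP:
            raise ValueError("annotation records must carry a repeat class, not NOREP")


class ClassMapping(dict):
    """Map from repeat ID (e.g. a RepeatMasker repeat name) to RepeatClass.

    Unmapped IDs are silently ignored during label construction; mapping
    an ID to NOREP is rejected.
    """

    def __setitem__(self, key: str, value: RepeatClass) -> None:
        value = RepeatClass(value)
        if value == RepeatClass.NOREP:
            raise ValueError(f"repeat ID {key!r} cannot map to NOREP")
        super().__setitem__(key, value)

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, RepeatClass | int | str]]) -> "ClassMapping":
        mapping = cls()
        for key, value in items:
            if isinstance(value, str):
                value = RepeatClass[value]
            mapping[key] = RepeatClass(value)
        return mapping


def read_class_mapping(path: str | Path) -> ClassMapping:
    """Read a two-column ``repeat_id<TAB>class_name`` mapping file."""
    mapping = ClassMapping()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            repeat_id, name = fields
            try:
                mapping[repeat_id] = RepeatClass[name]
            except KeyError:
                raise FormatError(
                    f"{path}:{lineno}: unknown repeat class name {name!r}"
                ) from None
    return mapping


_NON_ACGT = re.compile(r"[^ACGT]")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``(name, sequence)`` tuples.

    Sequences are uppercased and every non-ACGT symbol (ambiguity codes
    included) is replaced by N, since the downstream encoder knows only
    the five symbols A, C, G, T, N.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: expected FASTA header line starting with '>'"
                )
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _NON_ACGT.sub("N", str(record.seq).upper())
        records.append((record.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def parse_repeatmasker_out(
    path: str | Path, mapping: ClassMapping
) -> list[AnnotationRecord]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard dialect has three header lines followed by
    whitespace-delimited columns; query coordinates (columns 6 and 7,
    1-based inclusive) are converted to 0-based half-open.  Records whose
    repeat name (column 10) is absent from ``mapping`` are dropped.
    Strand is ignored: the per-base annotation is strand-agnostic.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path) as handle:
        lines = handle.readlines()
    for lineno, line in enumerate(lines[3:], 4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 10:
            raise FormatError(f"{path}:{lineno}: expected >= 10 columns")
        name, begin, end, repeat_id = fields[4], fields[5], fields[6], fields[9]
        try:
            begin_i, end_i = int(begin), int(end)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric coordinate fields {begin!r}, {end!r}"
            ) from None
        if repeat_id not in mapping:
            continue
        records.append(
            AnnotationRecord(
                sequence_name=name,
                start=begin_i - 1,
                end=end_i,
                repeat_class=mapping[repeat_id],
                source_id=repeat_id,
            )
        )
    return records


def records_to_label_track(
    records: Sequence[AnnotationRecord], sequence_length: int
) -> np.ndarray:
    """Paint annotation records onto a per-position label track.

    Overlaps between records of different classes are resolved
    last-writer-wins in input order (a deterministic rule; genuinely
    ambiguous base pairs are rare in real gold standards).  Uncovered
    positions stay 0.
    """
    track = np.zeros(sequence_length, dtype=np.int8)
    for record in records:
        if record.end > sequence_length:
            raise ValueError(
                f"record [{record.start}, {record.end}) exceeds sequence "
                f"length {sequence_length}"
            )
        track[record.start : record.end] = int(record.repeat_class)
    return track


def read_bed(path: str | Path) -> list[AnnotationRecord]:
    """Read BED (>= 4 columns; column 4 holds the repeat class name)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] < 4:
        raise FormatError(f"{path}: need at least 4 BED columns (chrom, start, end, name)")
    records = []
    for row in frame.itertuples(index=False):
        try:
            repeat_class = RepeatClass[str(row[3])]
        except KeyError:
            raise FormatError(f"{path}: unknown repeat class name {row[3]!r}") from None
        records.append(
            AnnotationRecord(
                sequence_name=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                repeat_class=repeat_class,
            )
        )
    return records


def write_bed(
    segments, sequence_name: str, path: str | Path, append: bool = False
) -> None:
    """Write classified segments as BED5 (name = class, score = rounded sum).

    ``segments`` must be sorted by start and non-overlapping.  With
    ``append`` the lines are added to an existing file (multi-record
    FASTA predictions write one block per sequence).
    """
    previous_end = None
    lines = []
    for segment in segments:
        if previous_end is not None and segment.start < previous_end:
            raise ValueError(
                f"overlapping segments at {segment.start} < {previous_end}"
            )
        previous_end = segment.end
        lines.append(
            f"{sequence_name}\t{segment.start}\t{segment.end}"
            f"\t{segment.repeat_class.name}\t{round(segment.score)}\n"
        )
    with open(path, "a" if append else "w") as handle:
        handle.writelines(lines)
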