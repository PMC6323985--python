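"""Readers and writers for the text formats the toolkit touches.

Single home for the coordinate convention: every interval in every module is
0-based half-open (BED convention). The only place 1-based coordinates appear
is wiggle output, where the fixedStep declaration adds exactly one to start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Peak",
    "TagRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tags",
    "write_tags",
    "write_wig_fixedstep",
    "read_fasta",
    "write_fasta",
    "read_pcm",
]


class BedParseError(ValueError):
    """Malformed BED/tag line; message carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (half-open)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A peak-caller interval with provenance.

    ``summit_offset`` is relative to ``interval.start``; ``None`` means the
    caller reported no point-source (narrowPeak column 10 value -1).
    """

    interval: GenomicInterval
    caller: str = ""
    experiment_id: str = ""
    tf: str = ""
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside "
                f"[0, {len(self.interval)})"
            )


@dataclass(frozen=True)
class TagRecord:
    """A deduplicated alignment reduced to its 5' start (chrom, pos5, strand)."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError(f"negative tag position {self.pos5}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer {what}: {token!r}") from exc


def read_bed(
    path: str | Path,
    *,
    caller: str = "",
    experiment_id: str = "",
    tf: str = "",
) -> list[Peak]:
    """Read BED3-BED6 or ENCODE narrowPeak into :class:`Peak` records.

    narrowPeak (BED6+4) column 10 is the summit offset; -1 maps to ``None``.
    The optional keyword arguments stamp provenance onto every record.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"line {lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            summit: int | None = None
            if len(fields) >= 10:  # narrowPeak
                summit_raw = _parse_int(fields[9], "summit", lineno)
                summit = None if summit_raw == -1 else summit_raw
                if summit is not None and not (0 <= summit < end - start):
                    raise BedParseError(
                        f"line {lineno}: summit {summit} outside peak"
                    )
            peaks.append(
                Peak(
                    interval=interval,
                    caller=caller,
                    experiment_id=experiment_id,
                    tf=tf,
                    score=score,
                    summit_offset=summit,
                )
            )
    return peaks


def write_bed(
    items: Iterable[GenomicInterval | Peak],
    path: str | Path,
    *,
    name_from_caller: bool = False,
) -> None:
    """Write intervals (or peaks) as sorted BED.

    Output is BED3, or BED5 (name, score) when peaks carry a caller name and
    ``name_from_caller`` is set. Sorted by (chrom, start, end) so the file
    round-trips through :func:`read_bed` deterministically.
    """
    rows = []
    for item in items:
        iv = item.interval if isinstance(item, Peak) else item
        if name_from_caller and isinstance(item, Peak):
            score = item.score if item.score is not None else 0
            rows.append((iv.chrom, iv.start, iv.end, item.caller or ".", score))
        else:
            rows.append((iv.chrom, iv.start, iv.end))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tags(path: str | Path) -> list[TagRecord]:
    """Read tags from 3-column TSV (chrom, pos5, strand) or BED6.

    For BED6 the 5' position is derived from strand: the start for '+'
    reads, end-1 for '-' reads (half-open BED end).
    """
    tags: list[TagRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                chrom, pos_s, strand = fields
                pos5 = _parse_int(pos_s, "position", lineno)
            elif len(fields) >= 6:
                chrom = fields[0]
                start = _parse_int(fields[1], "start", lineno)
                end = _parse_int(fields[2], "end", lineno)
                strand = fields[5]
                pos5 = start if strand == "+" else end - 1
            else:
                raise BedParseError(
                    f"line {lineno}: expected 3 (TSV) or >=6 (BED6) fields, "
                    f"got {len(fields)}"
                )
            try:
                tags.append(TagRecord(chrom, pos5, strand))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return tags


def write_tags(tags: Iterable[TagRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f"{tag.chrom}\t{tag.pos5}\t{tag.strand}\n")


def write_wig_fixedstep(
    values_per_chrom: dict[str, Sequence[float]] | dict[str, np.ndarray],
    path: str | Path,
) -> list[str]:
    """Write per-base vectors as fixedStep wiggle (step=1 span=1).

    Wiggle is 1-based, so every block starts at position 1 for data that
    begins at 0-based position 0. Integer-valued entries (including the -1
    mappability sentinel) are emitted without a decimal point. Zero-length
    chromosomes are skipped; their names are returned as warnings.
    """
    skipped: list[str] = []
    with open(path, "w") as fh:
        for chrom, values in values_per_chrom.items():
            arr = np.asarray(values)
            if arr.size == 0:
                skipped.append(chrom)
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
            for v in arr:
                fv = float(v)
                if math.isfinite(fv) and fv == int(fv):
                    fh.write(f"{int(fv)}\n")
                else:
                    fh.write(f"{fv}\n")
    return skipped


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered chrom -> sequence map.

    Sequences are upper-cased (soft-masking ignored); record names are the
    header up to the first whitespace; duplicates and empty files are errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in genome:
            raise ValueError(f"duplicate FASTA record name: {name}")
        genome[name] = str(record.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pcm(path: str | Path) -> list["pwm_scan.PositionCountMatrix"]:
    """Read HOCOMOCO-style plain-text position count matrices.

    Layout: a ``>name`` header followed by L whitespace-separated rows of
    four counts (columns A, C, G, T); multiple records per file allowed.
    """
    from . import pwm_scan  # local import to avoid a cycle

    matrices = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is None:
            return
        if not rows:
            raise ValueError(f"PCM record {name!r} has no count rows")
        matrices.append(
            pwm_scan.PositionCountMatrix(tf_name=name, counts=np.array(rows))
        )

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                values = [float(tok) for tok in line.split()]
                if len(values) != 4:
                    raise ValueError(
                        f"PCM row must have 4 columns (A C G T), got {len(values)}"
                    )
                rows.append(values)
    flush()
    if not matrices:
        raise ValueError(f"no PCM records found in {path}")
    return matrices
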