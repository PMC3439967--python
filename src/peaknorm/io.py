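"""Readers and writers for the genomic text formats the tool touches.

All coordinates are handled 0-based half-open internally (native BED
convention).  The only 1-based emission is the WIG writer, which converts on
output.  Tag (read) records are reduced to a strand-aware 5' coordinate:
``start`` for plus-strand reads and ``end - 1`` for minus-strand reads
(BED ``end`` is exclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """Malformed record in a BED-like file; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A ChIP-enriched region with a summit position inside it."""

    interval: GenomicInterval
    summit: int
    name: str | None = None
    source_score: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class SequenceTag:
    """One aligned read reduced to its strand-aware 5'-most coordinate."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError(f"pos5 must be >= 0, got {self.pos5}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _data_lines(path: str | Path):
    """Yield (line_number, stripped fields) skipping headers and comments."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip():
                continue
            if stripped.lstrip().lower().startswith(_SKIP_PREFIXES):
                continue
            yield lineno, stripped.split("\t")


def _parse_coords(fields: Sequence[str], lineno: int, path) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >= 3 fields, got {len(fields)}")
    chrom = fields[0].strip()
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0 or end <= start:
        raise BedParseError(
            f"{path}:{lineno}: invalid interval [{start}, {end})"
        )
    return chrom, start, end


def parse_peak_bed(path: str | Path, summit_mode: str = "midpoint") -> list[Peak]:
    """Read a peak BED file.

    Parameters
    ----------
    path
        BED3+ file; track/browser/comment lines are skipped.
    summit_mode
        ``"midpoint"`` sets each summit to ``floor((start+end)/2)`` (the
        optional 4th column is kept as the peak name).  ``"column4_offset"``
        reads the 4th column as an integer summit offset from ``start``.
    """
    if summit_mode not in ("midpoint", "column4_offset"):
        raise ValueError(f"unknown summit_mode {summit_mode!r}")
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, lineno, path)
        name = None
        score = None
        if summit_mode == "midpoint":
            summit = (start + end) // 2
            if len(fields) >= 4 and fields[3]:
                name = fields[3]
        else:
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: summit offset column missing")
            try:
                offset = int(fields[3])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer summit offset {fields[3]!r}"
                ) from exc
            summit = start + offset
            if len(fields) >= 5 and fields[4]:
                name = fields[4]
        if len(fields) >= 5 and summit_mode == "midpoint":
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        try:
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit, name, score)
            )
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def parse_tag_bed(path: str | Path) -> list[SequenceTag]:
    """Read aligned reads from a BED6-like file into 5'-coordinate tags.

    Reads without a strand column (or with strand ``"."``) default to "+"
    with a single warning, so minimal BED3 tag files remain usable.
    """
    tags: list[SequenceTag] = []
    warned = False
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, lineno, path)
        strand = fields[5].strip() if len(fields) >= 6 else ""
        if strand in ("", "."):
            if not warned:
                logger.warning(
                    "%s: tags without strand information default to '+'", path
                )
                warned = True
            strand = "+"
        if strand not in ("+", "-"):
            raise BedParseError(f"{path}:{lineno}: invalid strand {strand!r}")
        pos5 = start if strand == "+" else end - 1
        tags.append(SequenceTag(chrom, pos5, strand))
    return tags


def write_interval_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED lines (chrom, start, end[, name[, score]])."""
    with open(path, "w") as fh:
        for peak in peaks:
            fields = [peak.chrom, str(peak.start), str(peak.end)]
            if peak.name is not None:
                fields.append(peak.name)
                if peak.source_score is not None:
                    fields.append(f"{peak.source_score:g}")
            fh.write("\t".join(fields) + "\n")


def write_m_wig(
    peaks: Sequence[Peak],
    m_values: Sequence[float],
    path: str | Path,
    track_name: str,
) -> None:
    """Write per-peak M values as a variableStep WIG track.

    Peaks are sorted by (chrom, start); a new ``variableStep`` declaration is
    emitted whenever the chromosome or the span (peak length) changes.  WIG
    positions are 1-based, hence ``start + 1``.
    """
    import math

    if len(peaks) != len(m_values):
        raise ValueError("peaks and m_values must have equal length")
    for peak, m in zip(peaks, m_values):
        if not math.isfinite(m):
            raise ValueError(
                f"non-finite M value for peak {peak.chrom}:{peak.start}-{peak.end}"
            )
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        current: tuple[str, int] | None = None
        for i in order:
            peak = peaks[i]
            span = len(peak.interval)
            if current != (peak.chrom, span):
                fh.write(f"variableStep chrom={peak.chrom} span={span}\n")
                current = (peak.chrom, span)
            fh.write(f"{peak.start + 1} {m_values[i]:g}\n")


def parse_tss_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSS table (BED-like: chrom, tss, tss+1, gene_id, score, strand)."""
    genes: list[GeneAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise BedParseError(f"{path}:{lineno}: expected 6 fields")
        chrom = fields[0].strip()
        try:
            tss = int(fields[1])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer tss") from exc
        gene_id = fields[3]
        strand = fields[5].strip()
        try:
            genes.append(GeneAnnotation(gene_id, chrom, strand, tss))
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line text file into a set of gene ids."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
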