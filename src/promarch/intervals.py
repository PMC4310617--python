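"""Genomic intervals, BED I/O, promoter windows, and peak-to-window mapping.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A "peak" is a :class:`GenomicInterval` carrying an ENCODE
style quality score (0-1000) and a transcription-factor label.  A proximal
promoter is a symmetric window around the TSS (default half-width 500 bp,
i.e. the classic +/-500 bp window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptAnnotation",
    "PromoterWindow",
    "BedParseError",
    "parse_bed",
    "write_bed",
    "read_annotations",
    "promoter_window",
    "filter_by_score",
    "overlap_length",
    "map_peaks_to_windows",
]


class BedParseError(ValueError):
    """A malformed BED data line, reported with its 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, scored, labelled interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if not (0 <= self.score <= 1000):
            raise ValueError(f"score {self.score} outside [0, 1000]")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript reduced to its TSS (plus optional full span)."""

    tx_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PromoterWindow:
    """A symmetric window around a TSS; ``clipped`` records chromosome-edge truncation."""

    tx_id: str
    interval: GenomicInterval
    half_width: int
    clipped: bool = False


def parse_bed(stream: IO[str] | Iterable[str]) -> list[GenomicInterval]:
    """Parse BED lines into intervals.

    Columns 1-3 (chrom, start, end) are required; columns 4-6 (name, score,
    strand) are optional and default to "", 0, and '.'.  ``track``,
    ``browser`` and ``#`` comment lines and blank lines are skipped.  A
    malformed data line raises :class:`BedParseError` naming the line.
    """
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: fewer than 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-integer coordinate") from None
        label = fields[3] if len(fields) > 3 else ""
        try:
            score = int(float(fields[4])) if len(fields) > 4 and fields[4] not in (".", "") else 0
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
        strand = fields[5] if len(fields) > 5 and fields[5] else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand, score, label))
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: IO[str]) -> None:
    """Write 6-column BED, one line per interval, preserving input order."""
    for iv in intervals:
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{iv.score}\t{iv.strand}\n")


def read_annotations(stream: IO[str] | Iterable[str]) -> list[TranscriptAnnotation]:
    """Read transcript annotations from BED6.

    The TSS of a '+' transcript is the BED start; of a '-' transcript the BED
    end coordinate (the 5' end in each case).
    """
    anns = []
    for iv in parse_bed(stream):
        if iv.strand not in ("+", "-"):
            raise ValueError(f"transcript {iv.label!r} lacks a strand")
        tss = iv.start if iv.strand == "+" else iv.end
        anns.append(TranscriptAnnotation(iv.label, iv.chrom, iv.strand, tss, span=iv))
    return anns


def promoter_window(
    tx: TranscriptAnnotation,
    half_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PromoterWindow:
    """The symmetric window ``[tss - half_width, tss + half_width)``.

    The window is strand-agnostic (it is symmetric); the strand is recorded
    for downstream use.  Windows are clipped at position 0 and, when
    ``chrom_sizes`` is given, at the chromosome end; clipping is flagged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    start = tx.tss - half_width
    end = tx.tss + half_width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_sizes is not None and end > chrom_sizes[tx.chrom]:
        end, clipped = chrom_sizes[tx.chrom], True
    iv = GenomicInterval(tx.chrom, start, end, tx.strand, 0, tx.tx_id)
    return PromoterWindow(tx.tx_id, iv, half_width, clipped)


def filter_by_score(
    peaks: Iterable[GenomicInterval], cutoff: int
) -> list[GenomicInterval]:
    """Retain peaks with score strictly above ``cutoff``.

    ``cutoff=0`` is the "all data" mode and keeps every peak, including those
    scored exactly 0.  ``cutoff=500`` is the high-quality mode (score over
    half the 0-1000 maximum).
    """
    if not (0 <= cutoff <= 1000):
        raise ValueError("cutoff must lie in [0, 1000]")
    if cutoff == 0:
        return list(peaks)
    return [p for p in peaks if p.score > cutoff]


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def map_peaks_to_windows(
    windows: Sequence[PromoterWindow],
    peaks: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """For each promoter window, the peaks overlapping it by >= 1 bp.

    Any overlap counts (coverageBed semantics); a peak spanning two windows
    is reported for both.  Backed by a per-chromosome interval tree, so the
    cost is O((n + m) log n) rather than all-pairs.  Returned peak lists are
    sorted by coordinates for determinism.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    out: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        tree = trees.get(w.interval.chrom)
        hits = [] if tree is None else [h.data for h in tree.overlap(w.interval.start, w.interval.end)]
        hits.sort(key=lambda p: (p.start, p.end, p.label, p.score))
        out[w.tx_id] = hits
    return out
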