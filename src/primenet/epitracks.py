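"""Per-base epigenetic annotation of pegRNA target windows.

Chromatin-accessibility (DNase) peaks and methylation calls from one or more
labs are merged by union: a base is marked accessible/methylated if any input
track covers it. A record's genomic anchor then maps each wild-sequence
position to a genomic base, and the boolean readout is reported in the written
5'->3' orientation of the wild sequence (reversed for minus-strand anchors,
since the tracks themselves are locus properties with no strand).

Records without an anchor get all-false vectors (unknown is treated as
inaccessible/unmethylated) so sequence-only tables remain usable; explicit
per-base vectors may also be supplied directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomicAnchor, TargetRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["IntervalSet", "PerBaseAnnotation", "union_tracks", "annotate_window",
           "build_annotation"]


@dataclass(frozen=True)
class IntervalSet:
    """Strand-agnostic genomic intervals, normalized per chromosome.

    ``by_chrom`` maps chromosome name to an (N, 2) int array of sorted,
    merged [start, end) intervals (overlapping or abutting inputs coalesce).
    """

    by_chrom: dict = field(default_factory=dict)

    @staticmethod
    def _normalize(intervals) -> np.ndarray:
        arr = np.asarray(sorted((int(s), int(e)) for s, e in intervals), dtype=np.int64)
        if arr.size == 0:
            return arr.reshape(0, 2)
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalSet":
        return cls({c: cls._normalize(iv) for c, iv in d.items() if len(iv)})

    def covers(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of each genomic position in the track."""
        positions = np.asarray(positions, dtype=np.int64)
        iv = self.by_chrom.get(chrom)
        if iv is None or iv.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < iv[idx[ok], 1]
        return out

    def total_covered(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.by_chrom.values()))


@dataclass
class PerBaseAnnotation:
    """Boolean accessibility/methylation per wild-sequence position, 5'->3'."""

    dnase: np.ndarray
    methyl: np.ndarray

    def __post_init__(self):
        self.dnase = np.asarray(self.dnase, dtype=bool)
        self.methyl = np.asarray(self.methyl, dtype=bool)
        if self.dnase.shape != self.methyl.shape or self.dnase.ndim != 1:
            raise ValidationError("annotation vectors must be 1-D and equal length")

    def __len__(self) -> int:
        return self.dnase.shape[0]


def union_tracks(tracks: list[IntervalSet]) -> IntervalSet:
    """Union of interval sets: covered in the output iff covered in any input."""
    merged: dict[str, list] = {}
    for t in tracks:
        for chrom, iv in t.by_chrom.items():
            merged.setdefault(chrom, []).extend(map(tuple, iv))
    return IntervalSet.from_dict(merged)


def annotate_window(anchor: GenomicAnchor, length: int, track: IntervalSet) -> np.ndarray:
    """Per-base track membership for a window, in wild-sequence orientation.

    Position i of the readout corresponds to genomic base anchor.start + i on
    the plus strand and anchor.start + length - 1 - i on the minus strand.
    """
    if length < 1:
        raise ValidationError(f"window length must be >= 1, got {length}")
    if anchor.chrom not in track.by_chrom:
        logger.warning("chromosome %s absent from track; window all-false",
                       anchor.chrom)
    positions = np.arange(anchor.start, anchor.start + length, dtype=np.int64)
    cov = track.covers(anchor.chrom, positions)
    return cov[::-1].copy() if anchor.strand == "-" else cov


def build_annotation(
    record: TargetRecord,
    dnase: IntervalSet | None = None,
    methyl: IntervalSet | None = None,
    explicit: PerBaseAnnotation | None = None,
) -> PerBaseAnnotation:
    """Annotate one record, from its anchor + tracks or from explicit vectors."""
    n = len(record.wild_seq)
    if explicit is not None:
        if len(explicit) != n:
            raise ValidationError(
                f"record {record.record_id}: explicit annotation length "
                f"{len(explicit)} != sequence length {n}"
            )
        return explicit
    if record.anchor is None:
        logger.warning(
            "record %s has no genomic anchor; epigenetic channels set all-false",
            record.record_id,
        )
        return PerBaseAnnotation(np.zeros(n, bool), np.zeros(n, bool))
    d = annotate_window(record.anchor, n, dnase or IntervalSet())
    m = annotate_window(record.anchor, n, methyl or IntervalSet())
    return PerBaseAnnotation(d, m)
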