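"""Multichannel pseudo-image encoding of pegRNA-target pairs.

Each sequence (wild-type and edited) becomes a 128-position x 8-channel binary
block; the two blocks are stacked along a third axis, giving the model input
its 128 x 8 x 2 shape. Channels:

  0-3  one-hot base identity (A->0, G->1, T->2, C->3)
  4    chromatin accessibility (DNase sensitive -> 1)
  5    DNA methylation (methylated -> 1)
  6    protospacer + PAM + PBS regions
  7    RT (reverse-transcriptase template) region

Sequences shorter than 128 nt are left-aligned and zero-padded on the right,
so a position's meaning is preserved across records of equal layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epitracks import IntervalSet, PerBaseAnnotation, build_annotation
from .io_formats import EfficiencyTriple, RegionSpans, TargetRecord, ValidationError

__all__ = ["ChannelLayout", "PseudoImage", "one_hot_encode",
           "encode_epigenetic_channels", "encode_region_channels",
           "transfer_annotation_to_edit", "build_pseudo_image", "encode_dataset",
           "FRAME_LENGTH", "N_CHANNELS"]

FRAME_LENGTH = 128
N_CHANNELS = 8


@dataclass(frozen=True)
class ChannelLayout:
    base_to_channel: dict = field(
        default_factory=lambda: {"A": 0, "G": 1, "T": 2, "C": 3}
    )
    dnase_channel: int = 4
    methyl_channel: int = 5
    proto_pam_pbs_channel: int = 6
    rt_channel: int = 7


LAYOUT = ChannelLayout()


@dataclass
class PseudoImage:
    """Binary block of shape (128 positions, 8 channels, 2 sequences)."""

    values: np.ndarray
    effective_lengths: tuple[int, int]
    record_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (FRAME_LENGTH, N_CHANNELS, 2):
            raise ValidationError(
                f"pseudo-image must be (128, 8, 2), got {self.values.shape}"
            )


def one_hot_encode(seq: str) -> np.ndarray:
    """(len, 4) one-hot matrix with the A/G/T/C -> 0/1/2/3 channel mapping."""
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq):
        ch = LAYOUT.base_to_channel.get(base)
        if ch is None:
            raise ValidationError(f"non-ACGT base {base!r} at position {i}")
        out[i, ch] = 1.0
    return out


def encode_epigenetic_channels(annot: PerBaseAnnotation) -> np.ndarray:
    """(len, 2) matrix: column 0 accessibility, column 1 methylation."""
    return np.stack(
        [annot.dnase.astype(np.float32), annot.methyl.astype(np.float32)], axis=1
    )


def encode_region_channels(spans: RegionSpans, length: int) -> np.ndarray:
    """(len, 2) matrix: column 0 protospacer|PAM|PBS, column 1 RT region."""
    spans.validate(length)
    out = np.zeros((length, 2), dtype=np.float32)
    for start, end in (spans.protospacer, spans.pam, spans.pbs):
        out[start:end, 0] = 1.0
    out[spans.rt[0]: spans.rt[1], 1] = 1.0
    return out


def transfer_annotation_to_edit(
    wild_annot: PerBaseAnnotation, record: TargetRecord
) -> PerBaseAnnotation:
    """Carry the wild sequence's per-base annotation onto the edited sequence.

    Equal lengths map position-for-position. For indels an ungapped anchor
    alignment is used: positions are matched from the 5' end up to the first
    difference and from the 3' end back to it; inserted bases get False.
    """
    wild, edited = record.wild_seq, record.edited_seq
    nw, ne = len(wild), len(edited)
    if nw != len(wild_annot):
        raise ValidationError(
            f"record {record.record_id}: annotation length {len(wild_annot)} "
            f"!= wild length {nw}"
        )
    if nw == ne:
        return PerBaseAnnotation(wild_annot.dnase.copy(), wild_annot.methyl.copy())

    # longest common prefix / suffix, non-overlapping
    pre = 0
    while pre < min(nw, ne) and wild[pre] == edited[pre]:
        pre += 1
    suf = 0
    while suf < min(nw, ne) - pre and wild[nw - 1 - suf] == edited[ne - 1 - suf]:
        suf += 1
    if pre + suf > min(nw, ne):
        raise ValidationError(
            f"record {record.record_id}: cannot derive wild/edited correspondence"
        )
    d = np.zeros(ne, dtype=bool)
    m = np.zeros(ne, dtype=bool)
    d[:pre], m[:pre] = wild_annot.dnase[:pre], wild_annot.methyl[:pre]
    if suf:
        d[ne - suf:], m[ne - suf:] = wild_annot.dnase[nw - suf:], wild_annot.methyl[nw - suf:]
    return PerBaseAnnotation(d, m)


def _encode_one_sequence(
    seq: str, spans: RegionSpans, annot: PerBaseAnnotation
) -> np.ndarray:
    n = len(seq)
    if n > FRAME_LENGTH:
        raise ValidationError(f"sequence of {n} nt exceeds the {FRAME_LENGTH} frame")
    block = np.zeros((FRAME_LENGTH, N_CHANNELS), dtype=np.float32)
    block[:n, 0:4] = one_hot_encode(seq)
    block[:n, 4:6] = encode_epigenetic_channels(annot)
    block[:n, 6:8] = encode_region_channels(spans, n)
    return block


def _edited_spans(record: TargetRecord) -> RegionSpans:
    """Region spans expressed in edited-sequence coordinates.

    Spans are clipped at the edited length; spans entirely beyond it collapse
    onto the final position (degenerate edits only; typical 99-nt layouts are
    unaffected because edits land inside the RT region).
    """
    ne = len(record.edited_seq)

    def clip(span):
        s, e = span
        s, e = min(s, ne - 1), min(e, ne)
        return (s, max(e, s + 1))

    sp = record.spans
    return RegionSpans(clip(sp.protospacer), clip(sp.pam), clip(sp.pbs), clip(sp.rt))


def build_pseudo_image(record: TargetRecord, annot: PerBaseAnnotation) -> PseudoImage:
    """Encode one record into the (128, 8, 2) block: wild at slice 0, edited at 1."""
    record.validate()
    edited_annot = transfer_annotation_to_edit(annot, record)
    wild_block = _encode_one_sequence(record.wild_seq, record.spans, annot)
    edited_block = _encode_one_sequence(
        record.edited_seq, _edited_spans(record), edited_annot
    )
    values = np.stack([wild_block, edited_block], axis=2)
    return PseudoImage(
        values=values,
        effective_lengths=(len(record.wild_seq), len(record.edited_seq)),
        record_id=record.record_id,
    )


def encode_dataset(
    records: list[TargetRecord],
    dnase: IntervalSet | None = None,
    methyl: IntervalSet | None = None,
    annotations: dict[str, PerBaseAnnotation] | None = None,
) -> tuple[list[tuple[PseudoImage, EfficiencyTriple | None]], dict[str, str]]:
    """Encode a table of records; per-record failures are collected, not fatal.

    Returns (encoded, failures) where ``encoded`` preserves input order for
    the records that succeeded and ``failures`` maps record_id -> message.
    Raises only if every record fails.
    """
    encoded: list[tuple[PseudoImage, EfficiencyTriple | None]] = []
    failures: dict[str, str] = {}
    for rec in records:
        try:
            explicit = (annotations or {}).get(rec.record_id)
            annot = build_annotation(rec, dnase, methyl, explicit=explicit)
            encoded.append((build_pseudo_image(rec, annot), rec.observed))
        except (ValidationError, ValueError) as e:
            failures[rec.record_id] = str(e)
    if records and not encoded:
        raise ValidationError(f"all {len(records)} records failed encoding: {failures}")
    return encoded, failures


def stack_images(encoded) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded pairs into (N,128,8,2) inputs and (N,3) percent targets.

    Records without an observed triple get NaN targets.
    """
    X = np.stack([img.values for img, _ in encoded]).astype(np.float32)
    y = np.full((len(encoded), 3), np.nan, dtype=np.float32)
    for i, (_, obs) in enumerate(encoded):
        if obs is not None:
            y[i] = obs.as_array()
    return X, y
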