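"""Readers and writers for the formats the tool touches.

Sample tables are delimited text with one pegRNA-target pair per row: the
wild-type and edited target sequence, the functional-region spans
(protospacer, PAM, PBS, RT) in 0-based half-open wild-sequence coordinates,
an optional genomic anchor (chrom, start of position 0, strand) and an
optional observed outcome triple in percent. Column names are mapped through
a configurable dialect so existing exports can be read without code change.

Epigenetic tracks arrive as BED-like interval files (0-based half-open).
Checkpoints are single ``.npz`` archives bundling the model configuration,
every parameter and the initialization seed, so a run is replayable.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TargetRecord",
    "RegionSpans",
    "GenomicAnchor",
    "EfficiencyTriple",
    "FormatError",
    "ValidationError",
    "DEFAULT_DIALECT",
    "read_sample_table",
    "write_sample_table",
    "read_fasta",
    "read_bed_intervals",
    "write_bed_intervals",
    "save_checkpoint",
    "load_checkpoint",
]

VALID_BASES = frozenset("ACGT")
MAX_SEQ_LEN = 128


class FormatError(ValueError):
    """File does not conform to the expected format."""


class ValidationError(ValueError):
    """File parsed, but a record violates a domain invariant."""


@dataclass(frozen=True)
class RegionSpans:
    """Functional-region spans, 0-based half-open, in wild-sequence coordinates."""

    protospacer: tuple[int, int]
    pam: tuple[int, int]
    pbs: tuple[int, int]
    rt: tuple[int, int]

    def validate(self, seq_len: int, record_id: str = "?") -> None:
        for name in ("protospacer", "pam", "pbs", "rt"):
            start, end = getattr(self, name)
            if not (0 <= start < end <= seq_len):
                raise ValidationError(
                    f"record {record_id}: {name} span [{start},{end}) outside "
                    f"sequence of length {seq_len}"
                )


@dataclass(frozen=True)
class GenomicAnchor:
    """Genomic position of wild-sequence position 0."""

    chrom: str
    start: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative anchor start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class EfficiencyTriple:
    """Outcome fractions in percent: intended edit, no edit, unintended products."""

    valid: float
    unedited: float
    erroneous: float

    def __post_init__(self):
        for name in ("valid", "unedited", "erroneous"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} efficiency {v} outside [0,100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.valid, self.unedited, self.erroneous], dtype=float)

    def is_complete(self, tol: float = 0.5) -> bool:
        return abs(self.valid + self.unedited + self.erroneous - 100.0) <= tol


@dataclass
class TargetRecord:
    """One pegRNA-target pair."""

    record_id: str
    wild_seq: str
    edited_seq: str
    spans: RegionSpans
    anchor: GenomicAnchor | None = None
    observed: EfficiencyTriple | None = None
    cell_line: str | None = None

    def validate(self) -> None:
        for name, seq in (("wild_seq", self.wild_seq), ("edited_seq", self.edited_seq)):
            if not seq:
                raise ValidationError(f"record {self.record_id}: empty {name}")
            if len(seq) > MAX_SEQ_LEN:
                raise ValidationError(
                    f"record {self.record_id}: {name} longer than {MAX_SEQ_LEN} nt"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"record {self.record_id}: {name} contains non-ACGT "
                    f"character(s) {sorted(bad)}"
                )
        self.spans.validate(len(self.wild_seq), self.record_id)


# Canonical column names; a dialect maps canonical -> actual file column.
DEFAULT_DIALECT: dict[str, str] = {
    "record_id": "record_id",
    "wild_seq": "wild_seq",
    "edited_seq": "edited_seq",
    "protospacer_start": "protospacer_start",
    "protospacer_end": "protospacer_end",
    "pam_start": "pam_start",
    "pam_end": "pam_end",
    "pbs_start": "pbs_start",
    "pbs_end": "pbs_end",
    "rt_start": "rt_start",
    "rt_end": "rt_end",
    "chrom": "chrom",
    "anchor_start": "anchor_start",
    "strand": "strand",
    "eff_valid": "eff_valid",
    "eff_unedited": "eff_unedited",
    "eff_erroneous": "eff_erroneous",
    "cell_line": "cell_line",
}

_REQUIRED = (
    "record_id wild_seq edited_seq protospacer_start protospacer_end "
    "pam_start pam_end pbs_start pbs_end rt_start rt_end"
).split()

_OBS_COLS = ("eff_valid", "eff_unedited", "eff_erroneous")


def _row_value(row, dialect, key):
    col = dialect.get(key)
    if col is None or col not in row or pd.isna(row[col]):
        return None
    return row[col]


def read_sample_table(
    path, dialect: dict[str, str] | None = None, sep: str | None = None
) -> list[TargetRecord]:
    """Read a delimited sample table into validated :class:`TargetRecord` s.

    ``dialect`` maps canonical field names to the file's column names
    (defaults to :data:`DEFAULT_DIALECT`). The separator is sniffed from the
    extension unless given (.tsv -> tab, otherwise comma).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={dialect["record_id"]: str})
    missing = [dialect[k] for k in _REQUIRED if dialect[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[TargetRecord] = []
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        rid = str(row[dialect["record_id"]])
        try:
            if rid in seen_ids:
                raise ValidationError(f"duplicate record_id {rid!r}")
            seen_ids.add(rid)
            spans = RegionSpans(
                protospacer=(int(row[dialect["protospacer_start"]]),
                             int(row[dialect["protospacer_end"]])),
                pam=(int(row[dialect["pam_start"]]), int(row[dialect["pam_end"]])),
                pbs=(int(row[dialect["pbs_start"]]), int(row[dialect["pbs_end"]])),
                rt=(int(row[dialect["rt_start"]]), int(row[dialect["rt_end"]])),
            )
            chrom = _row_value(row, dialect, "chrom")
            anchor = None
            if chrom is not None:
                anchor = GenomicAnchor(
                    chrom=str(chrom),
                    start=int(row[dialect["anchor_start"]]),
                    strand=str(_row_value(row, dialect, "strand") or "+"),
                )
            obs = None
            vals = [_row_value(row, dialect, k) for k in _OBS_COLS]
            if all(v is not None for v in vals):
                obs = EfficiencyTriple(*(float(v) for v in vals))
            cell = _row_value(row, dialect, "cell_line")
            rec = TargetRecord(
                record_id=rid,
                wild_seq=str(row[dialect["wild_seq"]]).upper(),
                edited_seq=str(row[dialect["edited_seq"]]).upper(),
                spans=spans,
                anchor=anchor,
                observed=obs,
                cell_line=None if cell is None else str(cell),
            )
            rec.validate()
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"{path} line {line_no}: {e}") from e
        records.append(rec)
    return records


def write_sample_table(records: list[TargetRecord], path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "wild_seq": r.wild_seq,
            "edited_seq": r.edited_seq,
            "protospacer_start": r.spans.protospacer[0],
            "protospacer_end": r.spans.protospacer[1],
            "pam_start": r.spans.pam[0],
            "pam_end": r.spans.pam[1],
            "pbs_start": r.spans.pbs[0],
            "pbs_end": r.spans.pbs[1],
            "rt_start": r.spans.rt[0],
            "rt_end": r.spans.rt[1],
        }
        if r.anchor is not None:
            row.update(chrom=r.anchor.chrom, anchor_start=r.anchor.start,
                       strand=r.anchor.strand)
        if r.observed is not None:
            row.update(eff_valid=r.observed.valid, eff_unedited=r.observed.unedited,
                       eff_erroneous=r.observed.erroneous)
        if r.cell_line is not None:
            row["cell_line"] = r.cell_line
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs, file order preserved."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append((rec.id, str(rec.seq).upper()))
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    if not out:
        # distinguish empty/garbage files from valid empty parses
        text = Path(path).read_text().strip()
        if not text.startswith(">"):
            raise FormatError(f"{path}: not FASTA (no header line)")
    return out


def read_bed_intervals(path) -> "IntervalSet":
    """Read a BED-like file (>=3 tab-separated columns) into an IntervalSet.

    Coordinates are 0-based half-open; extra columns (name, score, strand,
    narrowPeak fields) are ignored.
    """
    from .epitracks import IntervalSet

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {line_no}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(
                    f"{path} line {line_no}: non-integer coordinate"
                ) from e
            if start >= end:
                raise ValidationError(
                    f"{path} line {line_no}: start {start} >= end {end}"
                )
            if start < 0:
                raise ValidationError(f"{path} line {line_no}: negative start")
            by_chrom.setdefault(chrom, []).append((start, end))
    return IntervalSet.from_dict(by_chrom)


def write_bed_intervals(intervals: "IntervalSet", path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals.by_chrom):
            for start, end in intervals.by_chrom[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def save_checkpoint(model_state: dict, path) -> None:
    """Persist ``{"config": dict, "params": {name: array}, "seed": int}``."""
    payload = {f"param/{k}": np.asarray(v) for k, v in model_state["params"].items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(model_state["config"], sort_keys=True).encode(), dtype=np.uint8
    )
    payload["__seed__"] = np.array(model_state.get("seed", -1), dtype=np.int64)
    np.savez(path, **payload)


def load_checkpoint(path, expected_config: dict | None = None) -> dict:
    with np.load(path) as npz:
        config = json.loads(bytes(npz["__config__"].tobytes()).decode())
        seed = int(npz["__seed__"])
        params = {
            k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")
        }
    if expected_config is not None and expected_config != config:
        diff = {
            k: (expected_config.get(k), config.get(k))
            for k in set(expected_config) | set(config)
            if expected_config.get(k) != config.get(k)
        }
        raise ValidationError(f"checkpoint configuration mismatch: {diff}")
    return {"config": config, "params": params, "seed": seed}
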