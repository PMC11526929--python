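"""On-disk formats: event-table CSV, FASTA/FASTQ, labeled matrices.

The spectral arm starts from per-cell scale-value CSV exports (one row per
cell, one column per detector channel); the sequencing arm starts from
FASTQ. Every writer/reader pair here is a lossless round trip, and readers
never silently drop rows — malformed input raises :class:`FormatError`
naming the offending record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "EventTable",
    "Read",
    "ReadSet",
    "read_event_table",
    "write_event_table",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_matrix",
    "write_matrix",
]

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file did not conform to the expected on-disk format."""


@dataclass
class EventTable:
    """Cells x channels intensity matrix with optional per-cell metadata.

    Parameters
    ----------
    channel_names
        Ordered, unique detector channel identifiers (length C).
    intensities
        ``(n_cells, C)`` array of scale-valued intensities (AU).
    truth_labels
        Optional per-cell ground-truth label (FP name, or an unordered-pair
        label for barcode cells). ``None`` when unlabeled.
    sample_ids
        Optional per-cell sample/transfection identifier.
    """

    channel_names: list[str]
    intensities: np.ndarray
    truth_labels: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (cells x channels)")
        if self.intensities.shape[1] != len(self.channel_names):
            raise ValueError(
                f"intensity columns ({self.intensities.shape[1]}) != "
                f"channel names ({len(self.channel_names)})"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("duplicate channel names")
        for attr in ("truth_labels", "sample_ids"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != self.n_cells:
                raise ValueError(f"{attr} length != n_cells")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row subset preserving order; mask is boolean or index array."""
        idx = np.arange(self.n_cells)[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        take = lambda v: [v[i] for i in idx] if v is not None else None
        return EventTable(
            channel_names=list(self.channel_names),
            intensities=self.intensities[idx],
            truth_labels=take(self.truth_labels),
            sample_ids=take(self.sample_ids),
        )

    def max_intensity(self) -> np.ndarray:
        """Per-cell maximum raw channel intensity (the cutoff statistic)."""
        return self.intensities.max(axis=1) if self.n_cells else np.empty(0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, columns=self.channel_names)


@dataclass
class Read:
    """One sequencing read."""

    id: str
    sequence: str
    qc_pass: bool = True
    truth_label: str | None = None
    orientation: str | None = None  # simulated strand, when known

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """A collection of reads with unique ids."""

    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate read ids")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def subset(self, keep: Iterable[bool]) -> "ReadSet":
        return ReadSet([r for r, k in zip(self.reads, keep) if k])


def read_event_table(
    path: str | Path,
    *,
    column_allowlist: Sequence[str] | None = None,
) -> EventTable:
    """Read a scale-value CSV export into an :class:`EventTable`.

    The first row must be a header of unique channel names; every data cell
    must parse as a number. ``column_allowlist`` restricts to the named
    columns (in file order), accommodating exports that carry extra
    metadata columns.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate channel name in header")
    keep = list(range(len(header)))
    if column_allowlist is not None:
        allowed = set(column_allowlist)
        keep = [i for i, name in enumerate(header) if name in allowed]
        missing = allowed - {header[i] for i in keep}
        if missing:
            raise FormatError(f"{path}: allowlisted columns absent: {sorted(missing)}")
    names = [header[i] for i in keep]
    data = np.empty((len(rows) - 1, len(keep)))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: line {r}: expected {len(header)} fields, got {len(row)}")
        for j, i in enumerate(keep):
            try:
                data[r - 2, j] = float(row[i])
            except ValueError:
                raise FormatError(
                    f"{path}: line {r}: non-numeric value {row[i]!r} in column {header[i]!r}"
                ) from None
    truth = _read_sidecar(path)
    return EventTable(channel_names=names, intensities=data, truth_labels=truth)


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write intensities as CSV; truth labels go to a ``.labels.csv`` sidecar."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    if table.truth_labels is not None:
        pd.DataFrame({"truth_label": table.truth_labels}).to_csv(
            _sidecar_path(path), index=False
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".labels.csv")


def _read_sidecar(path: Path) -> list[str] | None:
    side = _sidecar_path(path)
    if not side.exists():
        return None
    return pd.read_csv(side)["truth_label"].astype(str).tolist()


def _clean_seq(seq: str, where: str) -> str:
    seq = str(seq).upper().replace("U", "T")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise FormatError(f"{where}: illegal character(s) {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> mapping id -> upper-cased DNA sequence."""
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        out[rec.id] = _clean_seq(rec.seq, f"{path}: record {i} ({rec.id})")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> ReadSet:
    """FASTQ -> :class:`ReadSet`.

    QC status is parsed from a ``qc_pass=false`` token in the read comment
    when present (default pass); a ``truth=<label>`` token is picked up the
    same way.
    """
    reads = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        reads.append(
            Read(
                id=rec.id,
                sequence=_clean_seq(rec.seq, f"{path}: record {i} ({rec.id})"),
                qc_pass=tokens.get("qc_pass", "true").lower() != "false",
                truth_label=tokens.get("truth"),
            )
        )
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """Write reads with constant placeholder qualities; flags in the comment."""
    records = []
    for r in readset:
        tokens = []
        if not r.qc_pass:
            tokens.append("qc_pass=false")
        if r.truth_label is not None:
            tokens.append(f"truth={r.truth_label}")
        rec = SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(tokens))
        rec.letter_annotations["phred_quality"] = [30] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_matrix(
    matrix: np.ndarray | pd.DataFrame,
    row_labels: Sequence[str] | None,
    col_labels: Sequence[str] | None,
    path: str | Path,
) -> None:
    """Write a labeled matrix as CSV at full float precision."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if row_labels is not None and len(row_labels) != matrix.shape[0]:
            raise ValueError("row_labels length != n rows")
        if col_labels is not None and len(col_labels) != matrix.shape[1]:
            raise ValueError("col_labels length != n columns")
        df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
    # %.17g guarantees binary round-trip for float64
    df.to_csv(path, index_label="", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_matrix` (row labels in the first column)."""
    return pd.read_csv(path, index_col=0, float_precision="round_trip")
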