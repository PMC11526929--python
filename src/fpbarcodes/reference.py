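"""Reference spectra estimation and the unmixing basis.

Each FP's reference spectrum is the per-channel median fluorescence
intensity of its gated positive population minus the per-channel median of
untransfected control cells, clipped at zero and peak-normalized (max = 1).
The autofluorescence spectrum — the 19th basis component — is the
peak-normalized per-channel median of the controls themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import AUTOFLUORESCENCE_LABEL
from .io import EventTable, write_matrix

__all__ = [
    "ReferenceSpectrum",
    "ReferenceMatrix",
    "gate_positive",
    "moderate_intensity_band",
    "estimate_reference",
    "estimate_autofluorescence",
    "build_reference_matrix",
]


@dataclass(frozen=True)
class ReferenceSpectrum:
    """One basis column: nonnegative normalized per-channel weights.

    The default normalization is by peak (max = 1); sum normalization
    (unit total) is supported as an alternative convention.
    """

    label: str
    values: np.ndarray
    norm: str = "peak"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty vector")
        if (v < 0).any():
            raise ValueError("reference spectrum must be nonnegative")
        if self.norm == "peak" and not np.isclose(v.max(), 1.0):
            raise ValueError("reference spectrum must be peak-normalized (max = 1)")
        if self.norm == "sum" and not np.isclose(v.sum(), 1.0):
            raise ValueError("reference spectrum must be sum-normalized (sum = 1)")

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.values))


@dataclass(frozen=True)
class ReferenceMatrix:
    """C x R unmixing basis; FP columns in stable order, autofluorescence last.

    ``channel_names``, when set, let event tables be aligned to the basis
    rows by name rather than by position; a name mismatch is a hard error
    at unmixing time.
    """

    basis: np.ndarray
    column_labels: tuple[str, ...]
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        object.__setattr__(self, "basis", b)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        if b.ndim != 2 or b.shape[1] != len(self.column_labels):
            raise ValueError("basis shape inconsistent with column labels")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("duplicate column labels")
        if self.column_labels[-1] != AUTOFLUORESCENCE_LABEL:
            raise ValueError("last column must be autofluorescence")
        if self.channel_names is not None:
            object.__setattr__(self, "channel_names", tuple(self.channel_names))
            if len(self.channel_names) != b.shape[0]:
                raise ValueError("channel_names length != basis rows")

    @property
    def n_channels(self) -> int:
        return self.basis.shape[0]

    @property
    def fp_labels(self) -> tuple[str, ...]:
        return self.column_labels[:-1]

    def to_dataframe(self) -> pd.DataFrame:
        idx = list(self.channel_names) if self.channel_names else None
        return pd.DataFrame(self.basis, columns=list(self.column_labels), index=idx)

    def write(self, path) -> None:
        write_matrix(self.to_dataframe(), None, None, path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ReferenceMatrix":
        names = tuple(str(i) for i in df.index)
        if all(n.isdigit() for n in names):  # unnamed channels round-trip as counters
            names = None
        return cls(
            basis=df.to_numpy(dtype=float),
            column_labels=tuple(df.columns),
            channel_names=names,
        )


def gate_positive(events: EventTable, peak_channel: int, cutoff: float) -> EventTable:
    """Retain cells whose intensity at ``peak_channel`` exceeds ``cutoff`` (~10^3 AU).

    Emits a warning (not an error) when nothing survives; row order kept.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not 0 <= peak_channel < events.n_channels:
        raise ValueError(f"peak_channel {peak_channel} out of range")
    mask = events.intensities[:, peak_channel] > cutoff
    if not mask.any():
        warnings.warn("gate_positive: no cells above cutoff", stacklevel=2)
    return events.subset(mask)


def moderate_intensity_band(
    events: EventTable,
    peak_channel: int,
    lower_pct: float = 25.0,
    upper_pct: float = 90.0,
) -> EventTable:
    """Optional percentile band on peak-channel intensity.

    Reference spectra are estimated from positively transfected cells of
    moderate brightness; the band bounds are configurable percentiles of
    the gated population's peak-channel intensity.
    """
    if events.n_cells == 0:
        return events
    vals = events.intensities[:, peak_channel]
    lo, hi = np.percentile(vals, [lower_pct, upper_pct])
    return events.subset((vals >= lo) & (vals <= hi))


def _medians(events: EventTable) -> np.ndarray:
    if events.n_cells == 0:
        raise ValueError("empty event table")
    return np.median(events.intensities, axis=0)


def _normalize(values: np.ndarray, label: str, norm: str) -> ReferenceSpectrum:
    if values.max() <= 0:
        raise ValueError(f"degenerate spectrum for {label!r}: all channels <= 0")
    if norm == "peak":
        scaled = values / values.max()
    elif norm == "sum":
        scaled = values / values.sum()
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return ReferenceSpectrum(label=label, values=scaled, norm=norm)


def estimate_reference(
    pos_events: EventTable,
    control_events: EventTable,
    label: str = "FP",
    norm: str = "peak",
) -> ReferenceSpectrum:
    """Median(positive) − median(control) per channel, clipped ≥ 0, normalized.

    ``norm="peak"`` (default) scales the spectrum to max 1, so unmixed
    abundances read in peak-channel AU; ``norm="sum"`` scales to unit total.
    """
    if pos_events.channel_names != control_events.channel_names:
        raise ValueError("positive and control tables have different channels")
    diff = np.clip(_medians(pos_events) - _medians(control_events), 0.0, None)
    return _normalize(diff, label, norm)


def estimate_autofluorescence(
    control_events: EventTable, norm: str = "peak"
) -> ReferenceSpectrum:
    """Normalized per-channel median of untransfected control cells."""
    med = np.clip(_medians(control_events), 0.0, None)
    return _normalize(med, AUTOFLUORESCENCE_LABEL, norm)


def build_reference_matrix(
    spectra: Sequence[ReferenceSpectrum],
    channel_names: Sequence[str] | None = None,
) -> ReferenceMatrix:
    """Assemble the basis: FP columns in input order, autofluorescence last."""
    fps = [s for s in spectra if s.label != AUTOFLUORESCENCE_LABEL]
    afs = [s for s in spectra if s.label == AUTOFLUORESCENCE_LABEL]
    if len(afs) != 1:
        raise ValueError(f"need exactly one autofluorescence spectrum, got {len(afs)}")
    if not fps:
        raise ValueError("need at least one FP spectrum")
    sizes = {s.values.size for s in spectra}
    if len(sizes) != 1:
        raise ValueError("spectra have inconsistent channel counts")
    labels = [s.label for s in fps]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate FP labels")
    cols = fps + afs
    return ReferenceMatrix(
        basis=np.column_stack([s.values for s in cols]),
        column_labels=tuple(s.label for s in cols),
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )
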