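"""Evaluation surfaces: confusion fractions, F1, intensity histograms,
barcode fractional abundance, and intensity-cutoff sweeps.

Per-class F1 uses the one-vs-rest convention F1 = 2PR/(P+R) with F1 = 0
when a class has no true positives; "overall" F1 is the unweighted (macro)
mean across classes, so it equals 1 exactly when the confusion matrix is
the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    BarcodeCall,
    ThresholdSet,
    apply_intensity_cutoff,
    classify_table,
    score_table,
)
from .io import EventTable
from .reference import ReferenceMatrix
from .unmix import unmix_table

__all__ = [
    "F1Report",
    "confusion_fractions",
    "f1_scores",
    "misclassification_by_intensity",
    "default_intensity_bins",
    "barcode_fraction_table",
    "cutoff_sweep",
]


@dataclass(frozen=True)
class F1Report:
    """Per-class and macro-averaged F1 on one evaluation set."""

    per_class: dict[str, float]
    overall: float
    n_cells: int
    cutoff: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = list(self.per_class.items()) + [("overall", self.overall)]
        return pd.DataFrame(rows, columns=["class", "f1"])


def _as_labels(x) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


def confusion_fractions(
    actual: Sequence[str],
    inferred: Sequence[str],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Row-normalized confusion matrix: entry (a, i) is the fraction of
    class-``a`` cells inferred as ``i``.

    Rows cover actual classes with at least one cell (a requested class
    with zero cells is dropped with a warning); columns cover the union of
    requested classes and observed labels. Each row sums to 1.
    """
    a, p = _as_labels(actual), _as_labels(inferred)
    if a.size != p.size or a.size == 0:
        raise ValueError("actual and inferred must be equal-length and non-empty")
    if classes is None:
        classes = list(dict.fromkeys(list(a)))
    cols = list(dict.fromkeys(list(classes) + list(dict.fromkeys(list(p)))))
    rows = []
    kept = []
    for c in classes:
        mask = a == c
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"class {c!r} has no cells; row omitted", stacklevel=2)
            continue
        kept.append(c)
        rows.append([float((p[mask] == i).sum()) / n for i in cols])
    return pd.DataFrame(rows, index=kept, columns=cols)


def f1_scores(
    actual: Sequence[str],
    inferred: Sequence[str],
    classes: Sequence[str] | None = None,
    cutoff: float | None = None,
) -> F1Report:
    """Per-class precision/recall F1 and its macro average."""
    a, p = _as_labels(actual), _as_labels(inferred)
    if a.size != p.size or a.size == 0:
        raise ValueError("actual and inferred must be equal-length and non-empty")
    if classes is None:
        classes = sorted(set(a))
    per = {}
    for c in classes:
        tp = float(((a == c) & (p == c)).sum())
        fp = float(((a != c) & (p == c)).sum())
        fn = float(((a == c) & (p != c)).sum())
        per[c] = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
    overall = float(np.mean(list(per.values()))) if per else float("nan")
    return F1Report(per_class=per, overall=overall, n_cells=int(a.size), cutoff=cutoff)


def default_intensity_bins(
    low: float = 1e2, high: float = 1e7, n_bins: int = 24
) -> np.ndarray:
    """Log-spaced bin edges for misclassification-by-intensity histograms."""
    return np.logspace(np.log10(low), np.log10(high), n_bins + 1)


def misclassification_by_intensity(
    max_intensities: Sequence[float],
    correct_flags: Sequence[bool],
    bin_edges: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Histogram of misclassified cells over intensity bins.

    Returns one row per bin with ``bin_left``, ``bin_right`` and ``count``;
    with ``labels`` given, adds one count column per label (stratified).
    """
    x = np.asarray(max_intensities, dtype=float)
    ok = np.asarray(correct_flags, dtype=bool)
    if x.shape != ok.shape:
        raise ValueError("max_intensities and correct_flags must be equal length")
    edges = default_intensity_bins() if bin_edges is None else np.asarray(bin_edges, float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    out = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:]})
    bad = x[~ok]
    out["count"] = np.histogram(bad, bins=edges)[0]
    if labels is not None:
        lab = _as_labels(labels)
        for c in dict.fromkeys(list(lab)):
            out[c] = np.histogram(x[(~ok) & (lab == c)], bins=edges)[0]
    return out


def _pair_key(members) -> tuple[str, ...]:
    return tuple(sorted(members))


def barcode_fraction_table(
    samples: Mapping[str, tuple[str, str]],
    sample_ids: Sequence[str],
    calls: Sequence[BarcodeCall],
) -> pd.DataFrame:
    """Fractional abundance of inferred unordered pairs per sample.

    ``samples`` maps each sample to its true FP pair; ``sample_ids`` gives
    each call's sample. Rows are samples, columns inferred unordered pairs
    (labels ``"A+B"`` with members sorted); permutations collapse, so an
    inferred {B, A} matches a truth (A, B). Rows sum to 1.
    """
    if len(sample_ids) != len(calls):
        raise ValueError("sample_ids and calls must be equal length")
    unknown = set(sample_ids) - set(samples)
    if unknown:
        raise ValueError(f"calls reference unknown samples: {sorted(unknown)}")
    inferred = ["+".join(_pair_key(c.members)) for c in calls]
    col_order = ["+".join(_pair_key(p)) for p in samples.values()]
    cols = list(dict.fromkeys(col_order + sorted(set(inferred))))
    sid = _as_labels(sample_ids)
    inf = _as_labels(inferred)
    rows = []
    kept = []
    for s in samples:
        mask = sid == s
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"sample {s!r} has no cells; row omitted", stacklevel=2)
            continue
        kept.append(s)
        rows.append([float((inf[mask] == c).sum()) / n for c in cols])
    return pd.DataFrame(rows, index=kept, columns=cols)


def cutoff_sweep(
    events: EventTable,
    basis: ReferenceMatrix,
    thresholds: ThresholdSet,
    cutoffs: Sequence[float],
    *,
    k: int = 1,
    catalog: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Overall F1 and retained fraction as the intensity cutoff rises.

    ``events`` must carry truth labels (single-FP names for k=1, canonical
    pair labels for k=2). A cutoff that retains no cells yields NaN F1 and
    is flagged in the ``defined`` column.
    """
    if events.truth_labels is None:
        raise ValueError("events must carry truth labels")
    cutoffs = list(cutoffs)
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted ascending")
    n_total = events.n_cells
    rows = []
    for c in cutoffs:
        kept = apply_intensity_cutoff(events, c)
        if kept.n_cells == 0:
            rows.append((c, float("nan"), 0.0, 0, False))
            continue
        abund = unmix_table(basis, kept)
        calls = classify_table(score_table(abund, thresholds), k=k, catalog=catalog)
        if k == 1:
            inferred = [next(iter(call.members)) for call in calls]
            truth = kept.truth_labels
        else:
            inferred = ["+".join(_pair_key(call.members)) for call in calls]
            truth = ["+".join(sorted(t.split("+"))) for t in kept.truth_labels]
        rep = f1_scores(truth, inferred, cutoff=c)
        rows.append((c, rep.overall, kept.n_cells / n_total, kept.n_cells, True))
    return pd.DataFrame(
        rows, columns=["cutoff", "overall_f1", "fraction_retained", "n_retained", "defined"]
    )
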