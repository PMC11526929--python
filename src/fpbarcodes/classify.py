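"""Threshold training and top-k barcode calling.

Classification of a cell runs in three steps: the cell is unmixed to R
abundances, each FP abundance is divided by that FP's threshold to give a
unitless ratio score (18 scores; autofluorescence never gets one), and the
k highest-scoring FPs (k=1 for single-FP experiments, k=2 for barcodes)
are called present.

Thresholds are trained per FP by one-vs-rest ROC over the pooled training
cells of all FP transfections: candidate thresholds are the observed unique
abundances plus a +inf sentinel, a cell is called positive when its
abundance for the FP is >= the threshold, and the chosen threshold is the
one closest to the ideal (FPR, TPR) = (0, 1) corner, ties resolved toward
the largest (most conservative) threshold. Training/testing uses a 70/30
split repeated three times with results averaged across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AUTOFLUORESCENCE_LABEL
from .io import EventTable

__all__ = [
    "DEFAULT_INTENSITY_CUTOFF",
    "DEFAULT_BACKGROUND_LEVEL",
    "signal_to_noise",
    "ThresholdSet",
    "BarcodeCall",
    "SplitPlan",
    "split_indices",
    "split_train_test",
    "roc_curve",
    "choose_threshold",
    "train_thresholds",
    "score",
    "score_table",
    "classify_top_k",
    "classify_table",
    "apply_intensity_cutoff",
]

#: Default per-cell maximum-intensity cutoff (AU) applied before evaluation.
DEFAULT_INTENSITY_CUTOFF = 1e4
#: Typical autofluorescence background magnitude (AU).
DEFAULT_BACKGROUND_LEVEL = 1e3


def signal_to_noise(
    cutoff: float = DEFAULT_INTENSITY_CUTOFF,
    background: float = DEFAULT_BACKGROUND_LEVEL,
) -> float:
    """SNR implied by an intensity cutoff over the background level (10^4/10^3 = 10)."""
    if background <= 0:
        raise ValueError("background must be > 0")
    return cutoff / background


@dataclass(frozen=True)
class ThresholdSet:
    """One positive abundance threshold per FP; autofluorescence excluded."""

    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        if AUTOFLUORESCENCE_LABEL in self.thresholds:
            raise ValueError("autofluorescence must not carry a threshold")
        for fp, t in self.thresholds.items():
            if not t > 0:
                raise ValueError(f"threshold for {fp!r} must be > 0, got {t}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fp": list(self.thresholds), "threshold": list(self.thresholds.values())}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ThresholdSet":
        return cls(dict(zip(df["fp"].astype(str), df["threshold"].astype(float))))


@dataclass(frozen=True)
class BarcodeCall:
    """The k distinct FPs called in one cell, as an unordered set."""

    members: frozenset[str]
    member_scores: tuple[float, ...] = ()
    cell_index: int | None = None

    def label(self, catalog: Sequence[str] | None = None) -> str:
        """Canonical unordered label, members sorted by catalog order."""
        key = (lambda m: catalog.index(m)) if catalog else None
        return "+".join(sorted(self.members, key=key))


@dataclass(frozen=True)
class SplitPlan:
    """70/30 train/test partitioning repeated ``n_repeats`` times."""

    train_fraction: float = 0.7
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split_indices(n: int, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint exhaustive (train, test) index pairs, one per repeat.

    Train size is ``round(train_fraction * n)``; each repeat uses a distinct
    child seed so partitions differ, and the whole plan is deterministic.
    """
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    root = np.random.SeedSequence(plan.seed)
    n_train = int(round(plan.train_fraction * n))
    out = []
    for child in root.spawn(plan.n_repeats):
        perm = np.random.default_rng(child).permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def split_train_test(
    events: EventTable, plan: SplitPlan
) -> list[tuple[EventTable, EventTable]]:
    """:func:`split_indices` lifted to labeled event tables."""
    if events.truth_labels is None:
        raise ValueError("events must carry truth labels")
    return [
        (events.subset(tr), events.subset(te))
        for tr, te in split_indices(events.n_cells, plan)
    ]


def roc_curve(abundances: np.ndarray, is_target: np.ndarray) -> pd.DataFrame:
    """One-vs-rest ROC for the rule ``abundance >= threshold => positive``.

    Candidate thresholds are the sorted unique abundances plus a +inf
    sentinel; rows are ordered by descending threshold so the curve runs
    from (0, 0) to (1, 1). Both classes must be present.
    """
    a = np.asarray(abundances, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    if a.shape != y.shape or a.ndim != 1:
        raise ValueError("abundances and labels must be 1-D and equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    thresholds = np.concatenate([[np.inf], np.unique(a)[::-1]])  # descending
    tpr = np.array([(a[y] >= t).mean() for t in thresholds])
    fpr = np.array([(a[~y] >= t).mean() for t in thresholds])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def choose_threshold(roc: pd.DataFrame) -> float:
    """Threshold closest to the ideal (0, 1) ROC corner.

    Distance is Euclidean, sqrt(FPR^2 + (1 - TPR)^2); ties resolve to the
    largest (most conservative) threshold. A degenerate curve whose best
    point is the +inf sentinel is returned with a warning.
    """
    if len(roc) == 0:
        raise ValueError("empty ROC curve")
    d = np.hypot(roc["fpr"].to_numpy(), 1.0 - roc["tpr"].to_numpy())
    best = d.min()
    t = roc["threshold"].to_numpy()[np.isclose(d, best)].max()
    if np.isinf(t):
        warnings.warn("degenerate ROC: returning the +inf sentinel", stacklevel=2)
    return float(t)


def train_thresholds(
    abundances: pd.DataFrame,
    labels: Sequence[str],
    fp_labels: Sequence[str] | None = None,
) -> ThresholdSet:
    """One-vs-rest ROC threshold per FP over the pooled training set.

    ``abundances`` is the unmixed table (one column per basis label);
    ``labels`` gives each training cell's true FP. Every FP must appear in
    the labels so both ROC classes exist.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(abundances):
        raise ValueError("labels length != number of cells")
    if fp_labels is None:
        fp_labels = [c for c in abundances.columns if c not in (AUTOFLUORESCENCE_LABEL, "residual")]
    out = {}
    for fp in fp_labels:
        is_target = labels == fp
        if not is_target.any():
            raise ValueError(f"no training cells labeled {fp!r}")
        roc = roc_curve(abundances[fp].to_numpy(), is_target)
        out[fp] = choose_threshold(roc)
    return ThresholdSet(out)


def score(
    abundances: Mapping[str, float] | pd.Series, thresholds: ThresholdSet
) -> dict[str, float]:
    """Ratio scores for one cell: abundance_f / threshold_f per FP.

    Autofluorescence (and any residual column) is ignored, so a 19-entry
    abundance vector yields an 18-entry score vector.
    """
    return {
        fp: float(abundances[fp]) / t for fp, t in thresholds.thresholds.items()
    }


def score_table(abundances: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Vectorized :func:`score` over an unmixed table."""
    fps = list(thresholds.thresholds)
    return abundances[fps] / pd.Series(thresholds.thresholds)


def classify_top_k(
    scores: Mapping[str, float] | pd.Series,
    k: int = 1,
    catalog: Sequence[str] | None = None,
    min_score: float | None = None,
) -> BarcodeCall:
    """Call the k distinct FPs with the highest scores.

    Ties resolve by fixed catalog order (input order of ``catalog``, or the
    score mapping's own order). Members are unordered in the call. With
    ``min_score`` set (e.g. 1.0), a cell whose scores all fall below it is
    returned *unclassified* (empty member set); the default always assigns
    the top-k.
    """
    items = list(scores.items())
    if k < 1 or k > len(items):
        raise ValueError(f"k={k} outside 1..{len(items)}")
    if min_score is not None and all(v < min_score for _, v in items):
        return BarcodeCall(members=frozenset(), member_scores=())
    order = {fp: i for i, fp in enumerate(catalog)} if catalog else {
        fp: i for i, (fp, _) in enumerate(items)
    }
    ranked = sorted(items, key=lambda kv: (-kv[1], order.get(kv[0], len(order))))
    top = ranked[:k]
    return BarcodeCall(
        members=frozenset(fp for fp, _ in top),
        member_scores=tuple(float(s) for _, s in top),
    )


def classify_table(
    scores: pd.DataFrame, k: int = 1, catalog: Sequence[str] | None = None
) -> list[BarcodeCall]:
    """Per-row top-k calls; tie-break column order is the catalog order."""
    cat = list(catalog) if catalog is not None else list(scores.columns)
    cols = list(scores.columns)
    order = np.array([cat.index(c) for c in cols])
    vals = scores.to_numpy()
    calls = []
    for i in range(vals.shape[0]):
        # stable selection: sort by (-score, catalog position)
        idx = np.lexsort((order, -vals[i]))[:k]
        calls.append(
            BarcodeCall(
                members=frozenset(cols[j] for j in idx),
                member_scores=tuple(float(vals[i, j]) for j in idx),
                cell_index=i,
            )
        )
    return calls


def apply_intensity_cutoff(
    events: EventTable, cutoff: float = DEFAULT_INTENSITY_CUTOFF
) -> EventTable:
    """Drop cells whose maximum raw channel intensity is below the cutoff.

    The statistic is the max over raw channels (cell brightness), not any
    unmixed abundance.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return events.subset(events.max_intensity() >= cutoff)
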