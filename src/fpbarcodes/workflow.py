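"""End-to-end synthetic experiments tying the pipeline stages together.

Each driver regenerates its own ground truth from a single seed, runs the
full pipeline (reference estimation -> unmixing -> threshold training ->
classification -> evaluation, or read simulation -> filtering ->
orientation -> assignment), and returns the evaluation surfaces. These are
the entry points the CLI and the reproduction script build on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_FP_NAMES, DEFAULT_N_CHANNELS, unordered_pairs
from .classify import (
    DEFAULT_BACKGROUND_LEVEL,
    DEFAULT_INTENSITY_CUTOFF,
    SplitPlan,
    ThresholdSet,
    apply_intensity_cutoff,
    classify_table,
    score_table,
    split_indices,
    train_thresholds,
)
from .evaluate import (
    barcode_fraction_table,
    confusion_fractions,
    cutoff_sweep,
    f1_scores,
)
from .io import EventTable, ReadSet
from .nanopore import (
    LibraryProfile,
    assign_reads,
    completeness_check,
    pair_count_matrix,
)
from .reference import (
    build_reference_matrix,
    estimate_autofluorescence,
    estimate_reference,
    gate_positive,
    moderate_intensity_band,
)
from .synthetic import (
    CellSimConfig,
    ReadSimConfig,
    build_construct_references,
    make_fp_sequences,
    make_linker,
    make_promoter,
    make_reference_set,
    simulate_cells,
    simulate_panel,
    simulate_reads,
)
from .unmix import unmix_table

__all__ = [
    "estimate_basis_from_simulation",
    "SingleFPResult",
    "run_single_fp_experiment",
    "BarcodeResult",
    "run_barcode_experiment",
    "NanoporeResult",
    "run_nanopore_experiment",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def estimate_basis_from_simulation(
    refs,
    config: CellSimConfig,
    *,
    n_control: int = 1000,
    gate_cutoff: float = DEFAULT_BACKGROUND_LEVEL,
):
    """Estimate the unmixing basis from simulated calibration transfections.

    One single-FP simulation per FP is gated positive at the FP's peak
    channel (cutoff ~10^3 AU), band-filtered to moderate brightness, and
    median-subtracted against an untransfected control simulation; the
    autofluorescence column comes from the controls.
    """
    seeds = _child_seeds(config.seed, len(refs) + 1)
    control = simulate_cells(
        refs,
        refs[0].fp_id,
        replace(config, n_cells=n_control, transfected_fraction=0.0, seed=seeds[-1]),
    )
    spectra = []
    for s, sm in zip(seeds, refs):
        events = simulate_cells(refs, sm.fp_id, replace(config, seed=s))
        pos = gate_positive(events, sm.peak_channel, gate_cutoff)
        pos = moderate_intensity_band(pos, sm.peak_channel)
        spectra.append(estimate_reference(pos, control, label=sm.fp_id))
    spectra.append(estimate_autofluorescence(control))
    return build_reference_matrix(spectra, channel_names=control.channel_names)


@dataclass
class SingleFPResult:
    """Averaged (n-repeat) evaluation of single-FP classification."""

    basis: object
    thresholds: list[ThresholdSet]
    per_fp_tpr: pd.Series  # mean held-out recall per FP, after cutoff
    confusion: pd.DataFrame  # mean row-normalized confusion, after cutoff
    f1_with_cutoff: float
    f1_without_cutoff: float
    fraction_retained: float
    cutoff: float
    snr: float
    panel: EventTable
    abundances: pd.DataFrame
    split_plan: SplitPlan


def run_single_fp_experiment(
    n_fps: int = len(DEFAULT_FP_NAMES),
    n_channels: int = DEFAULT_N_CHANNELS,
    cells_per_fp: int = 300,
    seed: int = 0,
    *,
    cutoff: float = DEFAULT_INTENSITY_CUTOFF,
    config: CellSimConfig | None = None,
    plan: SplitPlan | None = None,
    basis=None,
    spectrum_width: float = 1.5,
) -> SingleFPResult:
    """Simulate, calibrate, train and evaluate the 18-FP classification task.

    The panel pools ``cells_per_fp`` cells from each single-FP transfection;
    cells are gated positive (max intensity > ~10^3), split 70/30 three
    times, thresholds trained per repeat on the pooled training cells, and
    held-out cells classified top-1. Reported metrics average the repeats;
    the intensity cutoff (default 10^4 AU, SNR 10 over the ~10^3
    background) is applied at evaluation time only.
    """
    sim_seed, calib_seed, split_seed = _child_seeds(seed, 3)
    refs = make_reference_set(n_fps, n_channels, seed, width=spectrum_width)
    fp_ids = [r.fp_id for r in refs]
    if config is None:
        config = CellSimConfig(n_cells=cells_per_fp, seed=sim_seed)
    else:
        config = replace(config, n_cells=cells_per_fp, seed=sim_seed)
    if basis is None:
        basis = estimate_basis_from_simulation(refs, replace(config, seed=calib_seed))
    if plan is None:
        plan = SplitPlan(seed=split_seed)

    panel = simulate_panel(refs, fp_ids, config)
    # positive-transfection gate on overall brightness
    panel = apply_intensity_cutoff(panel, DEFAULT_BACKGROUND_LEVEL)
    abund = unmix_table(basis, panel)
    labels = np.asarray(panel.truth_labels, dtype=object)
    max_int = panel.max_intensity()

    thresholds: list[ThresholdSet] = []
    tprs, confusions, f1c, f1n, retained = [], [], [], [], []
    for tr, te in split_indices(panel.n_cells, plan):
        ts = train_thresholds(abund.iloc[tr], labels[tr], fp_labels=fp_ids)
        thresholds.append(ts)
        scores = score_table(abund.iloc[te], ts)
        calls = classify_table(scores, k=1, catalog=fp_ids)
        inferred = np.asarray([next(iter(c.members)) for c in calls], dtype=object)
        actual = labels[te]
        keep = max_int[te] >= cutoff
        retained.append(keep.mean())
        f1n.append(f1_scores(actual, inferred, classes=fp_ids).overall)
        f1c.append(f1_scores(actual[keep], inferred[keep], classes=fp_ids).overall)
        conf = confusion_fractions(actual[keep], inferred[keep], classes=fp_ids)
        confusions.append(conf.reindex(index=fp_ids, columns=fp_ids, fill_value=0.0))
        tprs.append(pd.Series(np.diag(confusions[-1]), index=fp_ids))

    return SingleFPResult(
        basis=basis,
        thresholds=thresholds,
        per_fp_tpr=sum(tprs) / len(tprs),
        confusion=sum(confusions) / len(confusions),
        f1_with_cutoff=float(np.mean(f1c)),
        f1_without_cutoff=float(np.mean(f1n)),
        fraction_retained=float(np.mean(retained)),
        cutoff=cutoff,
        snr=cutoff / DEFAULT_BACKGROUND_LEVEL,
        panel=panel,
        abundances=abund,
        split_plan=plan,
    )


@dataclass
class BarcodeResult:
    """Evaluation of two-FP barcode identification by fractional abundance."""

    fraction_table: pd.DataFrame
    pair_recovery: float  # overall fraction of cells with exact unordered pair
    per_sample_recovery: pd.Series
    second_member_bias: float  # among wrong calls: fraction containing member 2 only
    thresholds: ThresholdSet
    n_cells: int


def run_barcode_experiment(
    n_pairs: int = 50,
    cells_per_pair: int = 100,
    seed: int = 0,
    *,
    cutoff: float = DEFAULT_INTENSITY_CUTOFF,
    first_member_attenuation: float = 1.0,
    config: CellSimConfig | None = None,
    spectrum_width: float = 1.5,
) -> BarcodeResult:
    """Simulate and classify two-FP barcode samples (top-2 calls).

    Thresholds are trained on a pooled single-FP panel (as in calibration
    practice); ``n_pairs`` unordered FP pairs are then sampled, equimolar
    by default. ``first_member_attenuation < 1`` emulates constructs whose
    first member is expressed far below the second, which drives
    misclassification toward barcodes sharing the second member.
    """
    pair_seed, train_seed, sim_seed, calib_seed = _child_seeds(seed, 4)
    refs = make_reference_set(seed=seed, width=spectrum_width)
    fp_ids = [r.fp_id for r in refs]
    if config is None:
        config = CellSimConfig(seed=0)
    basis = estimate_basis_from_simulation(
        refs, replace(config, n_cells=300, seed=calib_seed)
    )
    train_panel = simulate_panel(
        refs, fp_ids, replace(config, n_cells=300, seed=train_seed)
    )
    train_panel = apply_intensity_cutoff(train_panel, DEFAULT_BACKGROUND_LEVEL)
    thresholds = train_thresholds(
        unmix_table(basis, train_panel), train_panel.truth_labels, fp_labels=fp_ids
    )

    rng = np.random.default_rng(pair_seed)
    all_pairs = unordered_pairs(fp_ids)
    chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), size=n_pairs, replace=False)]
    bc_config = replace(
        config,
        n_cells=cells_per_pair,
        seed=sim_seed,
        first_member_attenuation=first_member_attenuation,
    )
    panel = simulate_panel(refs, chosen, bc_config)
    panel = apply_intensity_cutoff(panel, cutoff)
    abund = unmix_table(basis, panel)
    calls = classify_table(score_table(abund, thresholds), k=2, catalog=fp_ids)

    samples = {"+".join(p): tuple(p) for p in chosen}
    table = barcode_fraction_table(samples, panel.sample_ids, calls)

    truth_sets = [frozenset(s.split("+")) for s in panel.sample_ids]
    correct = np.array([c.members == t for c, t in zip(calls, truth_sets)])
    per_sample = pd.Series(
        {
            s: correct[np.asarray(panel.sample_ids, dtype=object) == s].mean()
            for s in samples
        }
    )
    # among misclassified cells of two-member truths: call kept the second
    # (position-2) member but lost the first
    wrong = ~correct
    bias_n = bias_d = 0
    for c, sid, w in zip(calls, panel.sample_ids, wrong):
        if not w:
            continue
        m1, m2 = sid.split("+")
        bias_d += 1
        if m2 in c.members and m1 not in c.members:
            bias_n += 1
    return BarcodeResult(
        fraction_table=table,
        pair_recovery=float(correct.mean()),
        per_sample_recovery=per_sample,
        second_member_bias=bias_n / bias_d if bias_d else float("nan"),
        thresholds=thresholds,
        n_cells=panel.n_cells,
    )


@dataclass
class NanoporeResult:
    """Evaluation of read filtering, orientation and one-hot assignment."""

    assignments: pd.DataFrame
    pair_counts: object  # PairCountMatrix
    completeness: dict
    accuracy: float  # correct / assigned
    fraction_assigned: float
    n_reads: int


def run_nanopore_experiment(
    reads_per_construct: int = 10,
    seed: int = 0,
    *,
    read_config: ReadSimConfig | None = None,
    drop_pairs: Sequence[tuple[str, str]] = (),
    min_reads: int = 1,
    fp_ids: Sequence[str] = DEFAULT_FP_NAMES,
) -> NanoporeResult:
    """Simulate the pooled barcode library and validate it end to end.

    All 324 ordered two-FP constructs are built (CMV - FP1 - tPT2A - FP2),
    minus any ``drop_pairs``; reads are drawn uniformly over the remaining
    constructs, corrupted, filtered, CMV-oriented and assigned against the
    full 324-reference set. Accuracy is the fraction of assigned reads
    whose label matches their source construct.
    """
    fp_seqs = make_fp_sequences(fp_ids, seed=seed)
    cmv, linker = make_promoter(), make_linker()
    references = build_construct_references(fp_seqs, cmv=cmv, linker=linker)
    pool = dict(references)
    for fp1, fp2 in drop_pairs:
        pool.pop(f"{fp1}-{fp2}")
    if read_config is None:
        read_config = ReadSimConfig(seed=seed)
    # exactly reads_per_construct reads per pool member, each with a child seed
    seeds = _child_seeds(read_config.seed, len(pool))
    merged = []
    for s, (label, seq) in zip(seeds, pool.items()):
        rs = simulate_reads(
            {label: seq}, None, replace(read_config, n_reads=reads_per_construct, seed=s)
        )
        for r in rs:
            merged.append(replace(r, id=f"{label}|{r.id}"))
    reads = ReadSet(merged)
    profile = LibraryProfile(mode="pooled_barcode")
    assignments = assign_reads(reads, references, cmv, profile)
    assigned = assignments[assignments["status"] == "assigned"]
    accuracy = (
        float((assigned["label"] == assigned["truth_label"]).mean())
        if len(assigned)
        else float("nan")
    )
    counts = pair_count_matrix(assignments, fp_ids)
    return NanoporeResult(
        assignments=assignments,
        pair_counts=counts,
        completeness=completeness_check(counts, min_reads=min_reads),
        accuracy=accuracy,
        fraction_assigned=len(assigned) / len(assignments),
        n_reads=len(assignments),
    )
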