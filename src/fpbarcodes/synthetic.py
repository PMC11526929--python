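"""Synthetic data with known ground truth for every pipeline stage.

Two generators live here. The spectral generator produces per-FP emission
spectra (unimodal bumps over detector channels, peak-normalized to 1) and
single-cell channel vectors built as

    cell = sum_over_members(expression x spectrum) + autofluorescence + noise

with lognormal cell-to-cell expression, a lognormal autofluorescence scale
centered at ~10^3 AU, per-channel multiplicative noise and an additive
floor. The sequence generator produces promoter-anchored constructs
(CMV - FP1 - tPT2A - FP2, or CMV - FP for single-FP plasmids) and long
reads corrupted by iid substitutions/indels, randomly reverse-complemented.

All randomness flows from the explicit ``seed`` of each config through one
:class:`numpy.random.Generator`; a fixed seed reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import DEFAULT_FP_NAMES, DEFAULT_N_CHANNELS
from .io import EventTable, Read, ReadSet

__all__ = [
    "SpectrumModel",
    "CellSimConfig",
    "ReadSimConfig",
    "make_reference_set",
    "simulate_cells",
    "simulate_panel",
    "make_fp_sequences",
    "make_promoter",
    "make_linker",
    "make_homolog",
    "make_construct_sequence",
    "build_construct_references",
    "simulate_reads",
    "UNTRANSFECTED_LABEL",
]

UNTRANSFECTED_LABEL = "none"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpectrumModel:
    """Ground-truth emission spectrum of one FP: unitless fractions, peak = 1."""

    fp_id: str
    channel_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.channel_weights, dtype=float)
        object.__setattr__(self, "channel_weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("channel_weights must be a non-empty 1-D vector")
        if (w < 0).any() or not np.isclose(w.max(), 1.0):
            raise ValueError("weights must be >= 0 with max exactly 1")

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.channel_weights))


@dataclass
class CellSimConfig:
    """Conditions for single-cell spectral simulation.

    Expression is lognormal with ``expression_median`` (AU, the median
    peak-channel intensity of a transfected cell) and ``expression_sigma``
    (std of log intensity). Autofluorescence is a flat spectrum scaled per
    cell by a lognormal factor with median ``autofluorescence_level``
    (default 10^3 AU, the background magnitude). Noise is per-channel
    multiplicative with coefficient of variation ``noise_cv`` plus an
    additive Gaussian floor of std ``noise_floor`` AU.

    ``member_correlation`` sets the correlation of the two barcode members'
    log expression (default 1: single-promoter, 2A-linked, equimolar);
    ``first_member_attenuation`` < 1 scales the first member's expression
    down, emulating the pathology where the first FP of a construct is
    expressed far below the second.
    """

    n_cells: int = 1000
    expression_median: float = 5e4
    expression_sigma: float = 1.0
    autofluorescence_level: float = 1e3
    autofluorescence_sigma: float = 0.3
    noise_cv: float = 0.05
    noise_floor: float = 30.0
    transfected_fraction: float = 1.0
    member_correlation: float = 1.0
    first_member_attenuation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.autofluorescence_level < 0:
            raise ValueError("autofluorescence_level must be >= 0")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")


@dataclass
class ReadSimConfig:
    """Conditions for nanopore-style read simulation (iid error model)."""

    n_reads: int = 1000
    sub_rate: float = 0.05
    ins_rate: float = 0.01
    del_rate: float = 0.01
    reverse_prob: float = 0.5
    fail_qc_prob: float = 0.02
    length_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for name in ("sub_rate", "ins_rate", "del_rate", "reverse_prob", "fail_qc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def make_reference_set(
    n_fps: int = len(DEFAULT_FP_NAMES),
    n_channels: int = DEFAULT_N_CHANNELS,
    seed: int = 0,
    *,
    width: float = 1.5,
    width_jitter: float = 0.3,
    fp_ids: Sequence[str] | None = None,
) -> list[SpectrumModel]:
    """Generate ``n_fps`` unimodal spectra with pairwise-distinct peak channels.

    Peaks are spread evenly across the channel axis; each spectrum is a
    Gaussian bump over channel index whose width (in channels) is ``width``
    perturbed per FP by up to ``width_jitter``, controlling spectral overlap.
    """
    if n_fps < 1:
        raise ValueError("n_fps must be >= 1")
    if n_channels < n_fps:
        raise ValueError(
            f"n_channels ({n_channels}) < n_fps ({n_fps}): distinct peaks impossible"
        )
    if fp_ids is None:
        fp_ids = (
            list(DEFAULT_FP_NAMES[:n_fps])
            if n_fps <= len(DEFAULT_FP_NAMES)
            else [f"FP{i+1:02d}" for i in range(n_fps)]
        )
    if len(fp_ids) != n_fps:
        raise ValueError("fp_ids length != n_fps")
    rng = np.random.default_rng(seed)
    peaks = np.round(np.linspace(0, n_channels - 1, n_fps)).astype(int)
    if len(set(peaks.tolist())) != n_fps:  # crowded axis: fall back to exact spacing
        peaks = np.arange(n_fps)
    channels = np.arange(n_channels, dtype=float)
    spectra = []
    for fp, peak in zip(fp_ids, peaks):
        sigma = width * (1.0 + width_jitter * (rng.random() * 2 - 1))
        w = np.exp(-0.5 * ((channels - peak) / sigma) ** 2)
        w[w < 1e-6] = 0.0
        w[peak] = 1.0
        spectra.append(SpectrumModel(fp_id=fp, channel_weights=w))
    return spectra


def _spectrum_lookup(refs: Sequence[SpectrumModel], fp_id: str) -> SpectrumModel:
    for s in refs:
        if s.fp_id == fp_id:
            return s
    raise KeyError(f"unknown fp_id {fp_id!r}")


def truth_label_for(construct: Sequence[str]) -> str:
    """Canonical truth label: single FP name, or members joined by '+' in
    construct (position) order."""
    construct = [construct] if isinstance(construct, str) else list(construct)
    return "+".join(construct)


def simulate_cells(
    refs: Sequence[SpectrumModel],
    construct: str | Sequence[str],
    config: CellSimConfig,
    *,
    rng: np.random.Generator | None = None,
) -> EventTable:
    """Simulate single-cell channel vectors for one construct (1 or 2 FPs).

    Transfected cells get ``expression x spectrum`` per member plus the
    autofluorescence contribution and noise; untransfected cells (fraction
    ``1 - transfected_fraction``) carry background only and are labeled
    ``"none"``. Truth labels join members with ``+`` in position order.
    """
    members = [construct] if isinstance(construct, str) else list(construct)
    if not 1 <= len(members) <= 2:
        raise ValueError("construct must have 1 or 2 members")
    spectra = [_spectrum_lookup(refs, m) for m in members]
    n_ch = spectra[0].channel_weights.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    transfected = rng.random(n) < config.transfected_fraction

    mu = np.log(config.expression_median)
    z1 = rng.standard_normal(n)
    expr = np.zeros((n, len(members)))
    expr[:, 0] = np.exp(mu + config.expression_sigma * z1)
    if len(members) == 2:
        rho = config.member_correlation
        z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        expr[:, 1] = np.exp(mu + config.expression_sigma * z2)
        expr[:, 0] *= config.first_member_attenuation

    basis = np.stack([s.channel_weights for s in spectra])  # members x C
    signal = expr @ basis
    signal[~transfected] = 0.0

    af_scale = config.autofluorescence_level * np.exp(
        config.autofluorescence_sigma * rng.standard_normal(n)
    )
    cells = signal + af_scale[:, None]  # flat AF spectrum

    if config.noise_cv > 0:
        cells = cells * np.exp(
            config.noise_cv * rng.standard_normal((n, n_ch)) - 0.5 * config.noise_cv**2
        )
    if config.noise_floor > 0:
        cells = cells + config.noise_floor * rng.standard_normal((n, n_ch))

    label = truth_label_for(members)
    labels = [label if t else UNTRANSFECTED_LABEL for t in transfected]
    names = [f"Ch{i+1:02d}" for i in range(n_ch)]
    return EventTable(channel_names=names, intensities=cells, truth_labels=labels)


def simulate_panel(
    refs: Sequence[SpectrumModel],
    constructs: Sequence[str | Sequence[str]],
    config: CellSimConfig,
) -> EventTable:
    """Simulate one table covering several constructs, ``config.n_cells`` each.

    Sub-seeds are drawn from ``config.seed`` so the panel is reproducible
    as a whole; ``sample_ids`` record the originating construct.
    """
    rng = np.random.default_rng(config.seed)
    tables, samples = [], []
    for c in constructs:
        t = simulate_cells(refs, c, config, rng=rng)
        tables.append(t)
        samples.extend([truth_label_for([c] if isinstance(c, str) else c)] * t.n_cells)
    return EventTable(
        channel_names=tables[0].channel_names,
        intensities=np.vstack([t.intensities for t in tables]),
        truth_labels=[l for t in tables for l in t.truth_labels],
        sample_ids=samples,
    )


# --------------------------------------------------------------------------
# sequence side


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_fp_sequences(
    fp_ids: Sequence[str] = DEFAULT_FP_NAMES,
    length: int = 720,
    seed: int = 0,
) -> dict[str, str]:
    """Random FP coding sequences, one per id (default 720 bp, typical FP CDS)."""
    rng = np.random.default_rng(seed)
    return {fp: _random_dna(rng, length) for fp in fp_ids}


def make_promoter(length: int = 550, seed: int = 101) -> str:
    """A synthetic stand-in for the CMV promoter (constant 5' anchor)."""
    return _random_dna(np.random.default_rng(seed), length)


def make_linker(length: int = 130, seed: int = 202) -> str:
    """A synthetic stand-in for the tPT2A self-cleaving linker."""
    return _random_dna(np.random.default_rng(seed), length)


def make_homolog(seq: str, identity: float, seed: int = 0) -> str:
    """Substitute bases so the result shares ``identity`` fraction with ``seq``.

    Used to stress-test assignment with highly homologous references.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = int(round((1 - identity) * len(arr)))
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    arr[pos] = _substitute(rng, arr[pos])
    return arr.tobytes().decode()


def _check_dna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name} contains non-ACGT characters")


def make_construct_sequence(
    fp1_seq: str,
    fp2_seq: str | None = None,
    *,
    cmv: str,
    linker: str | None = None,
) -> str:
    """Assemble a construct reference: ``cmv + fp1 [+ linker + fp2]`` (5'->3')."""
    _check_dna(fp1_seq, "fp1_seq")
    _check_dna(cmv, "cmv")
    if fp2_seq is None:
        return cmv + fp1_seq
    _check_dna(fp2_seq, "fp2_seq")
    if linker is None:
        raise ValueError("two-FP construct requires a linker")
    _check_dna(linker, "linker")
    return cmv + fp1_seq + linker + fp2_seq


def build_construct_references(
    fp_seqs: Mapping[str, str],
    *,
    cmv: str,
    linker: str | None = None,
    mode: str = "barcode",
) -> dict[str, str]:
    """Reference set for read assignment.

    ``mode="single_fp"`` gives one CMV-FP reference per FP (18 by default);
    ``mode="barcode"`` gives every ordered pair including same-FP pairs
    (18 x 18 = 324), since sequence order is observable and the pooled
    ligation can produce any ordered combination. Labels are
    ``"FP1-FP2"`` with position 1 first.
    """
    if mode == "single_fp":
        return {fp: make_construct_sequence(s, cmv=cmv) for fp, s in fp_seqs.items()}
    if mode != "barcode":
        raise ValueError(f"unknown mode {mode!r}")
    if linker is None:
        raise ValueError("barcode mode requires a linker")
    out = {}
    for fp1, s1 in fp_seqs.items():
        for fp2, s2 in fp_seqs.items():
            out[f"{fp1}-{fp2}"] = make_construct_sequence(s1, s2, cmv=cmv, linker=linker)
    return out


_REVCOMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode().translate(_REVCOMP)[::-1].decode()


def _substitute(rng: np.random.Generator, bases: np.ndarray) -> np.ndarray:
    """Replace each base by a uniformly chosen *different* base."""
    idx = np.searchsorted(_BASES, bases)
    shift = rng.integers(1, 4, size=bases.size)
    return _BASES[(idx + shift) % 4]


def _corrupt(rng: np.random.Generator, seq: str, cfg: ReadSimConfig) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    u = rng.random(n)
    deleted = u < cfg.del_rate
    sub = (u >= cfg.del_rate) & (u < cfg.del_rate + cfg.sub_rate)
    if sub.any():
        arr[sub] = _substitute(rng, arr[sub])
    arr = arr[~deleted]
    if cfg.ins_rate > 0:
        n_ins = rng.binomial(arr.size + 1, cfg.ins_rate)
        if n_ins:
            pos = np.sort(rng.integers(0, arr.size + 1, size=n_ins))
            arr = np.insert(arr, pos, rng.choice(_BASES, size=n_ins))
    if cfg.length_jitter > 0:
        pre = rng.integers(0, cfg.length_jitter + 1)
        post = rng.integers(0, cfg.length_jitter + 1)
        arr = np.concatenate(
            [rng.choice(_BASES, size=pre), arr, rng.choice(_BASES, size=post)]
        )
    return arr.tobytes().decode()


def simulate_reads(
    constructs: Mapping[str, str],
    weights: Sequence[float] | Mapping[str, float] | None,
    config: ReadSimConfig,
) -> ReadSet:
    """Draw reads from constructs by weight and corrupt them.

    Each read records its source label (``truth_label``) and its simulated
    orientation (``orientation`` attribute, "forward"/"reverse"); QC failure
    is flagged with probability ``fail_qc_prob`` independent of content.
    """
    if not constructs:
        raise ValueError("empty construct set")
    labels = list(constructs)
    if weights is None:
        w = np.ones(len(labels))
    elif isinstance(weights, Mapping):
        w = np.array([weights[l] for l in labels], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(labels):
            raise ValueError("weights length != number of constructs")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with at least one positive")
    p = w / w.sum()

    rng = np.random.default_rng(config.seed)
    source = rng.choice(len(labels), size=config.n_reads, p=p)
    rev = rng.random(config.n_reads) < config.reverse_prob
    fail = rng.random(config.n_reads) < config.fail_qc_prob
    reads = []
    for i in range(config.n_reads):
        label = labels[source[i]]
        seq = _corrupt(rng, constructs[label], config)
        if rev[i]:
            seq = reverse_complement(seq)
        reads.append(
            Read(
                id=f"read{i:06d}",
                sequence=seq,
                qc_pass=not fail[i],
                truth_label=label,
                orientation="reverse" if rev[i] else "forward",
            )
        )
    return ReadSet(reads)
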