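# fpbarcodes

Identification of combinatorial fluorescent-protein (FP) barcodes in single
cells from spectral flow cytometry, and validation of pooled barcode plasmid
libraries from nanopore long reads.

Genetically encoded barcodes built from *pairs* of FPs give a cheap,
non-destructive readout with far more diversity than single colors: 18 FPs
yield C(18,2) = 153 unordered two-FP barcodes, each with a distinctive
combined emission spectrum across the 48 detector channels of a spectral
cytometer. This package implements the complete computational path for such
experiments, aimed at cytometry and synthetic-biology groups building or
using FP-barcode libraries:

* **Spectral arm** — each cell's channel vector `b` is decomposed against a
  reference basis `A` (18 FP spectra + autofluorescence, peak-normalized) by
  non-negative least squares, `min_x ‖Ax − b‖₂ s.t. x ≥ 0`, giving 19
  abundances; each FP abundance is divided by a per-FP threshold trained by
  one-vs-rest ROC (the threshold closest to the (FPR, TPR) = (0, 1) corner,
  70/30 train/test split × 3 repeats), and the top-1 FP or top-2 barcode is
  called. A per-cell maximum-intensity cutoff (default 10⁴ AU ≈ SNR 10 over
  the ~10³ AU background) removes the dim cells that dominate errors.
* **Sequence arm** — nanopore reads of pooled `CMV–FP1–tPT2A–FP2` constructs
  are length/QC filtered, reoriented 5'→3' on the CMV promoter anchor (≥80%
  identity required), and assigned one-hot to the best of the 324 ordered
  construct references; an 18×18 position-pair count matrix and a
  completeness report validate that the pool contains every combination.
* **Synthetic data** — a seeded generator for spectra, single-cell events
  (lognormal expression, autofluorescence, channel noise) and
  construct-structured noisy reads, so the whole pipeline is testable with
  known ground truth.

See `docs/methods.md` for the models, defaults and numerical conventions.

## Worked example

```python
from fpbarcodes import run_single_fp_experiment, run_nanopore_experiment
from fpbarcodes.synthetic import ReadSimConfig

res = run_single_fp_experiment(cells_per_fp=100, seed=7)
print(f"SNR at the default cutoff : {res.snr:.0f}")
print(f"held-out TPR  (min / mean): {res.per_fp_tpr.min():.3f} / {res.per_fp_tpr.mean():.3f}")
print(f"macro F1 (with / without 1e4 cutoff): {res.f1_with_cutoff:.3f} / {res.f1_without_cutoff:.3f}")
print(f"fraction of cells retained at 1e4   : {res.fraction_retained:.3f}")

nn = run_nanopore_experiment(reads_per_construct=2, seed=7,
                             read_config=ReadSimConfig(seed=7))
print(f"reads assigned: {nn.fraction_assigned:.3f} of {nn.n_reads}")
print(f"assignment accuracy vs truth: {nn.accuracy:.3f}")
print(f"ordered pairs flagged missing: {len(nn.completeness['missing_ordered'])}")
```

prints

```
SNR at the default cutoff : 10
held-out TPR  (min / mean): 1.000 / 1.000
macro F1 (with / without 1e4 cutoff): 1.000 / 1.000
fraction of cells retained at 1e4   : 0.952
reads assigned: 0.972 of 648
assignment accuracy vs truth: 1.000
ordered pairs flagged missing: 0
```

The first block simulates 18 single-FP transfections (100 cells each),
estimates reference spectra from a simulated calibration run, trains the 18
ROC thresholds on three 70/30 splits and reports held-out recovery: at
SNR ≥ 10 every FP is recovered perfectly, and the 10⁴ cutoff discards ~5% of
cells. The second block simulates 2 reads from each of the 324 ordered
constructs at nanopore-like error rates (5% substitutions, 2% indels); the
~3% unassigned reads are QC failures, every assigned read maps to its true
construct, and no ordered pair is missing from the pool.

A `fpbarcodes` command-line interface exposes the same stages
(`simulate-cells`, `simulate-reads`, `estimate-refs`, `train-thresholds`,
`classify`, `evaluate`, `nanopore-assign`); run `fpbarcodes --help`.

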