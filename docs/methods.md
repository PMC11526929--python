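# Methods

`fpbarcodes` implements two complementary procedures around combinatorial
fluorescent-protein (FP) barcodes: identification of barcodes in single
cells from spectral flow cytometry, and validation of a pooled barcode
plasmid library from nanopore long reads. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not capture.

## The spectral model

A cell measured on a spectral cytometer yields an intensity vector
`b ∈ R^C` over `C = 48` detector channels (arbitrary units, scale values).
The measurement model is linear:

    b = A x + ε,    x ≥ 0

where `A ∈ R^(C×R)` is the reference basis — one peak-normalized emission
spectrum per FP plus one autofluorescence spectrum, `R = 19` for the
default 18-FP panel — and `x` the per-cell abundances ("relative
concentrations"). Unmixing solves the non-negative least squares problem

    min_x ||A x − b||₂  subject to x ≥ 0

per cell with the Lawson–Hanson active-set solver (`scipy.optimize.nnls`).
Optimality is characterized by the KKT conditions on the gradient
`g = Aᵀ(Ax − b)`: `|g_j| ≤ tol` on the active support and `g_j ≥ −tol`
off it; the test suite checks this directly and also compares the
objective against exhaustive enumeration of all `2^R` supports for small
`R`. Collinear basis columns are allowed — the contract is on the
objective value, not uniqueness. Because the feasible cone and objective
are positively homogeneous, `nnls(A, αb) = α·nnls(A, b)` for `α > 0`,
which makes downstream classification scale-invariant; this is asserted
numerically rather than assumed.

## Reference spectra

Each FP's reference spectrum is estimated from a single-FP calibration
sample: cells are gated positive at their FP's peak channel (cutoff
~10³ AU), optionally restricted to a moderate-brightness percentile band
(default 25th–90th of peak-channel intensity — the bounds are a package
choice, configurable, since only "moderate" is specified by practice),
and the per-channel median minus the per-channel median of untransfected
controls is taken, clipped at zero so the basis stays nonnegative, then
peak-normalized (max = 1). Peak normalization, rather than sum
normalization, makes an unmixed abundance read directly in peak-channel
AU and lines it up with the intensity-cutoff convention; sum
normalization is available as an option. The autofluorescence column is
the peak-normalized channel median of the controls themselves.

## Threshold training and classification

For each FP, a one-vs-rest ROC is built over the pooled training cells of
all 18 single-FP transfections: candidate thresholds are the sorted unique
abundances plus a `+∞` sentinel; a cell is called positive when its
abundance is `≥ t` (the tie at equality goes to "positive" — a
convention, stated here because it changes counts at repeated values).
The working threshold is the one closest (Euclidean distance) to the
ideal ROC corner (FPR, TPR) = (0, 1); distance ties resolve to the
largest, most conservative threshold. An all-equal abundance column
degenerates to the sentinel and warns rather than failing.

Classification divides each FP abundance by its threshold to give 18
unitless ratio scores (autofluorescence never gets a threshold or a call)
and takes the `k` highest-scoring distinct FPs — `k = 1` for single-FP
experiments, `k = 2` for two-FP barcodes, with score ties resolved by
fixed catalog order. Calls are unordered sets: emission spectra cannot
distinguish which FP sits first in a construct. An optional
"unclassified when all scores < 1" mode exists but is off by default; the
default always assigns the top-k.

Training/testing uses a 70/30 split repeated 3 times with distinct child
seeds; reported metrics are means over the repeats, with per-repeat
values retained.

The per-cell intensity cutoff (default 10⁴ AU on the maximum *raw*
channel, not on any abundance) removes dim cells before evaluation. Over
a ~10³ AU autofluorescence background this corresponds to SNR ≈ 10; the
package reports that ratio explicitly.

## Evaluation

Confusion matrices are row-normalized by actual class. Per-class F1 is
`2PR/(P+R)` with `F1 = 0` when a class has no true positives; "overall"
F1 is the unweighted macro average, which equals 1 exactly when the
confusion matrix is the identity (micro-averaging would collapse to
accuracy for this single-label problem and could not fall below
per-class values the way per-FP breakdowns require). Misclassification
histograms use 24 log-spaced intensity bins over [10², 10⁷] by default.
Barcode performance is summarized as fractional abundance: per sample,
the fraction of cells whose inferred unordered pair equals each possible
pair.

## Sequence arm

Constructs are `CMV – FP1 – tPT2A – FP2` (single-FP plasmids: `CMV – FP`).
Sequence order *is* observable, and the pooled Golden-Gate ligation can
produce any ordered pair including same-FP pairs, so the read-assignment
reference set enumerates all 18 × 18 = 324 ordered constructs, while the
spectral barcode space counts C(18,2) = 153 unordered combinations.

Reads pass three stages:

1. **Filtering** — QC-pass flag and an expected length window per library
   type: 1.2–1.8 kb (single-FP), 2.0–2.8 kb (known barcodes), 2.0–3.0 kb
   (pooled barcodes).
2. **Orientation** — the CMV promoter is aligned against the start of the
   read and of its reverse complement (window of 2×|CMV|, full-read
   search available); identity is matched bases over |CMV|, and reads
   under 0.8 identity on both strands are rejected (tallied, not
   dropped silently). The default identity comes from the
   edit-distance-optimal alignment (edlib extended CIGAR); an affine-gap
   identity (Biopython `PairwiseAligner`) is selectable and agrees on all
   clear-cut cases.
3. **Assignment** — one-hot: each read gets the single reference with the
   highest normalized alignment score. Two interchangeable scorers are
   provided, both with free end gaps on the read side so a read
   containing the reference exactly scores 1, both floored at 0:
   the default edit scorer `1 − 2d/|ref|` (infix edit distance `d`; the
   factor 2 mirrors the match-forfeited-plus-penalty cost of the affine
   convention and puts unrelated sequences near 0 rather than 0.5), and
   an affine scorer (match +1, mismatch −1, gap open −2, extend −0.5,
   normalized by the reference self-score). A winner below
   `min_score = 0.5` is labeled "unassigned" — a conservative floor the
   always-assign behavior can recover with `min_score = 0`.

The bulk scan over 324 kilobase-scale references is exact but pruned: a
cheap prescreen ranks references by the summed infix edit distance of
their head and tail segments (which deduplicate to ~18 each because the
promoter and linker are shared), and the full scan then visits references
in that order with an adaptive distance bound, so hopeless references
abort early. Ties in full distance still resolve by canonical reference
order; the result is identical to the brute-force scan (tested).

Assigned reads are tallied into an 18 × 18 (position-1 × position-2)
count matrix whose percentages sum to 100 over assigned reads; the
completeness check flags ordered pairs below `min_reads` and flags an
unordered combination missing only when both orderings are.

## Synthetic data

The generator is first-class, tested code; it defines the conditions
under which every claim in the test suite is measured.

* **Spectra** — discretized Gaussian bumps over channel index, peaks
  spread evenly (pairwise distinct), width 1.5 channels ± 30% jitter.
  Real FP spectra are asymmetric with secondary shoulders; the Gaussian
  form is a deliberate simplification whose width controls spectral
  overlap for stress tests.
* **Cells** — `intensity = Σ_members expression × spectrum +
  autofluorescence + noise`. Expression is lognormal (median 5×10⁴ AU of
  peak-channel intensity, σ_ln = 1.0 — a typical transient-transfection
  spread). Autofluorescence is a flat spectrum scaled per cell by a
  lognormal factor with median 10³ AU (σ_ln = 0.3), matching the stated
  background magnitude. Noise is per-channel multiplicative lognormal
  (CV 5%) plus an additive Gaussian floor (σ = 30 AU); the instrument's
  true noise is uncharacterized, so these defaults are plausible
  placeholders, not instrument claims. Two-member barcodes draw the two
  expressions perfectly correlated by default (single promoter, 2A
  linkage); `first_member_attenuation < 1` reproduces the pathology
  where the construct's first FP is expressed far below the second,
  which empirically drives misclassification toward barcodes sharing
  the second member.
* **Sequences** — FP coding sequences are iid random DNA (720 bp), the
  promoter and linker stand-ins 550 bp and 130 bp, so constructs land at
  1,270 bp (single-FP) and 2,120 bp (barcode), inside their length
  windows. Real FPs share substantial homology; `make_homolog` builds
  references at a chosen identity (the ≥80% stress case is tested).
  Read errors are iid substitutions (5%) and indels (1% + 1%) with
  random strand orientation and an independent QC-failure flag —
  no homopolymer or quality-correlated error structure.

Consequences: passing tests demonstrate the pipeline's correctness and
its noise/contamination behavior under this generative model; they do
not certify performance on a real cytometer (detector-correlated noise,
spectral ripple, mTFP1-like hardware pathologies) or a real flow cell
(structured nanopore errors).

All randomness descends from explicit integer seeds through
`numpy.random.Generator`s; fixed seeds give bit-identical tables and
read sets.

## Problem sizes and numerics

The shipped experiments use 300 cells per FP for the single-FP task
(5,400-cell panels; 70/30 × 3), 50 barcode pairs × 100 cells for the
barcode task, and 10 reads per ordered construct (3,240 reads) for the
pooled-library task — sizes chosen so the complete analysis reruns from
scratch in minutes on one core while keeping per-class counts large
enough for stable rates. Matrix CSVs are written with `%.17g` (binary
round trip) and read back with round-trip float parsing. NNLS tolerance
follows the solver default; the KKT test tolerance scales with
`‖AᵀA‖_∞`. Empty gates, empty classes and degenerate ROC curves warn and
tag rather than raise wherever a downstream decision is still possible.

## Known limitations

* Reference spectra and thresholds are estimated from single-FP samples
  only; no joint recalibration on barcode samples.
* No probabilistic or learned classifier; the ratio-score rule is the
  deliberate baseline.
* The `k = 2` rule always returns two members — a cell expressing one FP
  strongly and nothing else still yields a second (noise) member unless
  the optional all-scores-<1 mode is enabled.
* The nanopore arm models neither basecalling nor chimeric reads;
  "unassigned" covers only low-scoring reads.
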