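# Methods

## FRET acceptor-photobleaching model and estimator

The estimator operates on four registered images of one cell: donor and
acceptor, each before and after acceptor bleaching. Its model is donor
de-quenching only: with true FRET efficiency E ∈ [0, 1) and a bleached
acceptor fraction B ∈ [0, 1], expected donor intensities in the bleached
region are D_pre = D0·(1 − E) and D_post = D0·(1 − E·(1 − B)); the acceptor
loses the fraction B. Sensitized emission and acceptor cross-excitation are
not modeled — the estimator contains no correction for them, so simulating
them would only add a bias the method cannot remove.

Per ROI, FRET_eff = (D_post − D_pre)/D_post and
Bleach_eff = (1 − A_post/A_pre)·100. In the noiseless limit the ROI
efficiency equals E·B/(1 − E·(1 − B)), which collapses to E at complete
bleach; this closed form is the recovery oracle used throughout the tests.
The printed form of the bleach formula is ambiguous about parenthesization;
(1 − A_post/A_pre)·100 is the only reading under which a 60% threshold is
meaningful, and is what is implemented.

Aggregation rules, in order:

* **QC filter.** Only ROIs with Bleach_eff strictly greater than 60% are
  used. An ROI at exactly 60% is excluded.
* **Cell value.** Mean of QC-passing ROI efficiencies (up to six ROIs —
  six is a maximum, not a minimum; `n_rois_used` is reported) minus the
  FRET_eff of one unbleached reference ROI ≥ 3 µm (edge-to-edge, via the
  pixel size) from the bleached region. The reference uses the identical
  formula; no further background subtraction is applied. Negative corrected
  efficiencies are preserved — the subtraction can legitimately produce
  them, and clamping would bias negative controls upward.
* **Cells with zero passing ROIs** are flagged unreportable (NaN) rather
  than dropped, so batch outputs always account for every input cell.
* **Normalization.** Per-cell corrected efficiency divided by the mean
  corrected efficiency of the positive-control condition (the fused
  donor–acceptor tandem). Requested normalization with a missing or
  non-positive-mean control is an error, not a silent skip.
* **Distance constraint violations** are errors at panel construction, not
  warnings: a too-close reference contaminates the correction and there is
  no sensible partial result.

## Synthetic acquisitions

The generator renders what the estimator assumes, plus realistic detection
noise: nuclear-localized signal (a disc), a rectangular bleached region
inside it, six circular measurement ROIs in the bleached area and a circular
unbleached reference elsewhere in the nucleus. Noise is Poisson on the
expected signal counts, then a constant background offset, then Gaussian
read noise, stored as 16-bit unsigned with saturation clipping; masks are
rasterized centre-in. One top-level seed spawns independent per-channel
substreams, so identical parameters give bit-identical images.

Defaults (chosen once as a moderately bright confocal acquisition; the
source protocols state no bit depth or detector settings, so these are
fabricated and documented as such): 200×200 px at 0.1 µm/px, D0 = A0 = 1000
counts/px, background 10 counts, read noise 2 counts RMS, B = 0.9,
positive-control E = 0.35. Scenario presets mirror the study designs:
binary pair vs negative/positive controls, third-partner competition (the
competitor lowers the pair's true E by 16%, the magnitude the method is
expected to resolve), and pathogenic-variant panels (variant E = 0).

What the generator does **not** emulate: point-spread-function blur,
3-D structure, bleach kinetics across the bleach repeats (only the end
state), donor photobleaching during acquisition, spectral bleed-through, and
cell-to-cell expression variability. Passing recovery tests therefore shows
the estimator and its QC/aggregation logic are correct under their own
model, with shot-noise-limited data; it does not certify robustness to
optical artifacts real microscopy adds.

Co-localization pairs are built inside the nucleus mask from a shared plus
an independent Gaussian field, so the population Pearson correlation equals
the target exactly and the sample correlation converges at the usual 1/√n
rate. Track pairs draw disordered-segment residues to satisfy the IDR rule
through the disorder track, the pLDDT track, or both (chosen per residue),
and non-segment residues to satisfy neither.

## Statistics

The signed-rank test computes W+ (midranks for ties, zero differences
dropped and counted). For up to 25 nonzero differences the two-sided p is
exact: the null distribution of W+ over all 2^n sign assignments is built by
convolution over doubled ranks (so midranks stay integral), and
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Beyond 25, a normal approximation
with tie correction and a 0.5 continuity correction toward the mean is used;
the method is recorded in every result.

The published analysis style applies a paired test to condition groups that
are arguably independent cell populations. `compare_groups` keeps that
behaviour available — equal-sized groups are paired by rank order — but
records the pairing in the result and offers the unpaired rank-sum
alternative, which is the statistically safer recommendation for
independent cells; unequal group sizes fall back to rank-sum explicitly.
The unit of replication is the cell by default. Star bands: * p ≤ 0.05,
** p ≤ 0.009, *** p ≤ 0.0009, most extreme band first. Boxplot summaries
use linear-interpolation quartiles and Tukey whiskers (furthest observation
within 1.5·IQR); no multiple-testing correction is applied across condition
pairs.

## Structure confidence

PAE matrices are read from the two common JSON layouts (nested or flat
row-major lists under `pae`/`predicted_aligned_error`, and the
residue1/residue2/distance triplet form); chain ranges come from an explicit
argument or a companion model file and must partition the matrix. An
interface score is the arithmetic mean over one rectangle rows(a)×cols(b) in
1-based inclusive residue coordinates; the matrix is asymmetric, so
averaging both rectangles is opt-in (`symmetric=True`), not the default.

Contacts use VDW overlap r_i + r_j − d with an inclusive cutoff of −0.4 Å
(the "contact" default of interactive clash/contact finders; a small
comparison epsilon keeps planted exact-boundary pairs inclusive under
floating point). Radii are the Bondi (1964) element table with common metal
extensions, overridable per call. Pairs within one residue and non-hydrogen
pairs closer than 1.9 Å (treated as covalently bonded, which also removes
peptide-bond neighbours) are excluded. Neighbour search uses a k-d tree at
the maximal contact distance, so results equal the all-pairs computation
exactly — an equivalence the test suite checks against an independent
all-pairs oracle. pLDDT extraction uses the predicted-model convention
(per-residue confidence in the B-factor field), CA as the representative
atom for polymer residues and the first atom otherwise, with missing residue
numbers reported as NaN gaps.

## Sequence features

IDR consensus: residue flagged iff disorder > 0.5 OR pLDDT < 50, both
strict, so a residue at exactly the threshold is structured; either track
may be absent, degrading to the present one. Maximal flagged runs of length
≥ `min_len` (default 5) become segments; the minimum length suppresses
single-residue flips and is configurable down to 1 (the raw rule). Reported
coordinates are 1-based inclusive.

Conservation: columns where the reference sequence has a gap are dropped
first, so profile coordinates equal reference residue numbers. The default
score is the fraction of non-gap residues sharing the reference residue's
physicochemical class (hydrophobic AVLIMFWYC, positive KRH, negative DE,
polar STNQ, special GP); the identity option scores matches to the reference
residue itself. Scoring against the reference (rather than the column
majority) keeps the profile monotone when reference-like sequences are
added and ties each score to the residue the coordinates name. The viewer
tracks such profiles are usually compared against use unspecified internal
metrics, so agreement with them is qualitative; the default threshold of
0.8 marks "highly conserved" and is a package choice, not a published value.

Charge classification: f+ = fraction of K/R, f− = fraction of D/E, histidine
neutral at physiological pH. Regions are assigned in priority order — R1 if
f+ < 0.25 and f− < 0.25; else R2 (Janus/boundary) if FCR ≤ 0.35; else R3
(strong polyampholyte) if |NCPR| ≤ 0.35; else R4/R5 (negative/positive
polyelectrolyte) by the sign of NCPR — which makes the assignment exhaustive
and mutually exclusive over the whole composition simplex (verified by grid
enumeration at 0.01 resolution).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problem sizes chosen to make
Monte-Carlo error small against each tolerance: 120–200 px scenes, 25 seeds
× 4 efficiency levels × 18 ROIs for stochastic recovery (MAE tolerance
0.02), 12 cells per arm for the competition scenario (±3 percentage
points), 500 randomized panels and 100 random 500-atom sets for the oracle
equivalences, 1,000 random track pairs for the IDR rule, 2,000 replicates
for type-I calibration, and 50 seeds for Pearson recovery. All randomness
descends from a single seed via spawned substreams. Floating-point
comparisons against brute-force oracles use 1e-12 absolute slack; the
noiseless FRET recovery bound is 1e-9.

## Known limitations

* The FRET model omits spectral cross-talk and donor bleaching; efficiencies
  from real data carry those biases and the package does not correct them.
* Conservation scores are a transparent stand-in, comparable to viewer
  tracks qualitatively but not numerically.
* The paired signed-rank pairing of independent groups reproduces the
  published analysis convention; rank-sum is provided and preferable when
  pairing has no experimental basis.
* PAE region scores are computed per model; when several predicted models
  exist, the package reports each rather than aggregating to a single
  "best" value.
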