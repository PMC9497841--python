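# Methods

`cfaekit` re-implements, as a tested pipeline, a quality-gated nonlinear
characterization of complex fractionated atrial electrograms (CFAEs) and a
feature-selected coarse-tree classification of paroxysmal vs persistent
atrial fibrillation (ParAF vs PerAF). Clinical CFAE recordings of the kind
the method targets are rarely shareable, so the package ships a synthetic
electrogram generator that stands in for them; everything downstream is
format-identical to what a clinical cohort would provide (16 s, 1 kHz,
single-channel recordings at six left-atrial sites per patient).

## Synthetic electrograms

Each recording is a quasi-periodic train of activation complexes. Activation
times are drawn with Gaussian cycle-length jitter around a mean cycle length
(CL), truncated below at a 100 ms refractory floor. Each activation is a
derivative-of-Gaussian biphasic wavelet (nominal width 12 ms); fractionation
adds 1–4 jittered sub-deflections within ±25 ms at 40–80% relative amplitude,
reproducing the multi-deflection CFAE morphology. Peak amplitude is
normalized to ~1 mV — clinical CFAE amplitude distributions are not well
characterized, so the scale is a convention, and every index used downstream
is amplitude-invariant or amplitude-normalized.

Baseline noise is **band-limited** (4th-order low-pass at 100 Hz, SD set by
`noise_sd`). This is a deliberate model choice: sample-to-sample white noise
at 1 kHz makes the delay-embedded trajectory untrackable and collapses the
determinism index to exactly zero on every segment, which no contact
electrogram exhibits; band-limiting restores the short-horizon continuity
real signals have.

Class presets (chosen once, not calibrated to any clinical table):

| preset | mean CL | CL jitter SD | fractionation | noise SD |
|---|---|---|---|---|
| ParAF | 185 ms | 10 ms | 2 | 0.04 mV |
| PerAF | 145 ms | 25 ms | 5 | 0.06 mV |

These directions (shorter CL, more jitter, heavier fractionation in PerAF)
produce higher sample entropy, lower determinism, shorter AFCL and higher
dominant frequency in PerAF — the contrasts reported for clinical cohorts.
Only the directions are modeled; the magnitudes of the synthetic indices are
not meant to match clinical values. Patients within a class vary by N(0, 8 ms)
in CL and N(0, 2 ms) in jitter; a `separation` knob scales the between-class
contrast (0 gives a null cohort) for calibration studies.

Two artifact classes can be injected on schedule: low-frequency drift
(raised-cosine-windowed sub-2 Hz sinusoid, default 5 mV) and signal loss
(amplitude × 0.01 plus ~0.1 µV noise, so "near-zero range" detectors face a
small but non-zero signal). The generator records ground-truth activation
times and the artifact schedule with every recording.

What the generator does *not* emulate: biophysical tissue dynamics, spatial
correlation between sites, ventricular far-field, catheter-contact dynamics,
and non-stationary mains interference. Passing tests therefore demonstrate
the pipeline's internal correctness and calibration, not clinical
performance.

## Preprocessing

**Powerline removal.** Sine/cosine pairs at the mains frequency and its first
harmonic are fitted by least squares over the full record and subtracted.
This removes only the coherent mains projection (two degrees of freedom per
harmonic over 16 000 samples), so electrogram morphology is untouched even
though fractionated deflections concentrate spectral energy near 50 Hz — a
notch filter wide enough to suppress the tone measurably distorts the
deflections (interference-free correlation drops to ~0.983). The method
assumes the interference is stationary over 16 s; slowly drifting mains would
need block-wise refitting.

**Botteron-style envelope.** Zero-phase 4th-order band-pass 20–250 Hz,
full-wave rectification, zero-phase 4th-order low-pass at 20 Hz, clipped at
zero. The 20 Hz lower band edge (instead of the classical 40 Hz) favors slow
local activations; the 250 Hz upper edge is the classical value. All filters
are applied forward-backward, so activation timing is unbiased.

**Equalization.** The envelope is divided by its local activation-amplitude
profile: local maxima at least 100 ms apart and above 5% of the global 95th
percentile define a profile by linear interpolation of their heights, floored
at that same 5% level. Each activation is thereby scaled by approximately its
own height, bringing low- and high-amplitude activations to a common level
without amplifying inter-activation noise. (A sliding-percentile divisor with
any window longer than one cycle cannot equalize alternating amplitudes — the
divisor is locally constant — which is why the profile form is used.)

## Quality screening

Each recording is cut into 16 one-second segments. A segment is discarded
(bit 0 in the quality vector q1) when either criterion fires:

* **Drift:** the Welch spectrum of the segment (512-sample Hamming windows,
  50% overlap, 2048-point FFT) has its 0–2 Hz peak above the 3–12 Hz peak
  *and* the segment's peak |amplitude| exceeds 2× the recording's median
  per-second peak. The 512-sample window is the shortest that resolves the
  0–2 Hz band from the fibrillatory band at 1 kHz (a 256 ms Hamming window's
  mainlobe spans both).
* **Signal loss:** the segment's amplitude range is strictly below 10% of the
  recording's median per-second range.

All thresholds are relative to the recording itself, so they are invariant to
gain. A per-recording manual override (16 bits) can replace the automated
vector, mirroring clinician adjudication. Coarser vectors are products of
consecutive disjoint q1 groups (q2 from pairs, q4 from quadruples), which
preserves time correspondence and can only widen the discarded coverage —
hence the discard fraction is non-decreasing in window length. The discard
summary reports, per window length (and per site / AF type), the discarded
percentage and the *information loss*: good 1 s sub-segments thrown away
because a longer window containing them was discarded.

## Indices

**Sample entropy.** SE(m, r, N) = −ln(B_{m+1}/B_m) with m = 2, r = 0.35 × SD
of the segment, Chebyshev (maximum absolute coordinate) distance,
self-matches excluded, and N − m templates for both lengths. Constant
segments and zero-match cases return NaN and are excluded from averages,
mirroring the discard philosophy rather than clamping. SE is invariant to
offset and positive scaling because r scales with the SD.

**Delay embedding selection.** For each window length, the time delay τ is
the first robust local minimum of the auto-mutual-information curve (16
equiprobable bins; a lag qualifies when strictly below every value within ±3
lags, which rejects single-lag estimator dips; argmin as fallback) and the
dimension d is the smallest with a false-nearest-neighbor fraction below 1%
(Kennel ratio criterion, R_tol = 10, with a numerical distance floor so exact
recurrences of periodic orbits are not declared false by rounding noise).
Per-segment votes are reduced by the mode, ties toward the smaller value.
Known limitation: on noiseless periodic tones the histogram MI curve carries
no quarter-period minimum (the joint distribution is a one-dimensional
curve), so delay selection is only meaningful for broadband signals —
electrograms qualify.

**Determinism.** The recurrence plot uses ε = 10% of the mean pairwise
Euclidean distance among embedded points ("mean phase-space diameter" read as
mean inter-point distance; the maximal-extent reading is available as a
configuration). DET is the fraction of recurrence points on diagonals of
length ≥ l_min = 50 points, with the line of identity excluded from both
counts (Theiler window of 1, standard RQA practice); l_min is interpreted in
recurrence points, as no unit is attached to it.

**AFCL.** Activations are detected on the equalized envelope as local maxima
above 0.3 × the moving 95th percentile (2 s window) with a 100 ms refractory;
AFCL is the mean successive interval over the full 16 s. On clean morphology
the programmed mean interval is recovered within ±5 ms (and detection within
±10 ms of ground truth). On heavily fractionated short-CL signals the 20 Hz
envelope merges activation pairs closer than ~110 ms, biasing AFCL upward by
up to ~8 ms — an inherent resolution limit of envelope-based detection.

**Dominant frequency.** Welch periodogram with a 4096-point Hamming window,
50% overlap and an 8192-point FFT (0.122 Hz resolution); DF is the largest
peak in 3–12 Hz. In the pipeline the spectrum is taken of the (mean-removed)
Botteron envelope rather than the raw electrogram: the envelope's fundamental
sits at the activation rate, whereas a narrow biphasic deflection has
negligible low-frequency content and its raw spectrum peaks at harmonics of
the rate. This keeps DF ≈ 1000/AFCL within 0.3 Hz on clean periodic trains.
AFCL and DF are computed on the full 16 s regardless of the quality vector.

## Stability and statistics

CV = 100 × sample SD (n−1) / mean. Intra-recording CV is computed across the
usable segments of each recording and averaged over recordings with equal
weight (pooling is the alternative; equal weight keeps each recording's
dispersion commensurable); intra-patient CV across each patient's per-site
mean values, averaged over patients. Both are reported with and without
discards, overall and per class, plus ΔCV. Kruskal–Wallis (tie-corrected,
chi-square reference) compares sites within a patient and is flagged
unreliable when any site has fewer than 5 values; Breusch–Pagan (squared
residuals of the group-means model regressed on group indicators, LM = nR²)
screens heteroscedasticity. Mann–Whitney compares classes per site and index,
after summarizing each recording by the mean over usable segments; the three
per-window p-values are arithmetically averaged — a reporting convention
carried over from the source methodology, not a combined inference — and no
multiple-testing correction is applied by default. Under null cohorts the
stage's empirical type-I error at α = 0.05 is within 0.03–0.07.

## Selection and classification

The patient × (index, site) feature matrix (24 columns with six sites) takes
SE/DET as per-recording means over usable segments of each window length and
AFCL/DF from the 16 s computations; missing cells stay NaN. Pearson
correlation matrices of the per-window matrices are element-wise averaged.
The correlation filter greedily removes, from the most correlated remaining
pair above |r| = 0.60, the member with the larger mean absolute correlation
to everything else (ties: the later column), which is deterministic and
invariant to row order and positive rescaling. A 500-tree random forest
(Gini importance, `max_features=None` so a dominant feature is never
displaced by the feature-subsampling lottery, seeded) rescales importances to
a 0–100 score; features above 40 are selected. "Coarse tree" means a Gini
decision tree capped at 4 internal splits (`max_leaf_nodes=5`). Subset search
evaluates every non-empty subset of the selected features (capped at 12
features) by leave-one-patient-out cross-validation — every row of the
held-out patient leaves the training set, asserted per fold — with ties
broken toward smaller subsets, then column order. Single-feature accuracies
are always computed on the full unfiltered 24 features, since the filter can
eliminate whole index families whose single-feature behavior is still of
interest.

## Problem sizes and determinism

The default synthetic run uses 2 + 2 patients × 6 sites (24 recordings) with
embedding voting on a 60-segment subsample per window length; calibration
suites use 500 null cohorts (Mann–Whitney), 100 seeds (Breusch–Pagan) and 25
seeds (forest ranking). One global seed drives synthesis, the forest and all
calibration draws; a fixed seed reproduces the entire report bundle
bit-for-bit, and every output table carries the run-config hash. All outputs
are delimited text.
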