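# Methods

`painmap` implements a complete, testable pipeline for heat-pain recognition
from peripheral physiological signals: synthetic multimodal data generation,
signal cleaning, a 155-feature bank, a repeated-epoch feature-selection
protocol with SVM evaluation, a Mapper topological feature chart, and an
effect-size interaction analysis.  This note records the model assumptions,
the parameters that matter, and the design choices made where the procedure
was genuinely open.

## The synthetic study

Real per-subject-calibrated heat-pain datasets are access-restricted, so the
package ships a generator whose defaults emulate the structure of such a
study: 85 subjects, five stimulus levels (baseline B plus four calibrated
intensities T1–T4), 20 trials per subject per level, and a 5.5 s response
window per trial recorded on five synchronized channels — zygomaticus,
corrugator, and trapezius surface EMG (arbitrary units), skin conductance
(µS), and ECG (mV).  One extra pain-free (B) recording per subject serves as
the baseline reference for the similarity features; it is not one of the 20
counted trials.

Channel models:

* **EMG** — band-limited Gaussian noise (default band 20–250 Hz at 512 Hz)
  whose envelope amplitude is the driving parameter:
  `amp = base · gain_subject · (1 + d · cv · o/4 + cv · ε)`, with `o` the
  level ordinal, `cv = 0.25` the trial-to-trial coefficient of variation, and
  `d` the within-subject Cohen's d between B and T4.  Defaults: facial sites
  (zygomaticus, corrugator) d = 0.65, trapezius d = 0.35 — the facial response
  to pain is the stronger one, and these values sit mid-band of the medium
  (0.5–0.8) and small (0.2–0.5) effect categories the interaction analysis
  reports.
* **SCL** — subject tonic baseline (uniform 2–10 µS) plus a stimulus-locked
  phasic response: a Bateman (bi-exponential) kernel with 0.75 s rise, 2 s
  decay, 0.7 s latency, amplitude 0.3 µS scaled by the same kind of level
  effect (d = 0.6), plus slow drift and measurement noise.
* **ECG** — a train of Gaussian-bump QRS complexes (σ = 20 ms, 1 mV).  Mean
  rate is the subject's resting heart rate (uniform 55–95 bpm) with a small
  level-dependent *decrease* (d = −0.35 on a 2 bpm trial SD) and 2% relative
  beat-to-beat RR jitter.  Only R-peak timing carries information; no P/T
  morphology is modelled.
* All channels receive an additive 50 Hz mains sinusoid (configurable scale;
  0 disables it).

Per-subject response gains are log-normal with median 1 (σ = 0.25), so
residualizing subject effects matters downstream.  Everything derives from a
single master seed through `numpy.random.SeedSequence`; regenerating any
trial is bit-exact.  A *null mode* zeroes every level effect, making the
level labels exchangeable — the basis of the type-I-error checks.

The generator also provides a feature-level shortcut
(`synth_feature_matrix`): a registry-shaped matrix of unit-variance noise
with subject intercepts and effects injected into designated columns.  It
exercises the selection and interaction machinery against a known ground
truth without paying for signal synthesis, and is used wherever the test is
about the selection statistics rather than the signal path.

What the generator does **not** emulate: real EMG burst morphology,
electrode artifacts, motion, respiration coupling, habituation across trials,
or any correlation structure between channels beyond the shared level effect.
Passing tests therefore demonstrate that the machinery recovers what was
injected under clean conditions — not that the pipeline would reach any
particular accuracy on real recordings.

## Preprocessing

EMG and ECG are bandpass filtered with 4th-order Butterworth filters
(20–250 Hz and 0.1–250 Hz; edges are clipped to 0.45·fs when a reduced rate
is used).  Filtering is zero-phase (forward–backward) so that timing features
(TMNP/TMNV, R-peaks) are not shifted.  SCL is only segmented — its
information lives below 2 Hz and either filter band would destroy it.

Power-line interference is removed by empirical mode decomposition: the
signal is sifted into intrinsic mode functions (cubic-spline envelopes
through mirrored extrema, Cauchy-type stopping criterion 0.2, at most 10
modes, 12 siftings per mode) and the mode carrying the mains tone is dropped
before reconstruction.  A candidate mode must (a) have its spectral peak
within ±5 Hz of the line frequency and (b) be tone-like, holding at least
half of its spectral power inside that band.  The second gate matters: when
the signal band itself contains the mains frequency, the dominant-frequency
rule alone matches the broadband signal mode, and dropping it deletes signal
rather than interference.  If no mode qualifies, the signal passes through
unchanged.  No EMD library in the environment fit, so the decomposition is
implemented here directly; reconstruction (sum of IMFs + residual = input) is
exact by construction and asserted in the tests.

The Hilbert spectrum — per-IMF analytic-signal amplitude squared, binned
over time (sample resolution ÷ 16) and frequency (64 bins spanning
[0, fs/2]) — is built from the modes retained after line removal, so each
channel is decomposed once per trial.  Binned total energy equals the summed
squared instantaneous amplitudes exactly.

## The feature bank

Each EMG channel gets 39 features, SCL 35 (all but the four
high-frequency-content features MDF, MNF, MOF, ZC), ECG 3 (HRV), for 155
modality-prefixed names (`z`/`c`/`t`/`s`/`h` + abbreviation).  Seven
theoretical groups:

* **Amplitude** — MAV, RMS, PK, P2P; higher-order MAVs of the 1st/2nd
  difference (HOMAV1/2) with MAV-normalized variants; mean relative time of
  local maxima/minima (TMNP/TMNV), extrema defined by a strict sign change of
  the first difference, times normalized to [0, 1].
* **Variability** — sample (n−1) variance and SD, range, IQR
  (linear-interpolation quantiles).
* **Stationarity** — median; SD of the means and of the SDs of 10 equal
  sub-windows (SDMN/SDSD); and the degree-of-stationarity family from the
  Hilbert spectrum: DS(f) = mean over time of (1 − H(t,f)/H̄(f))², with
  IDS = ∫DS df, and energy-weighted variants MIDS = ∫DS·w df and
  MMNDS = ΣDS·w where w(f) is the normalized marginal spectral energy.
* **Entropy** — ApEn and SampEn with Chebyshev template distance (m = 2,
  r = 0.2·SD); FuzzyEn as soft template matching with Gaussian membership
  exp(−(d/r)²) over the same template pairs (no per-template baseline
  removal — the simplest reading of the membership definition); Shannon
  entropy of a 16-bin amplitude histogram (bits); spectral entropy of the
  normalized Welch spectrum divided by log₂(#bins) (∈[0, 1]).  A constant
  signal yields all zeros.
* **Linearity** — per lag τ ∈ [1, 32], linear dependence ρ(τ)² (squared
  Pearson autocorrelation) versus total dependence g(τ) = 1 − exp(−2·MI(τ)),
  where MI is an 8×8 histogram mutual information with a Miller–Madow bias
  correction (without the correction the finite-sample MI bias, ~0.04 nats at
  these lengths, would masquerade as nonlinear dependence).  Histogram bins
  span the full signal range so per-lag histograms are summable.  LDF is the
  lag-mean of max(g − ρ², 0); PLDF is the same statistic on the pooled
  lag-pair population.
* **Similarity** — against the subject's pain-free baseline recording, same
  channel: Pearson correlation, 16×16-bin histogram MI (nats), and Welch
  magnitude-squared coherence (segment length fs/2 samples, 50% overlap,
  Hann) summarized over the modality band (EMG: its passband, SCL: 0–2 Hz):
  mean, median, trapezoidal integral, and the mean restricted to
  coherence > 0.5 (zero if empty).
* **Frequency** — Welch-spectrum mean/median/mode frequency, centroid
  √(Σf²P/ΣP), bandwidth √(Σ(f−MNF)²P/ΣP), and the zero-crossing count
  (zero samples skipped, no hysteresis — signals are pre-filtered).
* **HRV** — R peaks via 5–30 Hz bandpass → squaring → peaks above half the
  2 s rolling maximum with a 250 ms refractory period; then mean RR (ms),
  RMSSD (ms), and the least-squares slope of RR against beat index (ms/beat).
  Fewer than three detected beats yields zeros (5.5 s windows can be sparse).

Implementation notes: the ApEn/SampEn/FuzzyEn template statistics are
computed in one fused O(n²) pass (numba) with memberships below exp(−25)
skipped — beyond double reporting precision; Welch spectra and coherence are
computed on a strided segment matrix using the standard convention (the test
suite asserts exact agreement with `scipy.signal.welch`/`coherence`, which
serve as the independent reference); every closed-form feature is also
checked against naive brute-force oracles at 1e−9 relative (entropies 1e−6).
No NaN or Inf ever leaves extraction: degenerate conventions absorb them.

Z-scoring is available at the matrix level with statistics fit on a
designated row subset (the training partition in cross-validation; all rows
for the descriptive chart).  Constant columns map to zero.

## Feature selection and evaluation

Four classification problems are defined over the level sets {B,T1}, {B,T4},
{B,T1,T4}, and all five levels.  Per epoch (default 100), rows are stratified
by subject and level: one quarter per (subject, level) cell is held out,
the remaining train rows are dealt into three inner folds, and one
seed-chosen fold per epoch validates the selection objective.  With 20
trials per cell this gives exactly 15/5 train/test and 10/5
selection-train/validation rows per cell, verified exactly in the tests.

* **UFS** ranks features by the mean one-way ANOVA F value (hand-coded
  MS_between/MS_within; +∞ for perfect separation sorts first; scipy's
  `f_oneway` is the test oracle) over the epochs' selection-train rows.
* **SFS** runs greedy forward selection with a Gaussian Naive Bayes wrapper
  scored on the validation fold, to a fixed iteration budget, with ties
  broken by registry order.  Votes are tabulated per iteration (which feature
  entered at step i, across epochs).  Because epochs frequently agree on the
  selected *set* but not on entry *order*, the robust set is defined by total
  selection frequency across iterations ("most frequently selected"); the
  per-iteration table is retained for inspection.
* Both statistics are invariant to per-feature affine rescaling, so no
  z-scoring is applied before them; the evaluation stage, which is
  scale-sensitive, z-scores with outer-train statistics only.  Test rows
  never touch selection statistics or normalization fits.
* **Evaluation** trains a linear one-against-one SVM (C = 1) on the
  outer-train rows for each prefix of the ordered feature list and reports
  held-out accuracy mean ± SD across epochs.  The *local maximum* set size is
  the smallest n where adding feature n+1 yields neither a significant
  (epoch-paired t-test, α = 0.05) nor a substantive (≥0.5 accuracy point)
  gain; the *global maximum* is the rounded epoch-mean of the smallest n
  attaining each epoch's peak.  A strictly improving curve returns
  local = global = N; the local value is clipped to the global one, since on
  noisy curves the two rules can otherwise cross.

## The topological feature chart (Mapper)

The globally z-scored matrix is transposed so the 155 features are points in
trial space (the chart is descriptive, not predictive, so no per-CV
normalization is used).  Pipeline: Euclidean pairwise distances; lens =
distance to the 2nd nearest neighbour (an inverse density measure); a uniform
cover of the lens range with N = 4 intervals overlapping by L = 50% of their
length (interval length = range/(N − (N−1)·L), boundary-inclusive
membership); Ward clustering of each region; one node per cluster, edges
weighted by shared-feature count.

The cluster count per region uses the largest-gap heuristic on the Ward
merge heights (cut at the first gap exceeding mean + 1 SD of the gaps).  For
regions with two or fewer gaps that statistic is provably mute (a single
dominant gap can never exceed mean + SD), so when no gap stands out the tree
is instead cut at a global scale reference — the mean off-diagonal distance
of the whole cloud — which separates members that are far apart on the scale
of the dataset while leaving tight regions whole.  Node annotations: size,
mean lens, modality composition, and optional named-set tags (the functional
group labels seen in published charts are analyst-assigned; they are exposed
as manual annotations, not computed).  Export is GraphML plus a JSON
companion.

## Interaction analysis

For each feature, B and T4 values are residualized against fixed per-subject
intercepts (per-subject centering — exact for balanced data).  Normality of
the pooled residuals is gated by a Lilliefors-corrected Kolmogorov–Smirnov
test (α = 0.05): non-normal features use the Wilcoxon rank-sum test, normal
ones a two-sample t-test, both two-sided.  Cohen's d uses the pooled
(n−1-weighted) SD and is signed positive when T4 exceeds B; both the test and
d are computed on the residualized values.  Categories: "−" when p ≥ 0.05 or
|d| < 0.2; otherwise one, two, or three arrows at |d| bands 0.2/0.5/0.8 with
direction from sign(d).  No multiple-testing correction by default
(per-feature reporting); Benjamini–Hochberg is available as an option.  The
wide output table has one row per base feature and one column per modality,
with "na" where a feature is not defined for a modality.

## Problem sizes and numerical choices

The suite and the acceptance script run the generator's *reduced-rate
preset*: 128 Hz sampling with the EMG band clipped to 20–57.6 Hz (the mains
tone must stay below Nyquist, and all band edges scale accordingly).  This
preserves every structural property — trial counts, window lengths in
seconds, feature counts, stratification — at roughly 20× less computation
than 512 Hz.  Structural checks (the 155 × 8500 point cloud) run the full
85-subject roster; statistical checks (type-I calibration, effect recovery)
use reduced rosters whose sizes are stated in the tests, with the per-feature
test count kept above 1000 for calibration.  Selection runs in the smoke
pipeline use reduced epoch counts; the epoch count is a parameter everywhere
and defaults to 100.

Known limitations: EMD separates a mains tone from signal poorly when their
spectra overlap (the concentration gate then leaves the tone in, by design);
FuzzyEn follows the soft-matching definition without template-mean removal,
so values differ from implementations that remove it; LDF/PLDF, the
degree-of-stationarity variants, and the "modified" coherence summaries are
operationalizations of definitions whose original sources give latitude —
each is isolated behind its named function so an alternative can be swapped
in without touching the registry.
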