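# Methods

This note records the models, estimators and design choices behind
`eegfam`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and which parameters matter.

## Study geometries

Two recording geometries are supported throughout. `music12` models
music-listening sessions: 12 frontally weighted 10–20 electrodes
(Fp1, Fp2, F3, F4, F7, F8, Fz, C3, C4, T3, T4, Pz) at 250 Hz, stimuli of
roughly two minutes, continuous arousal/valence annotation in [-1, 1]
emitted at 1 Hz, familiarity scored 1–6 and stratified 1–3 (low) vs 4–6
(high). `video32` models music-video trials: the standard 32-channel
layout at 128 Hz, one-minute trials, a single 1–9 rating pair per trial,
familiarity scored 1–5 and stratified 1–2 vs 3–5. The video geometry is
assumed pre-filtered to 4–45 Hz, so its band set omits delta.

## Synthetic signal model

Each channel is a sum of

* a 1/f-power broadband floor (amplitude spectrum ∝ 1/√max(f, 1 Hz), DC
  removed), scaled to `noise_floor` μV RMS (default 10 μV), and
* one narrowband oscillator per band: white Gaussian noise through a
  causal fifth-order Butterworth band-pass, normalized to a per-band RMS
  amplitude (δ 8, θ 7, α 12, β 6, γ 4 μV).

The amplitudes were chosen once for realism and identifiability: total
signal RMS lands around 20 μV (a plausible scalp-EEG scale, comfortably
below the 100 μV²/Hz bad-channel screen), and each oscillator dominates
the in-band share of the floor so that injected power contrasts are
recoverable from Welch PSD estimates. The model makes no attempt to mimic
real EEG nonstationarities — no eye blinks, drift, or line noise — so
passing tests demonstrate correctness of the estimators and statistics,
not robustness to artifacts.

Three kinds of ground-truth effects can be injected:

* **Band-power effects** (`BandEffect`): for high-familiarity stimuli the
  oscillator amplitude at one electrode/band is multiplied by
  √power_ratio, so the measured high/low band-PSD ratio approaches
  power_ratio. With the default amplitudes the floor biases a 2.0 ratio
  down to ≈ 1.93 in the alpha band, within the 10 % recovery tolerance
  the tests assert.
* **Phase couplings** (`CouplingEffect`): both electrodes of a pair
  receive z_i = λ·s + √(1−λ²)·n_i with a shared narrowband source s.
  PSI has no closed form under this model, so λ is read from a
  pre-computed monotone lookup of measured PSI versus λ (21-point grid,
  40 s of signal, fixed internal seed, cached per band/rate). The lookup
  includes uncoupled in-band background at the floor-to-oscillator RMS
  ratio, which compensates most of the attenuation by the broadband
  floor. High targets can still saturate: in the gamma band with default
  amplitudes the reachable ceiling is ≈ 0.6, so a 0.8-vs-0.2 contrast
  realizes as ≈ 0.57 vs 0.18. Recovery guarantees are therefore stated
  as *ordering* (high > low), not absolute values.
* **Emotion couplings** (`EmotionCoupling`): latent arousal/valence
  trajectories multiply oscillator amplitude by clip(1 + strength·latent,
  0.05, ·). Arousal drives one band (default beta) on a set of electrodes
  (default F3, F4, Fz, C3, C4); valence drives an asymmetry on one pair
  (default alpha at F3/F4, left raised and right lowered). Separate
  strengths per familiarity stratum let emotion decodability differ
  between strata, which is how the stratified-classification direction
  experiments are constructed. Default strength 0.6.

Latent trajectories are Gaussian random walks smoothed with a σ = 3 s
kernel and passed through tanh, giving slowly varying values in (−1, 1)
roughly centred on zero; annotations add N(0, 0.03) observation noise
(clipped to the scale). Video trials draw a single latent pair uniform on
(−0.9, 0.9) and report 5 + 4·latent + N(0, 0.25) clipped to [1, 9]. All
draws for a session flow from one seeded generator, so identical
spec + seed reproduces bit-identical fixtures on disk.

## Preprocessing

Filters are applied forward–backward (zero phase): a group-delay-free
contract matters because Hilbert phases feed the connectivity indices.
The notch is a second-order IIR band-stop with quality factor 30; band
passes are Butterworth of order 5 (the same order used for connectivity
band extraction). Note that forward–backward application squares the
magnitude response, so the effective roll-off is twice the nominal order.
Windows are half-open [start, start + length) slices of 4 s (1000 samples
at 250 Hz, 512 at 128 Hz), non-overlapping, with the trailing remainder
discarded. Band intervals are treated as [lo, hi) when averaging spectra
so adjacent bands sharing an edge (4, 8, 13, 30 Hz) never double count.

## Features

PSD uses a Welch estimator: Hann taper, segment length min(window, 1 s),
50 % overlap, density scaling (μV²/Hz). The per-band feature is the
unweighted mean over in-band bins. Higuchi FD uses k_max = 8 by default —
a standard choice for 4 s windows of 512–1000 samples; the estimate is
the least-squares slope of log mean curve length against log(1/k).
Constant series are reported as FD 1.0 with a degenerate-input warning;
estimates outside [1, 2] (white-ish noise can reach ≈ 2.02) are returned
as computed and flagged rather than silently clamped.

Bad-channel screening flags PSD entries strictly above 100 μV²/Hz; a
subject is dropped when strictly more than 25 % of its PSD entries are
flagged (comparisons are strict because the rules are worded "above" and
"more than"); for surviving subjects a flagged electrode contributes no
PSD in any band (masked to NaN, so it simply disappears from downstream
cells).

Differential asymmetry features subtract the right-hemisphere feature
from the left homologue for each symmetric pair (5 pairs in music12,
14 in video32), applied to FD and to every band PSD. With E electrodes,
P pairs and B bands this yields E + P FD-type and (E + P)·B PSD-type
columns: 17 and 85 (music12), 46 and 184 (video32).

Continuous annotations label a window by the class covering the largest
fraction of its time span ("majority"); exact ties go to the class of the
chronologically earlier annotation, a deterministic, implementation-
independent tie-break. An annotation value of exactly 0 is *not* positive
(classes are defined by positivity). Video windows inherit the single
trial rating, binarized strictly above 4.5.

## Connectivity

Indices are computed on whole recordings — one value per
subject-stimulus-pair-band-method — not on windows. The
frequency-resolved correlation is realized as the zero-lag Pearson
correlation of the band-filtered series (the band filter provides the
frequency restriction); whether a maximal-lag variant was intended is
ambiguous, and zero lag is the assumption made here, consistent with the
sign-removing quadratic-mean aggregation. Coherence averages
magnitude-squared coherence over in-band bins from 1 s Welch segments at
50 % overlap (at least two segments are required — single-segment
coherence is identically 1). PSI uses Hilbert phases with the first and
last 0.5 s excluded, since the analytic signal is unreliable at record
boundaries. Aggregation across stimuli: arithmetic mean for coherence and
PSI, quadratic mean for correlation.

## Statistics

The familiarity × subject ANOVA requires balanced cells, so every
(familiarity, subject) cell is subsampled without replacement to the
global minimum cell size r, with a seeded generator for reproducibility;
r ≥ 2 is required to estimate within-cell error. The fit is an ordinary
fixed-effects two-way ANOVA with interaction (statsmodels OLS + anova_lm;
the design is balanced, so the type of sums of squares is immaterial).
Tukey HSD is applied to the subject factor when significant (familiarity
has two levels, so its post-hoc is the main test itself); simulation
loops can disable the post-hoc, which dominates runtime otherwise.

Significance thresholds follow the two analysis regimes (α = 0.05 music,
α = 0.0001 video) and **no multiple-testing correction is applied across
electrodes or bands** — a deliberate fidelity choice over statistical
best practice; per-table p-values should be read descriptively.

The familiarity-balance screen drops a subject when
min(high/low, low/high) stimulus counts fall below 0.30. Paired
connectivity tests are two-sided paired t-tests on per-subject overall
indices; an all-zero difference vector reports t = 0, p = 1, and a
non-zero constant difference reports |t| = ∞ with a degenerate flag.

Calibration (verified by simulation in the test suite): type-I error of
the familiarity test is 0.05 ± 0.02 at α = 0.05 over 500 null designs,
and power exceeds 0.9 for a 1-SD cell-mean shift with 10 subjects and
r = 30.

## Classification

Targets are binary: arousal high/low and valence positive/negative.
Classifiers are deliberately classic: an SVM with the Pearson VII (PUK)
kernel, an MLP with one hidden layer of (features + classes)/2 units
(400 iterations, seeded), and an entropy decision tree with minimum leaf
size 2 standing in for C4.5. Features are standardized within each
training fold. The PUK width is σ = √p for p features: on standardized
data pairwise squared distances grow linearly with p, and a fixed σ = 1
kernel degenerates toward a constant Gram matrix (we observed exactly
chance-level SVM accuracy before this correction) — the √p scaling plays
the same role as the "scale" heuristic for RBF kernels.

Evaluation is within-subject: each subject × stratum (low, high, all) ×
feature set (FD, PSD — never concatenated) × classifier × target cell is
scored by seeded stratified 10-fold cross-validation (folds shrink to the
smallest class count when a subject-stratum is small; a cell lacking both
classes is skipped and logged). Accuracy is compared to the chance level
(majority-class percentage) per subject, then averaged; strata are
compared with paired t-tests on per-subject above-chance margins.
Windows of the same stimulus may share folds — plain 10-fold CV without
grouping — so temporally adjacent, correlated windows inflate absolute
accuracy; stratum *comparisons* share that bias and remain meaningful.

## Problem sizes in the acceptance computations

The acceptance computations run the full pipeline at deliberately scaled
sizes chosen as the package's own default experiment grid: feature-count
checks on 2-subject sessions; band-ratio recovery on 2 subjects × 8
stimuli × 48 s; PSI-contrast detection on 100 sessions of 10 subjects ×
4 stimuli × 16 s; stratified-direction runs on 20 sessions of 4 subjects
× 8 stimuli × 96 s with strengths 0.9 (low) vs 0.0 (high), evaluated with
the PUK SVM on PSD features for arousal. Longer stimuli are used for the
stratified runs because the combined ("all") stratum sees twice the
training data of either pure stratum; with too few windows the
learning-curve advantage can mask the coupling dilution, whereas at
~24 windows per stimulus the injected ordering
low > all > high is recovered reliably.

## Known limitations

* The generator's stationary oscillator model cannot probe robustness to
  artifacts, drift or electrode failure; the bad-channel screen is tested
  on constructed tables rather than realistic contamination.
* PSI targets near 1 saturate under the default amplitude/floor ratios
  (see above); treat `psi_high`/`psi_low` as an ordered contrast, not a
  calibration promise.
* Absolute classification accuracies depend on generator effect sizes,
  which are free parameters; only structural quantities (feature counts,
  chance levels) and directions/calibrations are meaningful test targets.
* EDF files can be read (via optional mne) but not written; the CSV+JSON
  fixture format is the supported interchange.
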