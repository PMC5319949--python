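# eegfam

Familiarity-aware analysis of affective EEG.

Music familiarity is a subjectivity factor that most EEG emotion-recognition
pipelines ignore: listening to a well-known song engages memory and
expectation differently from hearing a novel one, which shows up both in
band power spectra and in inter-electrode coupling. `eegfam` implements a
complete, tested pipeline for studying that effect and for asking whether
restricting training data by familiarity changes how well arousal and
valence can be decoded from EEG. It targets researchers in affective
neuroinformatics who want each stage — from raw multichannel signal to
stratified classification report — as a composable, seedable library call.

Because affective EEG corpora are either unpublished or license-gated, the
package ships a first-class synthetic session generator with controllable
ground truth, in two geometries: 12 channels at 250 Hz with continuous
arousal/valence annotation in [-1, 1] and familiarity scored 1–6
("music12"), and 32 channels at 128 Hz with one 1–9 rating per trial and
familiarity scored 1–5 ("video32"). Every downstream stage is validated by
recovering the generator's injected effects.

## The analysis

For channels x, y of a recording (zero-phase Butterworth band-filtered to a
band B ∈ {δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–40 Hz}):

* **Band PSD** — Welch mean spectral density over [lo, hi), μV²/Hz, per
  non-overlapping 4 s window; values > 100 μV²/Hz are screened as
  bad-channel PSD, and subjects with > 25 % flagged entries are excluded.
* **Higuchi fractal dimension** — slope of log L(k) vs log(1/k) of
  normalized curve lengths, k = 1..k_max; FD ∈ [1, 2].
* **Connectivity** — per electrode pair: zero-lag correlation
  R = C_xy / √(C_xx C_yy); magnitude-squared coherence
  |P_xy|² / (P_xx P_yy) averaged over in-band bins; phase synchronization
  index PSI = |L⁻¹ Σ_t exp(i[φ_x(t) − φ_y(t)])| from Hilbert phases.
  Per-stratum overall indices use the arithmetic mean (coherence, PSI) or
  quadratic mean (correlation) and are compared with paired t-tests.
* **Replication-balanced two-way ANOVA** — familiarity × subject on
  single-electrode band PSD, each cell subsampled to the global minimum
  cell size, Tukey HSD post-hoc on the subject factor.
* **Stratified classification** — per subject and familiarity stratum
  (low / high / all), FD or PSD features (plus left-minus-right asymmetry
  features) classify binarized arousal and valence with a PUK-kernel SVM,
  a one-hidden-layer MLP, or an entropy decision tree, under seeded
  stratified 10-fold cross-validation, reported against the
  majority-class *chance level*.

## Worked example

```python
import eegfam

spec = eegfam.SessionSpec.music12(
    n_subjects=2, n_stimuli_per_subject=8, stimulus_duration=24.0,
    band_effect_map=(eegfam.BandEffect("T4", "alpha", 2.0),),
    seed=3,
)
recs = eegfam.simulate_session(spec)
table = eegfam.assemble_feature_table(recs, eegfam.FeatureConfig("music12"))

from eegfam.features import fd_feature_columns, psd_feature_columns
print(len(fd_feature_columns(table)), len(psd_feature_columns(table)))

hi = table[table.familiarity_group == "high"]["PSD:T4:alpha"].mean()
lo = table[table.familiarity_group == "low"]["PSD:T4:alpha"].mean()
print(round(hi / lo, 3))
```

prints

```
17 85
1.82
```

17 FD features (12 electrodes + 5 symmetric-pair asymmetries) and
85 PSD features (17 × 5 bands); the injected 2.0× alpha-power contrast at
T4 between high- and low-familiarity songs is recovered as 1.82 from the
extracted features (within the sampling error of sixteen short
recordings; the broadband floor biases the ratio slightly below target). The same session objects feed `connectivity_matrix`,
`two_way_anova` and `familiarity_stratified_eval`; the `eegfam` CLI chains
the stages from the shell (`eegfam simulate`, `features`, `connectivity`,
`anova`, `classify`, `report`).

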