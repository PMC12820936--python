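# Methods

This note documents the models and procedures implemented in
`convoscreen`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real interview
data.

## Synthetic cohort model

Each virtual participant carries six latent construct severities —
cognition, social connectedness, neuroticism, negative affect, social
satisfaction, psychological well-being — generated from a single shared
factor with loading 0.5 (`factor_loading`), so outcomes co-vary without
asserting any particular real-world correlation structure. Severities
are standard-normal on the z scale and mapped to [0, 1] by the normal
CDF for stream generation.

**Assessment scores** are the instrument-scaled severity plus Gaussian
measurement noise: score = μ + σ·(ρ·z + √(1−ρ²)·ε), with (μ, σ) set to
published cohort marginals (MoCA 24.54 ± 3.61, LSNS-6 14.13 ± 5.86,
neuroticism 16.44 ± 8.41, negative affect 48.57 ± 10.93, social
satisfaction 49.02 ± 11.77, psychological well-being 50.87 ± 9.99) and
sign chosen so that higher severity worsens the score. The
severity–score correlation ρ (`score_reliability`, default 0.9) plays
the role of instrument reliability; it caps the attainable AUROC of any
feature pipeline, since labels are dichotomized noisy scores. CDR (0.5
with probability σ(2z)) and clinical diagnosis (MCI with probability
σ(2z + 0.35)) are Bernoulli in the cognition severity, calibrated to
roughly the emulated cohort's 19/39 and 22/39 splits. Demographics: sex
F with probability 29/39, integer ages ~ N(80.69, 4.6²) clipped to
75–95, years of education ~ N(15.44, 2.34²) clipped to 8–22.

**Streams** are regime-switching Gaussian processes. A stream with
effect size *e* and centered severity u = 2·severity − 1 uses a sticky
transition matrix 0.88·I + 0.12·𝟙πᵀ whose stationary distribution π is
softmax(e·u·[−1.5, −0.5, 0.5, 1.5]) over four states: severity tilts
state occupancy toward higher states. State k emits
N((k − 1.5)·w_state, σ²I) along a fixed per-feature-set direction, plus
a direct mean shift 0.3·e·u·w_shift — so both the *dynamics* and the
*level* carry signal. Directions are deterministic per feature set
(hashed), emission SD defaults to 1. `effect_size` accepts a scalar or
a per-stream mapping; 0 decouples streams from labels exactly.

**Default feature sets** mirror the extraction pipelines they emulate:
emotion+AUs 24-dim at 1 Hz, generic facial embedding 1024-dim at 1 Hz,
acoustic statistics 34-dim at 10 Hz, speech embedding 768-dim,
utterance sentiment 9-dim at 1/15 Hz, a single static 8192-dim text
embedding, and a 1 Hz BPM stream. The speech-embedding default rate is
5 Hz (the real extraction cadence is 50 Hz): at 25–47-minute interview
lengths a full-rate 768-dim cohort would need tens of gigabytes, and
the participant-level aggregates the pipeline consumes are invariant to
frame rate; the rate is configurable for users who want the full
cadence. Interview lengths are uniform on 25–47 minutes.

**Pulse and BPM.** The cardiovascular channel is generated as a
quasi-periodic waveform (fundamental plus a 0.3-amplitude second
harmonic) whose instantaneous frequency is (mean BPM + jitter)/60 with
AR(1) jitter (lag-1 correlation 0.95, stationary SD 3 BPM by default) —
heart rate drifts smoothly, which is also what makes windowed spectral
estimation meaningful. Mean BPM shifts with severity (72 + 6·e·u). The
BPM stream the pipeline sees is *estimated* from this waveform by the
package's own spectral estimator, not copied from the truth; true
per-second BPM and true state paths live in an oracle-only channel that
featurization never touches.

**Label–attribute confounding** for fairness experiments: setting
`bias_attribute`/`bias_strength` adds a z-shift to all construct
severities of the flagged group (e.g. sex = F), making labels and
features genuinely group-dependent so that threshold mitigation has a
real disparity to remove. Default is 0 (no manufactured bias).

What passing tests on these cohorts shows: the protocol recovers known
structure, is calibrated on null data, and its estimators match
independent oracles. What they do not show: anything about the joint
distribution of real interview features — the generator matches a few
published marginals only, its regime-switching form is an assumption,
and real within-interview nonstationarity is uncharacterized.

## Temporal featurization

Statistical aggregation is per-dimension mean and *population* SD
(ddof = 0; a single frame gives SD 0).

The group HMM is a 4-state diagonal-covariance Gaussian HMM fitted to
all training participants' sequences jointly (multi-sequence
likelihood), K-means initialization, exactly 20 EM iterations (no early
stopping). Sequences are fitted and decoded at **native length**; the
alternative of zero-padding every sequence to the longest training
length T_max is available (`pad_to_tmax`) but off by default, because
zero-padding injects a spurious near-zero regime into Gaussian
emissions — with padding on, summaries are still computed over the
native prefix. State summaries use the most-likely joint path
(Viterbi); a posterior mode computes durations as mean posterior mass
instead. Duration is the occupancy fraction (sums to 1); frequency is
the number of maximal runs of a state per 100 native frames — the per-100
normalization makes it length-invariant and comparable across
participants. One HMM is fitted per (feature set × fold) and shared
across outcome tasks.

BPM estimation analyzes 6-second windows advanced 1 second at a time:
Hann-windowed, zero-padded ×8, dominant peak of the power spectrum
within 0.65–4.0 Hz (39–240 BPM; the band is this package's choice).
Quantiles use linear interpolation between order statistics.

Uniform resampling picks frame indices round(i·(F−1)/(T−1)), always
retaining both endpoints; only downsampling is allowed.

## Classifiers

Shallow families use scikit-learn with the published hyperparameters
(LR: L2, max_iter 1000; GBDT: 100 estimators, learning rate 1.0, depth
3; SVM: RBF, probability = True; RF: 100 trees) and run seed 42 + run.
LR and SVM sit behind a train-fold-fitted z-scoring step (Pipeline), a
conventional default recorded in the run manifest; tree ensembles take
raw features. Single-class training folds raise and are skipped with a
logged reason, never imputed.

The neural models (LSTM hidden 128 / one layer; transformer encoder
with embed 128, 4 heads, 2 pre-norm layers, 32-unit MLPs, dropout 0.1,
learned CLS token and positional embeddings; MLP with one 64-unit ReLU
layer, dropout 0.3) are implemented on a small in-package reverse-mode
autodiff engine over numpy, validated against finite differences. All
train exactly 10 epochs of Adam (lr 1e-3, batch 8) on cross-entropy —
optimizer and batch size are unstated in the protocol and fixed here as
standard values. Dropout is inference-disabled, so predictions are
deterministic given a seed.

## Evaluation protocol

Fold plans: per run, a shuffled participant-wise 5-fold partition gives
the test folds; within each outer training set a further fifth is held
out for validation (64/16/20). All families share the same plans; plans
are fully determined by the seed base (42).

The per-run metric is the **mean of the five fold-level metrics**, and
the summary across runs is mean ± 1.96·SE (a percentile mode exists).
Pooling the five folds' predictions before computing AUROC is available
(`per_run="pooled"`) but not the default: with unstratified
participant-wise folds the classifier's score scale shifts with each
training fold's class prior, and ranking scores *across* folds turns
those shifts into systematic inversions — measured at about 0.41 mean
AUROC on label-independent data, where fold-averaged AUROC is correctly
centered at 0.5. Fold-level AUROC is undefined on a single-class test
fold and such folds are dropped from that run's mean.

A related subtlety governs null testing: repeated CV runs on one cohort
are correlated through that cohort's sampling noise (a 39-participant
null cohort has a "true" CV AUROC that deviates from 0.5 by O(n^-1/2)).
Calibration is therefore asserted across independent cohorts, with the
standard error taken over cohort-level means.

Every fold-fitted object (HMMs, scalers, demographics encoders,
median cutoffs, classifiers) records a fingerprint of the participant
ids it saw; `assert_no_leakage` verifies that no fitted object touched
a validation or test participant.

## Fusion, attribution, fairness

Fusion ties and fallbacks are deterministic and logged: an even vote
goes to the class with the larger mean voter probability (positive
class if no probabilities); average-probability at exactly 0.5 goes
positive; selective voting requires validation AUROC strictly > 0.5
(undefined AUROCs do not qualify) and falls back to all voters when
none qualify. Demographics votes in every multimodal preset.

Shapley values impute missing features from background reference rows
(training-fold feature means by default — the baseline is a package
choice, logged per run) and switch automatically between exact subset
enumeration (⩽10 features) and permutation sampling. MM-SHAP divides
each modality's mean |φ| by nothing further — the per-dimension mean
*is* the dimension normalization — then normalizes across modalities;
all-zero attribution rows are excluded from the global mean and logged.
For fused pipelines, attribution is computed on the concatenated
per-modality feature blocks with the fused (average) probability as the
explained function.

Fairness ratio conventions: a 0/0 rate ratio is 1 (two identically
degenerate groups are not a disparity), a defined-vs-zero ratio is 0,
and DPR is 1 when no group selects anyone. The four-fifths flag raises
iff min(DPR, EOR) < 0.8. Equalized-odds post-processing searches the
intersection of the groups' ROC convex hulls along an FPR grid (501
points) for the balanced-accuracy-maximizing common operating point;
each group realizes it by mixing two adjacent ROC thresholds (decision
rule: score ⩾ t) and, where its envelope exceeds the common TPR, a coin
at rate FPR\*. On the fitting set the *expected* rates of this
randomized rule hit the target exactly; realized rates fluctuate with
the coin flips. The subgroup F1 trade-off uses positive-class F1 per
subgroup, unweighted mean (macro mode available); a subgroup with
neither positives nor positive predictions contributes 0.

Attribute binnings are fixed: sex; age ⩽78.9 vs >78.9; years of
education ⩽15 / 16 / ⩾17; NC vs MCI.

## Problem sizes used in the checks

The package's calibration checks run at deliberately reduced sizes
chosen to keep the full suite interactive: null calibration uses 10
independent 39-participant cohorts × 5 CV runs; signal recovery and
modality ranking use one 200-participant cohort × 5 runs; the
mitigation trade-off uses one biased 200-participant cohort × 50 runs;
Shapley oracle agreement uses 8-feature models at 2000 permutations.
These sizes are the package's own choices; the protocol itself supports
the full 100-run setting via configuration.

## Known limitations

- The generator's regime-switching form and its construct-to-stream
  assignments are assumptions; real extracted features are not
  guaranteed to have HMM-recoverable structure.
- Score calibration matches published marginal means/SDs only, not
  joint distributions or NC/MCI-conditional contrasts beyond what the
  shared factor induces.
- The transformer and LSTM are CPU-sized; at full stream dimensions
  they are slow and intended for methodological comparison, not
  throughput.
- Selective voting's gate uses small validation folds (6–7 participants
  at N = 39), so its validation AUROCs are high-variance; this mirrors
  the protocol rather than fixing it.
- No in-processing or adversarial debiasing; no race attribute; no
  early/mid fusion — all outside the implemented protocol.
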