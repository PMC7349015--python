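# Methods

This note documents the models, conventions, and design choices behind
`cogstates`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and what the synthetic validation does
and does not establish.

## Signals and windows

The data model assumes a 14-channel scalp EEG (10–20 subset AF3, F7, F3,
FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4) sampled nominally at
128 Hz, in microvolts, together with optional 30-fps 68-point facial
landmarks, a continuous-performance trial log, one engagement score in
[0, 1] per 10 s, and cognitive-skill scores in [0, 800].  The sampling
rate is a first-class parameter everywhere — nothing assumes 128 Hz — and
time is seconds from session start.  Sessions are segmented into
consecutive, non-overlapping, **half-open** windows `[start, end)` of a
configured length (10 s or 60 s); the trailing partial window is dropped
(`floor(duration/length)` windows).  Half-open intervals prevent a sample
or trial at a joint from being counted twice.  Artifact handling is out of
scope: recordings are assumed cleaned upstream.

## EEG features

**Time domain (15 per channel).** min, max, mean, sample variance and SD
(ddof = 1), coefficient of variation (SD/mean), Fisher kurtosis, skewness,
quartiles, Shapiro–Wilk W and p (scipy implementation), and the two Hjorth
parameters.  Hjorth mobility is `sqrt(var(Δx)/var(x))` and complexity is
`mobility(Δx)/mobility(x)`, with the derivative taken as the **forward
difference** and variances taken as **population** (1/N) variances — a
deliberate asymmetry with the descriptive statistics, pinned by tests.
For a pure tone of frequency f this gives mobility `2·sin(πf/fs)` per
sample and complexity ≈ 1, which the tests verify against brute-force
evaluation.

**Degenerate inputs.** A constant channel makes CV (when the mean is 0),
kurtosis, skewness, Shapiro–Wilk and the Hjorth parameters undefined;
these become NaN sentinels, the window's QC flag is set, and QC-flagged
rows are dropped before modeling.  Returning silent zeros instead would
bias feature scaling toward the sentinel value.  "Constant" is decided at
floating-point resolution (variance below `(1e-12·max|x|)²`), so a linear
ramp's forward differences are treated as constant even though they vary
in the last bit.

**Frequency domain (5 per channel).** A multi-level discrete wavelet
transform with the Daubechies-8 mother wavelet (periodization mode, exact
reconstruction) decomposes each window.  The decomposition depth is the
smallest level whose final approximation band lies within 0–4 Hz, which
isolates the delta band at any sampling rate (4 levels at 128 Hz, 7 at
1000 Hz).  Each level's dyadic band is labeled with the canonical rhythm
covering at least half of it — delta < 4 Hz, theta 4–8, alpha 8–16, beta
16–32, gamma 32–63 — and bands above 63 Hz are labeled noise and excluded
from the canonical feature set.  Two consequences are documented
prominently: **alpha here is the dyadic 8–16 Hz band**, wider than the
classical 8–12 Hz, because a dyadic filter bank cannot produce a
non-dyadic split; and the band map is keyed by frequency range, never by
level number, so the same code is correct at any sampling rate.

Band energy is the sum of squared coefficients over the levels mapped to
the band; total energy sums all levels including noise, so relative powers
over all mapped bands sum to 1 (±1e-9, a tested invariant).  Average power
is total energy per sample.  Zero total energy makes every relative power
NaN (QC-flagged).  Against a periodogram oracle, the dominant band of a
pure in-band sinusoid always agrees and the relative power matches within
15% (filter leakage at dyadic edges accounts for the slack).

**Baseline normalization.** Per-channel, per-band activity power can be
expressed in decibels relative to the mean power of a 36-s resting
recording (15 s eyes open + 15 s closed + 6 s ready):
`10·log10(P_act/P_base)`.  A non-positive baseline power is an error; zero
activity clamps at −120 dB rather than −∞.  Whether band powers should be
baseline-normalized before or instead of relative powers is genuinely
open; both are emitted (`rel_*` always, `db_*` when a baseline is given)
and the modeling default consumes `rel_*` + `avg_power`, keeping the
frequency vector at 5 features/channel (70 for 14 channels; 15/channel and
210 total in time mode; 280 combined).

## Facial features

Frame-level EAR, MAR, NTJ and NTC are ratios of Euclidean distances on the
1-based p1..p68 landmark scheme; the index arithmetic follows the standard
right-eye formula exactly, the left eye uses the symmetric block p43–p48,
and `ear` is the mean of the two (all three are emitted).  Being distance
ratios they are invariant under planar rotation, translation and uniform
scaling (property-tested on random similarity transforms).  A zero
denominator (collapsed geometry) flags the frame as degenerate; degenerate
frames are excluded from window statistics but never dropped from the
series.

Frame-to-window aggregation is not standardized anywhere; the package uses
{mean, sd, min, max} per base feature plus a blink count — minimal,
configurable summaries.  Blinks are maximal runs of ≥ 2 frames with
EAR < 0.21, the conventional operating point of landmark-based blink
detectors.  Deep frame embeddings are out of scope; a provider interface
(frames in, fixed-length vectors out, averaged across the window's frames)
replaces them, with a deterministic synthetic provider (a fixed random
linear map of the coordinates) for exercising the plumbing at d = 1024.

## Labeling

* Engagement: score > pooled-cohort median ⇒ engaged; a 60-s window uses
  the median of its six 10-s scores.  **Ties label non-engaged**: the low
  state is the positive, recall-weighted class, so ambiguity resolves
  toward it.  The threshold is always recomputed from the cohort at hand.
* Attention: mistakes (incorrect trials with onset in the window) < 4 ⇒
  high, ≥ 4 ⇒ low, for both window lengths.
* Skills: low < 200 ≤ moderate < 400 ≤ high.
* Dependence between binary label sets uses the plain 2×2 chi-square test
  (df = 1) without Yates continuity correction (a flag enables it).

## Modeling protocol

Stratified 80/20 split (70/30 recommended for the 1-per-subject skill
targets); scaling (standard, or robust = median/IQR for outlier-heavy
features) is fit on training rows only; classifier families from
scikit-learn with small grids around the published preset settings
(RF Gini 100/400/1000 trees, extra trees, single-hidden-layer-50 logistic
MLP, KNN k ∈ {3, 5, 11}, linear/RBF SVC, logistic regression, QDA); grid
selection by mean cross-validated F2 on the training split; final metrics
on the untouched test split with the low state as positive class.
Splitting is by window, not by subject, replicating the as-published
protocol (a subject's windows can span both splits); a
`group_by_subject` flag provides the stricter grouped split.

**Balancing.**  SMOTE is implemented directly (k-NN interpolation between
minority points, k = 5, reduced with a warning when the minority is
smaller, duplication fallback at minority = 1) and applied to training
data only.  Crucially, within cross-validation it is applied **inside each
fold** to the fold-training portion, so validation scores are measured on
untouched, naturally unbalanced data.  Balancing the pooled training set
before folding leaks synthetic interpolants into validation folds; a
forest then scores CV F2 ≈ 0.95 on *permuted* labels (it learns to
recognize interpolants, not classes) while collapsing to 0 on the test
split — in-fold balancing removes this artifact.

**Permutation control.**  The recovery experiment's attention task uses a
two-family grid {RF preset, KNN k = 11}, identically for the real and the
permuted-label fits.  On real signal RF wins selection outright.  On
permuted labels no classifier can beat the always-positive bound
(F2 = 5p/(4p+1) at positive prevalence p, the maximum over
label-independent predictors), and F2-oriented selection correctly drifts
to the recall-heavy family, landing near that bound (measured ≈ 0.41 vs
bound 0.45); a single forced RF would instead predict the majority class
and score ≈ 0, which says the same thing — no signal — less legibly.
F-beta of (precision, recall) = (0, 0) is defined as 0.

## Synthetic cohorts

The generator is a pure function of (config, seed): identical inputs give
bit-identical cohorts (per-subject seeds are spawned from the cohort
seed).  Defaults emulate the target study design: 14-minute sessions at
128 Hz, one engagement score per 10 s (84 per session), one trial per
second, and an imbalanced low-attention state (~15% of windows, matching
the published 202/1360 imbalance); latent engagement (p = 0.5) and
attention states are drawn per 10-s interval, coupled
(P(lapse|engaged) = 0.08, P(lapse|non-engaged) = 0.22) so the two label
sets are chi-square dependent, as observed in practice.

EEG is a sum of band-limited sinusoids — one random in-band carrier and
phase per channel and band — rather than filtered noise, because sinusoids
have analytically known band powers for oracle tests.  Engagement trades
alpha against beta power (alpha suppression with beta rise when engaged,
the direction of the classical beta/(alpha+theta) engagement index);
attention trades theta against beta (theta rise and beta drop during
lapses).  Amplitude pairs are power-balanced and the two state
contributions combine in the power domain, so **total power is identical
across all four latent combinations**: only the deliberately modulated
bands are informative, making the feature-importance recovery check sharp
(relative-power normalization would otherwise smear class signal into
every band).  Background noise is an equal mix of white and 1/f noise
(2 µV by default); a per-subject gain U(0.5, 2) emulates the
inter-individual differences (hair, skull thickness) that motivate decibel
baseline normalization.  The default
`engagement_signal_strength = 1` (perfect class separation) with this
modest noise is the idealized recoverability regime the validation is
defined in; strength scales both the score separation and the EEG
amplitude separation, down to indistinguishable classes at 0.

Mistake counts per 10-s window are Poisson (0.5 high / 8.0 low attention)
truncated to the trials available; the low rate is set high enough that
the < 4-mistakes rule recovers the latent state with ≈ 99% fidelity —
lower, more realistic rates inject label noise that caps attainable F2,
which is a property of the labeling rule, not of the classifier.
Engagement scores blend a class-separated component (engaged
0.5 + 0.5·Beta(2,2), non-engaged mirrored) with a class-free uniform
component by the signal strength.  Landmarks animate a neutral symmetric
face template with Poisson blinks (150–300 ms closures, refractory 0.4 s,
8/min engaged vs 18/min non-engaged), occasional mouth openings, slow
sinusoidal head-pose drift driving NTJ/NTC, and Gaussian jitter.  Skill
scores are uniform on [0, 800] with no signal linkage — the skill modeling
path is validated on features with injected structure instead.

**What synthetic validation shows — and does not.**  Passing recovery
demonstrates that the implementation chain (windowing, band-power
extraction, labeling rules, balancing, scoring) is internally consistent
and leak-free at desk scale.  It does not establish that real EEG carries
the assumed band-power signatures, that real engagement scores separate at
the median, or that real performance approaches these F2 values: real
recordings have nonstationary spectra, artifacts, inter-subject
variability far beyond a gain factor, and far weaker class separation.
Published headline scores on human cohorts are therefore not reproduced
here and the recovery numbers must not be read as comparable to them.

## Problem sizes

The standard desk-scale recovery uses 60 subjects × 84 ten-second windows
(5040 windows, 70 features), a 100-tree forest, 3-fold CV for model
selection and 3 permutation replicates; the analysis drivers use a
12-subject, 5-minute cohort for the staged walkthrough.  The acceptance
script reports windowing arithmetic at the 109-subject study scale, where
segmentation yields 9156 ten-second and 1526 sixty-second windows.

## Known limitations

* Dyadic alpha (8–16 Hz) differs from the classical definition; studies
  needing 8–12 Hz alpha should use a non-dyadic method.
* The EDF reader requires `mne`; CSV is the canonical format and the only
  one with write support.
* Facial-landmark ingestion starts from precomputed landmarks; no video
  processing or landmark detection is included.
* Window-level (not subject-level) splitting can leak subject identity
  between train and test; use `group_by_subject` for deployment-grade
  estimates.
* The generator's distributions are plausible stand-ins, not fits to any
  recording.
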