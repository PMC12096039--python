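# Methods

`dyadtrf` implements an encoding-model analysis of EEG recorded while two
people dance together, and a ground-truth simulator that makes every stage of
that analysis testable without access to real recordings. This note documents
the models, the simulator's assumptions, the numerical choices, and what the
synthetic validations do and do not establish.

## The encoding model

Each EEG channel `y_c(t)` is modeled as a sum of convolutions of feature time
series `x_k(t)` with per-feature temporal response functions (TRFs)
`w_k(τ)` over lags τ ∈ [−250, +300] ms (56 lags at 100 Hz):

    y_c(t) = Σ_k Σ_τ w_{k,c}(τ) x_k(t − τ) + b_c + ε_c(t)

The negative lags let the model capture anticipatory (premotor) activity;
the window is deliberately shorter than the ~500 ms beat period so that one
event's response is not confounded with the next beat's.

The features are: broadband spectral flux of the music (gammatone filter
bank, 128 log-spaced bands 100–8000 Hz; per-band envelope derivative,
half-wave rectified, band-averaged); the velocity magnitude of the dancer's
own vertical bounce; the partner's bounce velocity magnitude; the social
coordination sign (product of the two signed bounce velocities: +1 in-phase,
−1 anti-phase); and, as artifact controls, left/right EOG and cheek/neck
EMG. All series are standardized to the participant-level SD computed across
all trials (means untouched).

Weights are estimated by ridge regression with the intercept unpenalized,
implemented by column/target centering (algebraically identical to zeroing
the intercept's penalty entry). The regularization λ is chosen per held-out
trial by leave-one-trial-out cross-validation over the grid
{0, 10⁻⁴, 10⁻³, …, 10⁸}, maximizing the channel-mean Pearson correlation of
the held-out prediction; ties break toward the smaller λ (less smoothing,
deterministic). A subject's TRF is the average of the leave-one-trial-out
fold fits, each at its fold's λ. Prediction accuracy is "generic": each
participant's trials are predicted from the unweighted mean of all other
participants' TRFs, and Pearson r is computed per channel on the
trial-concatenated series (per-trial averaging is available as an option;
concatenation is the default reading of accuracy "across all trials").

The unique contribution of a feature, Δr, is the per-channel difference in
generic prediction accuracy between the full model and a reduced model
refit without that feature. Body-part-specific models replace the bounce
features with 16 marker velocity magnitudes plus neck EMG, with reduced
models dropping each hand, each foot, or the four head markers together. A
coordination control refits the comparison inside a model that also carries
both dancers' velocity-sign series, so that Δr(coordination) cannot be an
artifact of encoding movement direction alone.

### Numerical implementation

Cross-validation and generic prediction run entirely on per-trial
sufficient statistics (XᵀX, Xᵀy, column/target sums and target energies):
each fold needs one eigendecomposition of the pooled centered Gram matrix,
after which the whole λ grid and all held-out correlations cost only
matrix-vector work, and reduced models reuse the full model's Gram blocks
by index subsetting. This makes the λ sweep essentially free relative to
the Gram products and is exactly equivalent (to solver precision) to the
naive per-λ ridge solve, which the tests verify against an independently
coded normal-equations oracle. Degenerate systems at λ = 0 fall back to the
minimum-norm solution with a warning. Lagged designs zero-pad trial edges
so every trial keeps its length.

## Statistics

Relevant electrodes per feature are those with a grand-average Δr > 0
across the conditions where the process is expected (all four for music and
self movement; the two visual-contact conditions for partner movement and
coordination); an empty selection falls back to the best channel with a
warning. Per-participant Δr averaged over those electrodes enters a 2×2
repeated-measures ANOVA (visual contact × musical input). With 1-df
effects, each F is computed as the squared paired t of the corresponding
within-subject contrast — the tests verify this identity and agreement with
an independent ANOVA implementation — and p values are Bonferroni-corrected
(×4) across features. A significant interaction triggers follow-up music
contrasts within each vision level (difference, SE, p), with no further
correction inside the family.

ERP analyses epoch the EEG (−250..+300 ms) at feature events: local maxima
of spectral flux (keeping only peaks 3 SD above the trial mean), velocity
peaks, and coordination sign flips (attributed to whichever dancer's
velocity changes sign within ±1 sample; "both" events are excluded from
self/other contrasts). External-stimulus epochs use a prestimulus baseline,
internally initiated ones the whole-epoch mean. Group contrasts
(lowest/highest 20% amplitude splits; to-in-phase vs to-anti-phase) are
tested per condition at the process channel with a paired cluster-based
permutation test: pointwise paired t thresholded at two-sided p < 0.05 for
n−1 df, cluster mass = summed t over a contiguous same-sign run, null
distribution = max |mass| over sign flips of the participant differences,
corrected p = (1 + #{null ≥ obs}) / (1 + n_perm), 1000 permutations. The
implementation matches an independent single-sample cluster-permutation
implementation on the same data, and its p values are uniform under null
simulations.

## The simulator

A synthetic session holds two dancers, 32 trials (4 blocks × 2 trials per
cell of the 2×2 design), 40 s per trial at 100 Hz over the 64-channel
extended 10-10 layout (positions from the standard BioSemi montage).

**Forward model.** EEG = Σ_k topography_k ⊗ (kernel_k ∗ regressor_k) +
noise. Ground-truth kernels are sums of 30 ms FWHM Gaussian lobes at the
canonical latencies of the responses the analysis should find: music
(frontal) +60/−120/+200 ms with +/−/+ polarity; self movement (bilateral
central) −100/0/+80 ms (−/+/−); partner movement (occipital) +70/+160 ms
(+/−); coordination (occipital) −180/−90/+30/+160 ms (−/+/−/+). EOG/EMG
leakage is a zero-lag single-sample impulse 100× the neural amplitude with
topographies at the lateral frontal poles, temporal sites, and the
occipital periphery. Regressors are scaled to unit SD before convolution so
that kernel amplitudes are comparable across processes — matching the
empirical observation that the per-event responses of the different
processes have similar size. Condition gating: the partner kernel is ×0
without visual contact; the coordination kernel is ×1 with visual contact
and shared music, ×0.25 with visual contact and different music, ×0
without visual contact. The gating factors are configuration, not
constants: they encode the qualitative condition pattern, not measured
effect sizes.

**Dancer dynamics.** Each dancer's bounce velocity is a near-sinusoid at
the beat rate with mean-reverting Ornstein–Uhlenbeck phase error (SD 0.5
rad, timescale 0.5 s — sloppy-but-entrained lay-dancer timing, tens of ms
of asynchrony) and slow lognormal amplitude modulation. With visual
contact, reset events every 2–6 s alternately pull dancer B toward relative
phase 0 and π, guaranteeing both in-phase and anti-phase episodes and at
least one coordination transition per 10 s on average. This phase-reset
model is a stand-in for unknown real coupling dynamics: it produces the
event structure the coordination analyses need, not a behavioral claim.
In the different-music condition the two tempos differ by exactly 8.5%.
The phase jitter also serves an estimation purpose: perfectly periodic
regressors would make the lagged design rank-deficient (kernels identifiable
only up to period-shifted ghosts); the jitter broadens the spectral lines
enough that cross-validated ridge resolves the true latencies.

**Music events.** An impulse train at the inter-beat interval with i.i.d.
lognormal amplitudes (σ = 0.5), giving the right-skewed loudness
distribution a 20% loud/soft split needs.

**Full-body kinematics.** 22 markers × xyz = 66 dimensions, generated from
15 movement primitives on a random orthonormal basis. One primitive is the
bounce — uniform vertical displacement of all markers whose score is the
integral of the bounce velocity — carrying 1% of the signal variance (the
bounce's share in real dance kinematics); the others are 0.2–5 Hz
band-limited noise with geometrically decaying variances (ratio 0.7), and
isotropic sensor noise contributes 4% of total variance. PCA of a
session-length record (320 s; the analysis pools all trials) recovers the
bounce score at |r| ≥ 0.95 and places it around the 10th component; with
default noise the top-15 components retain ≈97% of the variance. Single-
trial records (40 s) are too short: neighbouring eigenvalues are then close
enough that sampling fluctuations mix the bounce with a noise primitive.

**Noise.** Pink (1/f) background mixed through a dozen random smooth scalp
topographies plus a 10% white sensor floor, scaled so that the channel-mean
neural signal variance over noise variance equals the configured SNR
(default 0.25). The spatial mixing matters: fully channel-independent noise
would make the neighbour-correlation bad-channel criterion (< 0.8) flag
every clean channel, which no real recording does. The simulator emits the
1–8 Hz-band analogue of cleaned EEG directly, so the synthetic validation
runs skip the band-pass/re-reference stage (applying an 8 Hz low-pass to
data whose ground-truth kernels contain 30 ms lobes would smear the very
latencies being tested); the preprocessing operators are validated
separately on constructed inputs.

All randomness descends from a single seed through spawned seed sequences:
sessions are bit-reproducible and cohorts use independent per-dyad streams.

## Validation studies and their scale

The kernel-recovery study simulates 20 participants at SNR 0.25, fits the
full pipeline per participant and condition, and reads the salient
deflections (local extrema with prominence ≥ 20% of the series' absolute
maximum) off the grand-average TRFs at the process channels. All injected
latencies are recovered exactly at the 10 ms sample resolution; the run
takes ~2 minutes on one CPU.

The gating-specificity study uses 20 independent cohorts of 6 participants
(4 trials per condition, 40 s) and compares channel-mean Δr where kernels
are gated off (no-vision conditions) against where they are active. The
gated-on contributions are unambiguous (partner: ≈ +0.023 at Oz;
coordination: ≈ +0.036 at Oz in the vision+same-music condition). The
gated-off Δr values show a small systematic negative offset (partner:
≈ −0.001 channel-mean, ≈ −1×10⁻⁴ at Oz; coordination: ≈ −0.0005): with few
participants, the full model's generic weights for an inert regressor are
pure noise, and that noise lowers the full model's prediction below the
reduced model's. The offset scales as 1/((N−1)·n_samples) and is negligible
at realistic cohort sizes, but at this study size it is detectably non-zero
against the across-seed standard error — a finite-sample property of nested
generic-model comparisons worth knowing when interpreting small-N Δr maps,
and the one synthetic check that does not pass at desk scale.

Null calibration runs 200 null simulations each for the ANOVA and the
cluster permutation test (Kolmogorov–Smirnov uniformity at α = 0.01), and
the ERP–TRF correspondence study verifies that impulse-locked grand-average
ERPs correlate r ≥ 0.9 with the injected kernel when events are a full
second apart.

## What the synthetic validations do not show

The simulator's linear forward model matches the analysis model by
construction, so recovery results certify the estimation machinery — not
that real EEG is linear in these features. Real data add nonstationarity,
ASR/ICA preprocessing residue, imperfect marker tracking, volume-conduction
structure richer than Gaussian-bump topographies, and behavioral coupling
dynamics unlike the phase-reset stand-in. Artifact leakage here is exactly
zero-lag and exactly 100×; real leakage varies. Condition gating factors
(1/0.25/0) are stipulated, so condition contrasts on synthetic data test
sensitivity, not effect sizes.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| fs | 100 Hz | analysis rate for EEG and regressors |
| lag window | −250..+300 ms | 56 lags; pre-onset half captures premotor activity |
| λ grid | {0} ∪ {10⁻⁴…10⁸} | ridge CV grid, 14 values |
| trial duration | 40 s | song length |
| trials | 32 = 4 blocks × 8 | 8 per condition cell |
| snr | 0.25 | channel-mean neural variance / noise variance |
| artifact gain | 100 | EOG/EMG impulse amplitude vs neural lobes |
| coordination gains | 1 / 0.25 / 0 | vision+same / vision+different / no-vision |
| tempo difference | 8.5% | different-music condition, exact |
| lobe FWHM | 30 ms | separable at 100 Hz sampling |
| phase jitter | 0.5 rad, τ = 0.5 s | dancer timing error (OU) |
| bounce variance share | 1% | rank ≈ 10 among 15 primitives |
| kinematic noise | 4% | isotropic sensor noise fraction |
| cluster permutations | 1000 | sign-flip max-mass null |
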