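# dyadtrf

EEG encoding models for dyadic dance: multivariate temporal response
functions (mTRFs) that decompose the EEG of two people dancing together
into the unique contributions of music acoustics, self-generated movement,
the partner's movement, social coordination, and ocular/muscular artifact
leakage — plus event-locked ERP analyses that anchor the recovered
responses in classical physiology, and a ground-truth dyad simulator that
makes the whole pipeline testable end to end.

It is written for researchers analyzing mobile-EEG experiments on
naturalistic, interactive behavior, where several neural processes and
large movement artifacts overlap in the same recording and simple
event-averaging cannot separate them.

## The model

Each EEG channel is modeled as a sum of lagged linear responses to feature
time series:

    y_c(t) = Σ_k Σ_τ w_{k,c}(τ) · x_k(t − τ) + b_c + ε_c(t),   τ ∈ [−250, +300] ms

with features x_k: spectral flux of the music (gammatone filter bank, 128
log-spaced bands, 100–8000 Hz), bounce velocity magnitude of the dancer and
of the partner, the coordination sign (product of the two signed bounce
velocities: +1 in-phase, −1 anti-phase), and EOG/EMG controls. Weights are
fit by ridge regression (intercept unpenalized), with λ selected per trial
by leave-one-trial-out cross-validation over {0, 10⁻⁴, …, 10⁸}. Prediction
is *generic*: each participant's EEG is predicted from the average TRF of
all other participants, and the unique contribution of feature k is

    Δr_k = r(full model) − r(model without x_k)

per electrode, participant, and condition of the 2×2 design
(visual contact yes/no × same/different music). Condition effects on Δr are
tested with a 2×2 repeated-measures ANOVA (Bonferroni ×4), and ERP
contrasts (loud/soft, fast/slow, to-in-phase/to-anti-phase) use paired
cluster-based permutation tests (1000 sign-flip permutations).

The simulator generates complete dyadic sessions from known kernels —
canonical auditory P50-N100-P200, central movement-related −100/0/+80 ms,
occipital visual +70/+160 ms, and a quadriphasic occipital coordination
response — with condition gating, 100× zero-lag artifact leakage, and pink
spatially-correlated background noise, so every downstream estimate can be
checked against ground truth. See `docs/methods.md` for details.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (three dyads, 2×2 design) into `results/run/`:

```bash
python analysis/01_simulate.py      # sessions + trial inventory
python analysis/02_features.py      # standardization + movement primitives
python analysis/03_fit_trf.py       # mTRF fits and delta r partitioning
python analysis/04_stats.py         # electrode selection + 2x2 RM-ANOVA
python analysis/05_erp.py           # ERP contrasts + cluster permutation
```

`02_features.py` prints, for the default seed:

```
top-15 principal movements explain 96.9% of kinematic variance
bounce recovered as PM11 (1.0% of variance, |r| = 0.978 with the injected score)
```

i.e. PCA of the 66-dimensional posture series retains >95% of the variance
in 15 movement primitives and finds the injected bounce — the vertical
oscillation that drives most movement-related EEG — as a ~1%-variance
component, as in real dance kinematics. `03_fit_trf.py` then reports the
recovered grand-average TRF deflections against the injected ground truth:

```
music_flux      +60 (+), +120 (-), +200 (+)           injected: +60 (+), +120 (-), +200 (+) ms
self_velocity   -100 (-), +0 (+), +80 (-)             injected: -100 (-), 0 (+), +80 (-) ms
other_velocity  +70 (+), +160 (-)                     injected: +70 (+), +160 (-) ms
coordination    -180 (-), -90 (+), +30 (-), +160 (+)  injected: -180 (-), -90 (+), +30 (-), +160 (+) ms
```

every salient deflection lands on its injected latency. `04_stats.py`
prints the condition statistics; on this cohort the coordination Δr shows
main effects of vision (F(1,5) = 1083, p_bonf < 0.001) and music
(F(1,5) = 92, p_bonf < 0.001) with a vision × music interaction
(F(1,5) = 74, p_bonf = 0.001), and the partner-movement Δr a vision main
effect (F(1,5) = 51, p_bonf = 0.003) — the simulated gating pattern, found
by the pipeline. `05_erp.py` lists the ERP clusters; to-in-phase vs
to-anti-phase differences at Oz survive correction only in the
vision + same-music condition, mirroring the Δr result.

A command-line interface wraps the same stages
(`dyadtrf simulate|features|preprocess|fit|erp|stats|all --config cfg.yaml
--seed N --out DIR`; exit codes: 0 ok, 2 config error, 3 data error), and
`dyadtrf.io.read_eeg` reads EDF/BDF, delimited text, and the HDF5 session
container.

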