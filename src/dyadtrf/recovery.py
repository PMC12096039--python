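"""Ground-truth recovery studies on synthetic cohorts.

These are the workhorse validation analyses: simulate a cohort of dyads
whose EEG was generated from known kernels, run the full encoding pipeline,
and read out (a) the latencies of the salient deflections of the recovered
grand-average TRFs, (b) the gating specificity of the unique contributions
(delta r), and (c) the variance captured by the movement-primitive PCA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from dyadtrf import features, partition
from dyadtrf.simulate import SimConfig, make_cohort, make_fullbody
from dyadtrf.trf import peak_latencies

#: channels where each process is read out
READOUT_CHANNELS = {
    "music_flux": ["Fz"],
    "self_velocity": ["C3", "C4"],
    "other_velocity": ["Oz"],
    "coordination": ["Oz"],
}


def _channel_mean(weights, names, channel_names, regressor, channels):
    ri = names.index(regressor)
    idx = [channel_names.index(c) for c in channels]
    return weights[ri][:, idx].mean(axis=1)


def recovered_latencies(result: partition.CohortResult) -> dict[str, float]:
    """Salient-deflection latencies (ms) of the grand-average TRFs.

    Music: last positive deflection at Fz (all conditions). Self: earliest
    pre-onset negative deflection on the C3/C4 average (all conditions).
    Other: first post-onset positive deflection at Oz (visual-contact
    conditions). Coordination: last positive deflection at Oz
    (visual contact + same music).
    """
    win = result.window
    all_conds = sorted(result.mean_weights)
    vis_conds = [c for c in all_conds if "vision=yes" in c]

    w_all = result.mean_weights_over(all_conds)
    w_vis = result.mean_weights_over(vis_conds)
    w_vs = result.mean_weights["vision=yes/music=same"]

    out: dict[str, float] = {}
    music = _channel_mean(w_all, result.regressor_names, result.channel_names,
                          "music_flux", READOUT_CHANNELS["music_flux"])
    pos = peak_latencies(music, win, "positive")
    out["music_last_positive_ms"] = float(pos.max()) if pos.size else np.nan

    selfw = _channel_mean(w_all, result.regressor_names, result.channel_names,
                          "self_velocity", READOUT_CHANNELS["self_velocity"])
    neg = peak_latencies(selfw, win, "negative")
    neg = neg[neg < 0]
    out["self_premotor_negative_ms"] = float(neg.min()) if neg.size else np.nan

    other = _channel_mean(w_vis, result.regressor_names, result.channel_names,
                          "other_velocity", READOUT_CHANNELS["other_velocity"])
    pos = peak_latencies(other, win, "positive")
    pos = pos[pos > 0]
    out["other_first_positive_ms"] = float(pos.min()) if pos.size else np.nan

    coord = _channel_mean(w_vs, result.regressor_names, result.channel_names,
                          "coordination", READOUT_CHANNELS["coordination"])
    pos = peak_latencies(coord, win, "positive")
    out["coordination_last_positive_ms"] = float(pos.max()) if pos.size \
        else np.nan
    return out


def kernel_recovery_run(n_participants: int = 20, seed: int = 1,
                        config: SimConfig | None = None,
                        ) -> tuple[dict[str, float], partition.CohortResult]:
    """Simulate a default cohort, fit the full mTRF model, read latencies."""
    if n_participants % 2:
        raise ValueError("participants come in dyads; use an even count")
    cohort = make_cohort(n_participants // 2, config or SimConfig(),
                         seed=seed)
    trials = partition.cohort_trials(cohort)
    result = partition.fit_cohort(trials)
    return recovered_latencies(result), result


def specificity_run(n_seeds: int = 20, seed: int = 0,
                    n_participants: int = 6, n_blocks: int = 2,
                    duration_s: float = 40.0) -> pd.DataFrame:
    """Per-seed channel-mean delta r for gated-off vs gated-on contrasts.

    Each seed simulates an independent cohort and partitions variance with
    reduced models dropping the partner-movement and coordination
    regressors. Returns one row per seed with the channel-averaged delta r
    in the no-vision conditions (where both kernels are gated off) and in
    the conditions where each kernel is active.
    """
    children = SeedSequence(seed).spawn(n_seeds)
    config = SimConfig(duration_s=duration_s, n_blocks=n_blocks)
    rows = []
    for i, child in enumerate(children):
        cohort = make_cohort(n_participants // 2, config,
                             seed=int(child.generate_state(1)[0]))
        trials = partition.cohort_trials(cohort)
        res = partition.fit_cohort(trials, reduced={
            "other_velocity": ["other_velocity"],
            "coordination": ["coordination"],
        })
        dr = res.delta_r
        no_vis = dr.condition.str.contains("vision=no")
        vis = dr.condition.str.contains("vision=yes")
        vis_same = dr.condition == "vision=yes/music=same"
        rows.append({
            "seed_index": i,
            "other_off": dr[no_vis & (dr.regressor == "other_velocity")
                            ]["delta_r"].mean(),
            "coordination_off": dr[no_vis & (dr.regressor == "coordination")
                                   ]["delta_r"].mean(),
            "other_on": dr[vis & (dr.regressor == "other_velocity")
                           ]["delta_r"].mean(),
            "coordination_on": dr[vis_same & (dr.regressor == "coordination")
                                  ]["delta_r"].mean(),
        })
    return pd.DataFrame(rows)


def erp_correspondence_run(seed: int = 0, n_trials: int = 10,
                           duration_s: float = 40.0, snr: float = 5.0,
                           tempo_bpm: float = 60.0) -> float:
    """Correlation between an impulse-locked grand-average ERP and its kernel.

    Simulates trials whose EEG contains only the music kernel driven by a
    sparse event train (beats a full second apart, so epochs never overlap),
    epochs the EEG at the detected events with prestimulus baseline, and
    correlates the grand-average ERP at the frontal readout channel with
    the injected kernel over the lag window.
    """
    from dyadtrf import erp, layout
    from dyadtrf.kernels import default_kernel_presets
    from dyadtrf.simulate import ConditionLabel, make_event_train, \
        simulate_trial
    from dyadtrf.trf import LagWindow

    window = LagWindow()
    presets = default_kernel_presets()
    spec = presets["music_flux"]
    fz = layout.channel_names().index("Fz")
    children = SeedSequence(seed).spawn(n_trials)
    epochs = []
    for child in children:
        s1, s2 = (int(c.generate_state(1)[0]) for c in child.spawn(2))
        train = make_event_train(tempo_bpm, duration_s, s1)
        trial = simulate_trial({"music_flux": train},
                               {"music_flux": spec},
                               ConditionLabel("yes", "same"), snr, s2)
        onsets = erp.detect_onsets(trial.regressors["music_flux"], 100.0)
        es = erp.epoch(trial.eeg, onsets, window, "prestim")
        if es.epochs.size:
            epochs.append(es.epochs[:, :, fz])
    grand = np.vstack(epochs).mean(axis=0)
    kernel = spec.sample(window.lags, 100.0) * spec.topography[fz]
    return float(np.corrcoef(grand, kernel)[0, 1])


def pm_variance_run(seed: int = 0, duration_s: float = 320.0,
                    config: SimConfig | None = None) -> float:
    """Cumulative variance (%) of the top-15 principal movements.

    Generates one session's worth of bounce (the PCA pools all trials, so
    the default length is eight 40 s trials), expands it to full-body
    kinematics with the default 15-primitive model and sensor-noise
    fraction, and runs the movement-primitive PCA.
    """
    config = config or SimConfig()
    ss = SeedSequence(seed).spawn(2)
    train_seed, body_seed = (int(c.generate_state(1)[0]) for c in ss)
    from dyadtrf.simulate import make_bounce_pair

    v, _ = make_bounce_pair(120.0, 120.0, "uncoupled", duration_s,
                            train_seed, config.fs,
                            phase_jitter_rad=config.phase_jitter_rad,
                            amp_jitter=config.amp_jitter)
    body = make_fullbody(v, n_primitives=config.n_primitives,
                         noise_frac=config.fullbody_noise_frac,
                         seed=body_seed, fs=config.fs,
                         bounce_var_frac=config.bounce_var_frac,
                         primitive_decay=config.primitive_decay)
    pms = features.pca_movements(body.postures, n_keep=15, fs=config.fs)
    return float(pms.variance_explained[:15].sum() * 100.0)
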