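"""Cohort-level mTRF fitting and nested-model variance partitioning.

Drives the full/reduced-model comparisons: per participant and condition,
regressors are standardized to the participant-level SD, subject TRFs are
fit with per-trial cross-validated lambda, and each participant's EEG is
predicted from the other participants' average TRF (generic prediction).
Removing one regressor from the model and refitting yields its unique
contribution delta r per electrode. Also hosts the body-part-specific
models and the velocity-sign control for social coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dyadtrf import features, layout
from dyadtrf.kernels import ALL_REGRESSORS
from dyadtrf.simulate import DyadSession, TrialRecord
from dyadtrf.trf import (
    LAMBDA_GRID,
    LagWindow,
    cv_subject_fit,
    delta_r,
    feature_indices,
    generic_predict,
    pool_trials,
    trial_data,
)

#: markers of the body-part-specific full model (hands/feet/head analysis)
BODYPART_MARKERS = (
    "LB Head", "LF Head", "RF Head", "RB Head", "Sternum", "L Shoulder",
    "R Shoulder", "L Hand", "R Hand", "Pelvis", "L Hip", "R Hip", "L Knee",
    "L Foot", "R Knee", "R Foot",
)
BODYPART_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "L Hand": ("L Hand",),
    "R Hand": ("R Hand",),
    "L Foot": ("L Foot",),
    "R Foot": ("R Foot",),
    "head": ("LB Head", "LF Head", "RF Head", "RB Head"),
}


@dataclass
class CohortResult:
    """Cohort fit: grand-average full-model weights and optional delta-r table.

    ``mean_weights`` maps condition key -> (n_regressors, n_lags, n_channels)
    weights averaged over participants; ``delta_r`` is a long table with
    columns participant, condition, regressor, channel, r_full, r_reduced,
    delta_r (one row per excluded regressor and electrode).
    """

    mean_weights: dict[str, np.ndarray]
    regressor_names: list[str]
    window: LagWindow
    channel_names: list[str]
    delta_r: pd.DataFrame | None = None
    lambdas: pd.DataFrame | None = None

    def mean_weights_over(self, condition_keys: list[str]) -> np.ndarray:
        """Average the grand-average weights over a subset of conditions."""
        return np.mean([self.mean_weights[k] for k in condition_keys], axis=0)


def cohort_trials(sessions: list[DyadSession]) -> dict[str, list[TrialRecord]]:
    """Flatten dyad sessions into participant -> trials with unique ids."""
    out: dict[str, list[TrialRecord]] = {}
    for d, session in enumerate(sessions):
        for pid, trials in session.trials.items():
            out[f"d{d}_{pid}"] = trials
    return out


def with_velocity_signs(trials: list[TrialRecord]) -> list[TrialRecord]:
    """Add velocity_sign_self/other regressors from the signed bounce sources."""
    out = []
    for t in trials:
        regs = dict(t.regressors)
        regs["velocity_sign_self"] = features.velocity_sign(t.sources["v_self"])
        regs["velocity_sign_other"] = features.velocity_sign(t.sources["v_other"])
        out.append(TrialRecord(eeg=t.eeg, regressors=regs, condition=t.condition,
                               fs=t.fs, sources=t.sources))
    return out


def _standardized(trials_by_participant, names):
    raw = {pid: [{n: t.regressors[n] for n in names} for t in trials]
           for pid, trials in trials_by_participant.items()}
    return features.standardize(raw).series


def _condition_groups(trials: list[TrialRecord], pool: bool) -> dict[str, list[int]]:
    if pool:
        return {"all": list(range(len(trials)))}
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        groups.setdefault(t.condition.key, []).append(i)
    return groups


def fit_cohort(trials_by_participant: dict[str, list[TrialRecord]],
               regressor_names: list[str] | None = None,
               window: LagWindow | None = None,
               grid: tuple[float, ...] = LAMBDA_GRID,
               reduced: dict[str, list[str]] | None = None,
               pool_conditions: bool = False,
               channel_names: list[str] | None = None) -> CohortResult:
    """Fit subject TRFs across a cohort; optionally partition variance.

    ``reduced`` maps a model id to the list of regressors excluded from that
    reduced model; when given, generic predictions are computed for the full
    and each reduced model and their difference (delta r) is tabulated per
    electrode, participant, and condition.
    """
    if len(trials_by_participant) < 2:
        raise ValueError("generic prediction needs at least two participants")
    names = list(regressor_names or ALL_REGRESSORS)
    window = window or LagWindow()
    channel_names = channel_names or layout.channel_names()
    reduced = reduced or {}
    for model_id, excluded in reduced.items():
        for name in excluded:
            if name not in names:
                raise ValueError(f"model {model_id!r} excludes unknown "
                                 f"regressor {name!r}")
    model_keeps = {"full": np.arange(len(names) * window.n_lags)}
    for model_id, excluded in reduced.items():
        keep = [n for n in names if n not in excluded]
        model_keeps[model_id] = feature_indices(names, keep, window)

    standardized = _standardized(trials_by_participant, names)
    pids = list(trials_by_participant)

    # pass 1: subject TRFs per participant x condition x model; pooled
    # per-condition sufficient statistics are kept for the prediction pass
    subject_models: dict[tuple[str, str, str], object] = {}
    pooled_stats: dict[tuple[str, str], object] = {}
    weight_sums: dict[str, np.ndarray] = {}
    weight_counts: dict[str, int] = {}
    lam_rows = []
    for pid in pids:
        trials = trials_by_participant[pid]
        groups = _condition_groups(trials, pool_conditions)
        for cond_key, idxs in groups.items():
            data = [trial_data(standardized[pid][i], trials[i].eeg, window,
                               keep_data=False) for i in idxs]
            if reduced:
                pooled_stats[(pid, cond_key)] = pool_trials(data)
            for model_id, keep in model_keeps.items():
                mdata = data if model_id == "full" else [d.subset(keep)
                                                         for d in data]
                model, lams = cv_subject_fit(mdata, grid)
                subject_models[(pid, cond_key, model_id)] = model
                lam_rows.append((pid, cond_key, model_id,
                                 float(np.median(lams))))
            full = subject_models[(pid, cond_key, "full")]
            w = full.coef.reshape(len(names), window.n_lags, -1)
            if cond_key not in weight_sums:
                weight_sums[cond_key] = np.zeros_like(w)
                weight_counts[cond_key] = 0
            weight_sums[cond_key] += w
            weight_counts[cond_key] += 1

    mean_weights = {k: weight_sums[k] / weight_counts[k] for k in weight_sums}
    lambdas = pd.DataFrame(lam_rows, columns=["participant", "condition",
                                              "model", "median_lambda"])

    if not reduced:
        return CohortResult(mean_weights=mean_weights, regressor_names=names,
                            window=window, channel_names=channel_names,
                            lambdas=lambdas)

    # pass 2: generic predictions and delta r
    rows = []
    for pid in pids:
        trials = trials_by_participant[pid]
        groups = _condition_groups(trials, pool_conditions)
        for cond_key, idxs in groups.items():
            pooled = pooled_stats[(pid, cond_key)]
            preds = {}
            for model_id, keep in model_keeps.items():
                others = [subject_models[(q, cond_key, model_id)]
                          for q in pids if q != pid]
                mdata = pooled if model_id == "full" else pooled.subset(keep)
                preds[model_id] = generic_predict(
                    others, [mdata], model_id=model_id, participant=pid,
                    condition=cond_key)
            for model_id in reduced:
                dr = delta_r(preds["full"], preds[model_id])
                for ci, ch in enumerate(channel_names):
                    rows.append((pid, cond_key, model_id, ch,
                                 preds["full"].r[ci], preds[model_id].r[ci],
                                 dr[ci]))
    table = pd.DataFrame(rows, columns=["participant", "condition",
                                        "regressor", "channel", "r_full",
                                        "r_reduced", "delta_r"])
    return CohortResult(mean_weights=mean_weights, regressor_names=names,
                        window=window, channel_names=channel_names,
                        delta_r=table, lambdas=lambdas)


def unique_contributions(trials_by_participant,
                         excluded: dict[str, list[str]] | None = None,
                         **kwargs) -> CohortResult:
    """Standard seven-variable partitioning: one reduced model per regressor.

    Default reduced models drop, in turn: spectral flux (music), self bounce
    velocity, other bounce velocity, coordination, EOG (both channels),
    cheek EMG, and neck EMG.
    """
    if excluded is None:
        excluded = {
            "music_flux": ["music_flux"],
            "self_velocity": ["self_velocity"],
            "other_velocity": ["other_velocity"],
            "coordination": ["coordination"],
            "eog": ["eog_left", "eog_right"],
            "emg_cheek": ["emg_cheek"],
            "emg_neck": ["emg_neck"],
        }
    return fit_cohort(trials_by_participant, reduced=excluded, **kwargs)


def bodypart_models(trials_by_participant,
                    exclusions: dict[str, tuple[str, ...]] | None = None,
                    **kwargs) -> CohortResult:
    """Body-part-specific partitioning: 16 marker velocities + neck EMG.

    The full model uses the 16 major body markers' velocity magnitudes plus
    the neck EMG control; five reduced models drop the left/right hand,
    left/right foot, or all four head markers. Conditions are pooled, as in
    the body-part analysis.
    """
    exclusions = exclusions or BODYPART_EXCLUSIONS
    names = list(BODYPART_MARKERS) + ["emg_neck"]
    some_trials = next(iter(trials_by_participant.values()))
    missing = [m for m in names if m not in some_trials[0].regressors]
    if missing:
        raise ValueError(f"missing marker regressors: {missing}")
    kwargs.setdefault("pool_conditions", True)
    return fit_cohort(trials_by_participant, regressor_names=names,
                      reduced={k: list(v) for k, v in exclusions.items()},
                      **kwargs)


def coordination_control(trials_by_participant, **kwargs) -> CohortResult:
    """Coordination delta r against a model that also has velocity signs.

    The comprehensive model holds music, self- and other-velocity
    magnitudes, coordination, and the velocity-sign series of both dancers
    (no artifact controls); the reduced model drops coordination only.
    """
    trials_by_participant = {pid: with_velocity_signs(trials)
                             for pid, trials in trials_by_participant.items()}
    names = ["music_flux", "self_velocity", "other_velocity", "coordination",
             "velocity_sign_self", "velocity_sign_other"]
    return fit_cohort(trials_by_participant, regressor_names=names,
                      reduced={"coordination": ["coordination"]}, **kwargs)
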