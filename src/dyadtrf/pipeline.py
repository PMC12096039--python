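"""Pipeline orchestration: staged runs with manifests and reproducibility.

Stages: simulate -> features -> (preprocess) -> fit -> erp -> stats. Each
stage writes its outputs plus a manifest entry (config hash, seed, output
hashes) into one run directory; rerunning with the same config and seed
reproduces the outputs. Inputs are never mutated in place.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dyadtrf import erp as erp_mod
from dyadtrf import features, layout, partition, preprocess, stats
from dyadtrf.io import ConfigError, DataError, RunConfig, array_hash, \
    read_session, write_session
from dyadtrf.simulate import DyadSession, make_cohort, make_fullbody
from dyadtrf.trf import LagWindow

STAGE_ORDER = ("simulate", "features", "preprocess", "fit", "erp", "stats")
STAGE_DEPS = {
    "simulate": (),
    "features": ("simulate",),
    "preprocess": ("simulate",),
    "fit": ("features",),
    "erp": ("simulate",),
    "stats": ("fit",),
}


def _manifest_path(run_dir: Path) -> Path:
    return run_dir / "manifest.json"


def _load_manifest(run_dir: Path) -> dict:
    p = _manifest_path(run_dir)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(run_dir: Path, manifest: dict) -> None:
    _manifest_path(run_dir).write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.hash()
    df["seed"] = config.seed
    return df


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 outputs: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    stamped = _stamp(df, config)
    stamped.to_csv(path, index=False)
    outputs[str(path.name)] = array_hash(
        np.frombuffer(path.read_bytes(), dtype=np.uint8))


def run_pipeline(config: RunConfig, stages=None, out_dir=None) -> Path:
    """Run the requested stages into a run directory; returns its path."""
    stages = list(stages or STAGE_ORDER)
    if "preprocess" in stages and not config.apply_preprocess \
            and stages == list(STAGE_ORDER):
        stages.remove("preprocess")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    run_dir = Path(out_dir or f"run_{config.hash()}_{config.seed}")
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(run_dir)
    manifest["config_hash"] = config.hash()
    manifest["seed"] = config.seed
    manifest["config"] = config.to_dict()

    for stage in sorted(stages, key=STAGE_ORDER.index):
        done = set(manifest["stages"]) | set(stages[:stages.index(stage)])
        missing = [d for d in STAGE_DEPS[stage] if d not in done]
        if missing:
            raise ConfigError(
                f"stage {stage!r} requires {missing} to run first")
        outputs: dict[str, str] = {}
        _STAGE_FUNCS[stage](config, run_dir, outputs)
        manifest["stages"][stage] = {"outputs": outputs}
        _save_manifest(run_dir, manifest)
    return run_dir


def _sessions_path(run_dir: Path, i: int) -> Path:
    return run_dir / f"session_{i:02d}.h5"


def _load_cohort(config: RunConfig, run_dir: Path) -> list[DyadSession]:
    paths = sorted(run_dir.glob("session_clean_*.h5")) or \
        sorted(run_dir.glob("session_*.h5"))
    if not paths:
        raise DataError("no session containers in run directory")
    return [read_session(p) for p in paths]


def _stage_simulate(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    cohort = make_cohort(config.n_dyads, config.sim, seed=config.seed)
    rows = []
    for i, session in enumerate(cohort):
        path = _sessions_path(run_dir, i)
        write_session(path, session)
        outputs[path.name] = array_hash(
            np.concatenate([t.eeg.ravel() for t in session.trials["p0"]]))
        for pid, trials in session.trials.items():
            for j, t in enumerate(trials):
                rows.append((i, pid, j, t.condition.vision, t.condition.music,
                             t.n_samples, t.fs))
    table = pd.DataFrame(rows, columns=["dyad", "participant", "trial",
                                        "vision", "music", "n_samples", "fs"])
    _write_table(table, run_dir / "trials.csv", config, outputs)


def _stage_features(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    cohort = _load_cohort(config, run_dir)
    trials = partition.cohort_trials(cohort)
    std = features.standardize({
        pid: [dict(t.regressors) for t in tl] for pid, tl in trials.items()})
    rows = [(pid, name, sd) for pid, scales in std.scale.items()
            for name, sd in scales.items()]
    _write_table(pd.DataFrame(rows, columns=["participant", "series", "sd"]),
                 run_dir / "features" / "regressor_scales.csv", config,
                 outputs)
    # movement-primitive decomposition of one session's full-body kinematics
    session = cohort[0]
    v = session.trials["p0"][0].sources.get("v_self")
    if v is not None:
        body = make_fullbody(v, n_primitives=config.sim.n_primitives,
                             noise_frac=config.sim.fullbody_noise_frac,
                             seed=config.seed, fs=config.sim.fs,
                             bounce_var_frac=config.sim.bounce_var_frac,
                             primitive_decay=config.sim.primitive_decay)
        pms = features.pca_movements(body.postures, n_keep=min(
            config.sim.n_primitives, 15), fs=config.sim.fs)
        _write_table(pd.DataFrame({
            "component": np.arange(1, len(pms.variance_explained) + 1),
            "variance_explained": pms.variance_explained,
        }), run_dir / "features" / "pm_variance.csv", config, outputs)


def _stage_preprocess(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    names = layout.channel_names()
    pos = layout.channel_positions()
    for i, path in enumerate(sorted(run_dir.glob("session_??.h5"))):
        session = read_session(path)
        for trials in session.trials.values():
            for t in trials:
                quality = preprocess.flag_bad_channels(t.eeg, t.fs, names)
                bad = {k for k, q in enumerate(quality) if q.bad}
                eeg = preprocess.rereference_car(t.eeg, bad)
                if bad:
                    eeg = preprocess.interpolate_bad(eeg, bad, names, pos)
                t.eeg = eeg
        out = run_dir / f"session_clean_{i:02d}.h5"
        write_session(out, session)
        outputs[out.name] = array_hash(
            np.concatenate([t.eeg.ravel() for t in session.trials["p0"]]))


def _stage_fit(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    cohort = _load_cohort(config, run_dir)
    trials = partition.cohort_trials(cohort)
    window = LagWindow(fs=config.sim.fs)
    result = partition.unique_contributions(trials, window=window)
    _write_table(result.delta_r, run_dir / "fit" / "delta_r.csv", config,
                 outputs)
    _write_table(result.lambdas, run_dir / "fit" / "lambdas.csv", config,
                 outputs)
    rows = []
    for cond, w in result.mean_weights.items():
        for reg, channels in config.channels_of_interest.items():
            ri = result.regressor_names.index(reg)
            idx = [result.channel_names.index(c) for c in channels]
            series = w[ri][:, idx].mean(axis=1)
            for t_ms, value in zip(window.lag_times_ms, series):
                rows.append((cond, reg, "+".join(channels), t_ms, value))
    _write_table(pd.DataFrame(rows, columns=["condition", "regressor",
                                             "channels", "lag_ms", "weight"]),
                 run_dir / "fit" / "trf_weights.csv", config, outputs)


def _participant_group_means(trials, event_getter, channel_idx, window,
                             baseline_mode, split):
    """Per-condition, per-participant mean epochs for a two-group contrast."""
    by_cond: dict[str, dict[str, list]] = {}
    for pid, tl in trials.items():
        per_cond: dict[str, list] = {}
        for t in tl:
            per_cond.setdefault(t.condition.key, []).append(t)
        for cond, group in per_cond.items():
            epochs, amps = [], []
            for t in group:
                onsets = event_getter(t)
                if onsets is None or len(onsets.times_s) == 0:
                    continue
                es = erp_mod.epoch(t.eeg, onsets, window, baseline_mode)
                if es.epochs.size == 0:
                    continue
                epochs.append(es.epochs[:, :, channel_idx].mean(axis=2))
                amps.append(onsets.amplitudes[es.kept])
            if not epochs:
                continue
            ep = np.vstack(epochs)
            am = np.concatenate(amps)
            try:
                lo, hi = split(ep, am)
            except ValueError:
                continue
            slot = by_cond.setdefault(cond, {"a": [], "b": []})
            slot["a"].append(lo)
            slot["b"].append(hi)
    return by_cond


def _stage_erp(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    cohort = _load_cohort(config, run_dir)
    trials = partition.cohort_trials(cohort)
    window = LagWindow(fs=config.sim.fs)
    names = layout.channel_names()
    rng_seed = config.seed

    def amp_split(ep, am):
        lo, hi = erp_mod.split_extremes(am)
        return ep[lo].mean(axis=0), ep[hi].mean(axis=0)

    def phase_split(sign):
        def f(ep, am):
            lo = np.flatnonzero(am < 0)
            hi = np.flatnonzero(am > 0)
            if len(lo) < 2 or len(hi) < 2:
                raise ValueError("too few transitions")
            return ep[lo].mean(axis=0), ep[hi].mean(axis=0)
        return f

    contrasts = {
        "music": (lambda t: erp_mod.detect_onsets(
            t.regressors["music_flux"], t.fs, salience_sd=3.0),
            config.channels_of_interest["music_flux"], "prestim", amp_split),
        "self": (lambda t: erp_mod.detect_onsets(
            t.regressors["self_velocity"], t.fs),
            config.channels_of_interest["self_velocity"], "whole_epoch",
            amp_split),
        "other": (lambda t: erp_mod.detect_onsets(
            t.regressors["other_velocity"], t.fs),
            config.channels_of_interest["other_velocity"], "prestim",
            amp_split),
        "coordination": (lambda t: erp_mod.coordination_transitions(
            t.regressors["coordination"], t.sources["v_self"],
            t.sources["v_other"], t.fs),
            config.channels_of_interest["coordination"], "whole_epoch",
            phase_split(+1)),
    }
    rows = []
    for label, (getter, channels, mode, split) in contrasts.items():
        ch_idx = [names.index(c) for c in channels]
        groups = _participant_group_means(trials, getter, ch_idx, window,
                                          mode, split)
        for cond, g in groups.items():
            if len(g["a"]) < 5:
                continue
            res = erp_mod.cluster_perm_test(
                np.stack(g["a"]), np.stack(g["b"]),
                n_perm=config.n_permutations, seed=rng_seed, window=window)
            if not res.clusters:
                rows.append((label, cond, np.nan, np.nan, np.nan, np.nan))
            for cl in res.clusters:
                rows.append((label, cond, cl["start_ms"], cl["stop_ms"],
                             cl["mass"], cl["p"]))
    table = pd.DataFrame(rows, columns=["contrast", "condition", "start_ms",
                                        "stop_ms", "mass", "p"])
    _write_table(table, run_dir / "erp" / "clusters.csv", config, outputs)


def _stage_stats(config: RunConfig, run_dir: Path, outputs: dict) -> None:
    delta_r = pd.read_csv(run_dir / "fit" / "delta_r.csv")
    anovas = {}
    selections = []
    for regressor, expected in stats.EXPECTED_CONDITIONS.items():
        channels = stats.select_electrodes(delta_r, regressor, expected)
        selections.extend((regressor, c) for c in channels)
        table = stats.condition_means(delta_r, regressor, channels)
        try:
            anovas[regressor] = stats.rm_anova_2x2(table)
        except ValueError:
            continue
    result = stats.anova_table(anovas)
    _write_table(result, run_dir / "stats" / "anova.csv", config, outputs)
    _write_table(pd.DataFrame(selections, columns=["regressor", "channel"]),
                 run_dir / "stats" / "electrodes.csv", config, outputs)
    (run_dir / "stats" / "anova.json").write_text(
        result.to_json(orient="records", indent=2))
    outputs["anova.json"] = array_hash(np.frombuffer(
        (run_dir / "stats" / "anova.json").read_bytes(), dtype=np.uint8))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "erp": _stage_erp,
    "stats": _stage_stats,
}
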