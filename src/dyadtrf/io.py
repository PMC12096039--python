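"""Readers/writers: session container (HDF5), EEG formats, run configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from dyadtrf.kernels import KernelSpec
from dyadtrf.simulate import ConditionLabel, DyadSession, SimConfig, TrialRecord


class DataError(RuntimeError):
    """Malformed or unreadable input data."""


class ConfigError(RuntimeError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# session container


def write_session(path, session: DyadSession) -> None:
    """Write a dyad session (trials, regressors, ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = session.seed
        f.attrs["config"] = yaml.safe_dump(_config_dict(session.config))
        for pid, trials in session.trials.items():
            g = f.create_group(f"participants/{pid}")
            for i, t in enumerate(trials):
                tg = g.create_group(f"trials/{i:03d}")
                tg.create_dataset("eeg", data=t.eeg)
                tg.attrs["vision"] = t.condition.vision
                tg.attrs["music"] = t.condition.music
                tg.attrs["fs"] = t.fs
                rg = tg.create_group("regressors")
                for name, series in t.regressors.items():
                    rg.create_dataset(name, data=series)
                sg = tg.create_group("sources")
                for name, series in t.sources.items():
                    sg.create_dataset(name, data=series)
        kg = f.create_group("ground_truth")
        for name, spec in session.ground_truth.items():
            sg = kg.create_group(name)
            sg.create_dataset("peaks", data=np.asarray(spec.peaks, dtype=float))
            sg.create_dataset("topography", data=spec.topography)


def read_session(path) -> DyadSession:
    """Read a dyad session container written by :func:`write_session`."""
    try:
        with h5py.File(path, "r") as f:
            config = SimConfig(**_config_from_dict(
                yaml.safe_load(f.attrs["config"])))
            seed = int(f.attrs["seed"])
            trials: dict[str, list[TrialRecord]] = {}
            for pid in sorted(f["participants"]):
                g = f[f"participants/{pid}"]
                records = []
                for key in sorted(g["trials"]):
                    tg = g[f"trials/{key}"]
                    records.append(TrialRecord(
                        eeg=tg["eeg"][()],
                        regressors={n: tg["regressors"][n][()]
                                    for n in tg["regressors"]},
                        condition=ConditionLabel(tg.attrs["vision"],
                                                 tg.attrs["music"]),
                        fs=float(tg.attrs["fs"]),
                        sources={n: tg["sources"][n][()]
                                 for n in tg["sources"]},
                    ))
                trials[pid] = records
            kernels = {}
            for name in f["ground_truth"]:
                sg = f[f"ground_truth/{name}"]
                kernels[name] = KernelSpec(
                    name, [tuple(row) for row in sg["peaks"][()]],
                    sg["topography"][()])
    except OSError as exc:
        raise DataError(f"cannot read session container {path}: {exc}") from exc
    return DyadSession(trials=trials, ground_truth=kernels, config=config,
                       seed=seed)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["coordination_gains"] = {f"{v}/{m}": g for (v, m), g
                               in config.coordination_gains.items()}
    return d


def _config_from_dict(d: dict) -> dict:
    d = dict(d)
    if "coordination_gains" in d:
        d["coordination_gains"] = {tuple(k.split("/")): v for k, v
                                   in d["coordination_gains"].items()}
    for key in ("base_tempos_bpm", "reset_interval_s"):
        if key in d:
            d[key] = tuple(d[key])
    return d


# ---------------------------------------------------------------------------
# EEG readers


def read_eeg(path, fmt: str, fs: float | None = None,
             dataset: str | None = None):
    """Read multichannel EEG: returns (channels x time array, fs, labels).

    Formats: 'edf'/'bdf' (via mne), 'delimited' (one column per channel,
    optional 'time' column to infer fs), 'container' (a trial inside a
    session container, ``dataset`` like 'participants/p0/trials/000').
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt in ("edf", "bdf"):
        import mne

        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:
            raise DataError(f"cannot parse {fmt} file {path}: {exc}") from exc
        return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
    if fmt == "delimited":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise DataError(f"cannot parse delimited file {path}: {exc}") from exc
        if "time" in df.columns:
            tt = df.pop("time").to_numpy()
            fs = 1.0 / float(np.median(np.diff(tt)))
        if fs is None:
            raise DataError("delimited EEG needs a 'time' column or fs=")
        return df.to_numpy().T, float(fs), list(df.columns)
    if fmt == "container":
        if dataset is None:
            raise DataError("container format needs dataset=, e.g. "
                            "'participants/p0/trials/000'")
        try:
            with h5py.File(path, "r") as f:
                tg = f[dataset]
                return tg["eeg"][()], float(tg.attrs["fs"]), None
        except (OSError, KeyError) as exc:
            raise DataError(f"cannot read {dataset} from {path}: {exc}") from exc
    raise DataError(f"unknown EEG format {fmt!r}")


def read_wav(path):
    """Read a PCM WAV file -> (float waveform in [-1, 1], fs)."""
    from scipy.io import wavfile

    try:
        fs, data = wavfile.read(path)
    except Exception as exc:
        raise DataError(f"cannot read WAV {path}: {exc}") from exc
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(fs)


def read_kinematics(path) -> np.ndarray:
    """Read delimited 66-column kinematics (x,y,z per marker, meters)."""
    try:
        arr = pd.read_csv(path).to_numpy(dtype=float)
    except Exception as exc:
        raise DataError(f"cannot read kinematics {path}: {exc}") from exc
    if arr.shape[1] != 66:
        raise DataError(f"expected 66 columns, found {arr.shape[1]}")
    return arr


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    n_dyads: int = 2
    sim: SimConfig = field(default_factory=SimConfig)
    n_permutations: int = 1000
    channels_of_interest: dict = field(default_factory=lambda: {
        "music_flux": ["Fz"],
        "self_velocity": ["C3", "C4"],
        "other_velocity": ["Oz"],
        "coordination": ["Oz"],
    })
    apply_preprocess: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot load config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("sim", {})
        try:
            config = cls(**raw)
            if isinstance(sim, dict):
                config.sim = SimConfig(**_config_from_dict(sim))
        except TypeError as exc:
            raise ConfigError(f"invalid config: {exc}") from exc
        config.validate()
        return config

    def validate(self) -> None:
        if self.n_dyads < 1:
            raise ConfigError("n_dyads must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.sim.snr <= 0:
            raise ConfigError("snr must be positive")
        if self.sim.duration_s <= 0 or self.sim.n_blocks < 1:
            raise ConfigError("duration and n_blocks must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = _config_dict(self.sim)
        return d

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]
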