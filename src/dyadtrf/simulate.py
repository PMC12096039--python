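"""Synthetic dyadic-dance sessions with known ground-truth response kernels.

Two dancers bounce to music under a 2x2 design crossing visual contact
(yes/no) with musical input (same/different tempo). Each trial's 64-channel
EEG is generated by convolving known temporal kernels with the model
regressors (music events, bounce velocity magnitudes of self and partner,
the +/-1 in-phase/anti-phase coordination sign, and high-amplitude zero-lag
EOG/EMG leakage) and adding spatially-structured pink background noise.
Condition gating reproduces the qualitative pattern the analysis should
find: partner-movement responses exist only with visual contact, and
coordination responses are strongest with visual contact plus shared music.

Every random draw descends deterministically from the session seed, so
sessions are bit-reproducible and every downstream stage can be tested
against the stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import signal

from dyadtrf import layout
from dyadtrf.features import coordination_signal
from dyadtrf.kernels import (
    ARTIFACT_REGRESSORS,
    NEURAL_REGRESSORS,
    KernelSpec,
    default_kernel_presets,
)

VISION_LEVELS = ("yes", "no")
MUSIC_LEVELS = ("same", "different")


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the 2x2 design: visual contact x musical input."""

    vision: str
    music: str

    def __post_init__(self) -> None:
        if self.vision not in VISION_LEVELS:
            raise ValueError(f"vision must be in {VISION_LEVELS}")
        if self.music not in MUSIC_LEVELS:
            raise ValueError(f"music must be in {MUSIC_LEVELS}")

    @property
    def key(self) -> str:
        return f"vision={self.vision}/music={self.music}"


CONDITIONS = tuple(
    ConditionLabel(v, m) for v in VISION_LEVELS for m in MUSIC_LEVELS
)


@dataclass
class TrialRecord:
    """One trial: EEG matrix, model regressors, condition, and raw sources.

    ``eeg`` is channels x time in microvolt-scale arbitrary units at ``fs``;
    ``regressors`` maps each model variable name to a series length-matched
    to the EEG. ``sources`` keeps signed bounce velocities (needed by the
    coordination-transition attribution and velocity-sign controls).
    """

    eeg: np.ndarray
    regressors: dict[str, np.ndarray]
    condition: ConditionLabel
    fs: float
    sources: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.eeg.shape[1]
        for name, series in self.regressors.items():
            if len(series) != n:
                raise ValueError(f"regressor {name!r} length {len(series)} != {n}")
            if np.any(~np.isfinite(series)):
                raise ValueError(f"regressor {name!r} contains non-finite values")
        if np.any(~np.isfinite(self.eeg)):
            raise ValueError("EEG contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class SimConfig:
    """Simulator parameters; defaults are the study conditions.

    Trials last 40 s (the stimuli averaged ~40 s), sampled at 100 Hz over 64
    channels; a session holds 4 blocks of 8 trials (2 per condition). The
    different-music tempo ratio is exactly 8.5%. ``snr`` is the ratio of
    channel-mean neural signal variance to background-noise variance.
    """

    fs: float = 100.0
    duration_s: float = 40.0
    n_blocks: int = 4
    base_tempos_bpm: tuple[float, ...] = (112.0, 114.0, 116.0, 118.0,
                                          122.0, 124.0, 126.0, 128.0)
    tempo_diff: float = 0.085
    snr: float = 0.25
    artifact_gain: float = 100.0
    lobe_fwhm_ms: float = 30.0
    event_amp_sigma: float = 0.5
    phase_jitter_rad: float = 0.5
    jitter_tau_s: float = 0.5
    amp_jitter: float = 0.25
    reset_interval_s: tuple[float, float] = (2.0, 6.0)
    coupling_strength: float = 4.0
    coordination_gains: dict = field(default_factory=lambda: {
        ("yes", "same"): 1.0,
        ("yes", "different"): 0.25,
        ("no", "same"): 0.0,
        ("no", "different"): 0.0,
    })
    n_noise_sources: int = 12
    sensor_noise_frac: float = 0.1
    # full-body kinematics model
    n_primitives: int = 15
    fullbody_noise_frac: float = 0.04
    bounce_var_frac: float = 0.01
    primitive_decay: float = 0.7

    def kernel_presets(self) -> dict[str, KernelSpec]:
        return default_kernel_presets(self.artifact_gain, self.lobe_fwhm_ms)


@dataclass
class DyadSession:
    """One dyad's full session: 32 trials per participant plus ground truth."""

    trials: dict[str, list[TrialRecord]]
    ground_truth: dict[str, KernelSpec]
    config: SimConfig
    seed: int

    @property
    def participants(self) -> list[str]:
        return list(self.trials)


def _ou(rng, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with std ``sd`` and timescale ``tau``."""
    x = np.empty(n)
    a = np.exp(-dt / tau)
    q = sd * np.sqrt(1.0 - a * a)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, 1.0, n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + q * eps[i - 1]
    return x


def make_event_train(tempo_bpm: float, duration: float, seed: int,
                     fs: float = 100.0, amp_sigma: float = 0.5) -> np.ndarray:
    """Impulse train of musical events at the beat rate.

    Impulses sit at multiples of the inter-beat interval 60/tempo s, with
    i.i.d. lognormal amplitudes (``log N(0, amp_sigma^2)``); the right skew
    makes a loud/soft 20% amplitude split meaningful.
    """
    if tempo_bpm <= 0 or duration <= 0:
        raise ValueError("tempo and duration must be positive")
    rng = default_rng(seed)
    n = int(round(duration * fs))
    period = 60.0 / tempo_bpm
    times = np.arange(0.0, duration - 1e-9, period)
    idx = np.round(times * fs).astype(int)
    idx = idx[idx < n]
    train = np.zeros(n)
    train[idx] = rng.lognormal(mean=0.0, sigma=amp_sigma, size=idx.size)
    return train


def make_bounce_pair(tempo_a: float, tempo_b: float, coupling: str,
                     duration: float, seed: int, fs: float = 100.0,
                     phase_jitter_rad: float = 0.5, jitter_tau_s: float = 0.5,
                     amp_jitter: float = 0.25,
                     reset_interval_s: tuple[float, float] = (2.0, 6.0),
                     attract_targets: tuple[float, ...] = (0.0, np.pi),
                     coupling_strength: float = 4.0,
                     init_phases: tuple[float, float] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vertical bounce-velocity series for two dancers.

    Each dancer bounces near-sinusoidally at their own beat rate with
    mean-reverting (Ornstein-Uhlenbeck) phase error around the beat and slow
    lognormal amplitude modulation -- the sloppy-but-entrained timing of lay
    dancers. When ``coupling == "coupled"``, seeded reset events every 2-6 s
    alternately pull dancer B toward relative phase 0 and pi, guaranteeing
    both in-phase and anti-phase episodes with at least one transition per
    10 s on average.
    """
    if tempo_a <= 0 or tempo_b <= 0:
        raise ValueError("tempos must be positive")
    if coupling not in ("coupled", "uncoupled"):
        raise ValueError("coupling must be 'coupled' or 'uncoupled'")
    period = 60.0 / min(tempo_a, tempo_b)
    if duration < period:
        raise ValueError("duration shorter than one beat period")
    rng = default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    f_a, f_b = tempo_a / 60.0, tempo_b / 60.0

    if init_phases is None:
        init_phases = tuple(rng.uniform(0.0, 2.0 * np.pi, 2))
    if phase_jitter_rad > 0:
        err_a = _ou(rng, n, dt, jitter_tau_s, phase_jitter_rad)
        err_b = _ou(rng, n, dt, jitter_tau_s, phase_jitter_rad)
    else:
        err_a = err_b = np.zeros(n)

    # schedule of attraction targets (relative phase of B w.r.t. A)
    resets = []
    t = rng.uniform(*reset_interval_s)
    k = 0
    while t < duration:
        resets.append((t, attract_targets[k % len(attract_targets)]))
        t += rng.uniform(*reset_interval_s)
        k += 1

    phase_a = init_phases[0] + 2.0 * np.pi * f_a * np.arange(n) * dt + err_a
    base_b = init_phases[1] + 2.0 * np.pi * f_b * np.arange(n) * dt
    # coupling correction accumulated on top of the analytic base phase
    c = np.zeros(n)
    if coupling == "coupled":
        target = attract_targets[0]
        next_reset = 0
        for i in range(1, n):
            ti = i * dt
            while next_reset < len(resets) and resets[next_reset][0] <= ti:
                target = resets[next_reset][1]
                next_reset += 1
            pull = coupling_strength * np.sin(
                phase_a[i - 1] + target - base_b[i - 1] - c[i - 1])
            c[i] = c[i - 1] + pull * dt
    phase_b = base_b + c + (err_b - err_b[0])

    if amp_jitter > 0:
        amp_a = np.exp(_ou(rng, n, dt, 2.0, amp_jitter))
        amp_b = np.exp(_ou(rng, n, dt, 2.0, amp_jitter))
    else:
        amp_a = amp_b = np.ones(n)
    return amp_a * np.sin(phase_a), amp_b * np.sin(phase_b)


@dataclass
class FullBody:
    """66-dim posture series with the injected primitive basis and scores."""

    postures: np.ndarray  # time x 66
    basis: np.ndarray  # 66 x n_primitives, orthonormal columns
    scores: np.ndarray  # time x n_primitives
    bounce_index: int = 0


def make_fullbody(bounce_velocity: np.ndarray, n_primitives: int = 15,
                  noise_frac: float = 0.04, seed: int = 0, fs: float = 100.0,
                  bounce_var_frac: float = 0.01,
                  primitive_decay: float = 0.7) -> FullBody:
    """Full-body posture series (22 markers x xyz) from movement primitives.

    One primitive is the bounce: a uniform vertical displacement of all
    markers whose score is the integral of ``bounce_velocity``, carrying
    ``bounce_var_frac`` of the signal variance (the study found bounce at
    ~1% of kinematic variance). The remaining primitives are seeded
    band-limited noise with geometrically decaying variance on a random
    orthonormal basis; isotropic sensor noise contributes ``noise_frac`` of
    the total variance.
    """
    if not (1 <= n_primitives <= 66):
        raise ValueError("n_primitives must be in [1, 66]")
    if not (0.0 <= noise_frac < 1.0):
        raise ValueError("noise_frac must be in [0, 1)")
    rng = default_rng(seed)
    n = len(bounce_velocity)

    bounce_dir = np.zeros(66)
    bounce_dir[2::3] = 1.0  # z of every marker
    bounce_dir /= np.linalg.norm(bounce_dir)
    if n_primitives > 1:
        raw = rng.normal(size=(66, n_primitives - 1))
        q, _ = np.linalg.qr(np.column_stack([bounce_dir, raw]))
        q[:, 0] *= np.sign(q[:, 0] @ bounce_dir)
        basis = q[:, :n_primitives]
    else:
        basis = bounce_dir[:, None]

    bounce_score = np.cumsum(bounce_velocity) / fs
    bounce_score -= bounce_score.mean()
    bounce_score /= max(bounce_score.std(), 1e-30)

    shares = np.empty(n_primitives)
    if n_primitives == 1:
        shares[0] = 1.0
    else:
        decay = primitive_decay ** np.arange(n_primitives - 1)
        shares[0] = bounce_var_frac
        shares[1:] = (1.0 - bounce_var_frac) * decay / decay.sum()

    scores = np.empty((n, n_primitives))
    scores[:, 0] = bounce_score * np.sqrt(shares[0])
    if n_primitives > 1:
        sos = signal.butter(2, [0.2, 5.0], btype="bandpass", fs=fs, output="sos")
        white = rng.normal(size=(n, n_primitives - 1))
        band = signal.sosfiltfilt(sos, white, axis=0)
        band /= band.std(axis=0, keepdims=True)
        band -= band.mean(axis=0, keepdims=True)
        scores[:, 1:] = band * np.sqrt(shares[1:])

    postures = scores @ basis.T
    if noise_frac > 0:
        signal_var = shares.sum()  # total variance summed over the 66 dims
        noise_var_per_dim = noise_frac / (1.0 - noise_frac) * signal_var / 66.0
        postures = postures + rng.normal(0.0, np.sqrt(noise_var_per_dim),
                                         size=postures.shape)
    return FullBody(postures, basis, scores, bounce_index=0)


def _pink_noise(rng, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / (sd if sd > 0 else 1.0)


def _background_noise(rng, n_channels: int, n: int, n_sources: int,
                      sensor_frac: float) -> np.ndarray:
    """Spatially smooth pink background plus a white sensor floor.

    Pink sources are mixed through random Gaussian-bump topographies so that
    neighbouring electrodes see correlated background, as volume conduction
    produces on a real scalp.
    """
    names = layout.channel_names()
    mix = np.column_stack([
        layout.gaussian_topography([names[rng.integers(len(names))]],
                                   fwhm_m=rng.uniform(0.05, 0.12))
        for _ in range(n_sources)
    ])
    sources = np.stack([_pink_noise(rng, n) for _ in range(n_sources)])
    spatial = mix @ sources
    spatial /= max(spatial.std(), 1e-30)
    sensor = rng.normal(size=(n_channels, n))
    return (np.sqrt(1.0 - sensor_frac) * spatial
            + np.sqrt(sensor_frac) * sensor)


def convolve_kernel(x: np.ndarray, kernel_values: np.ndarray,
                    lags: np.ndarray) -> np.ndarray:
    """y(t) = sum_l k(l) x(t - l) over integer sample lags (can be negative)."""
    full = np.convolve(x, kernel_values)
    start = -int(lags[0])
    # full[t + start] collects sum over l of k(l) x(t - l)
    out = np.zeros_like(x)
    idx = np.arange(len(x)) + start
    valid = (idx >= 0) & (idx < len(full))
    out[valid] = full[idx[valid]]
    return out


def condition_gains(condition: ConditionLabel,
                    coordination_gains: dict | None = None) -> dict[str, float]:
    """Per-regressor kernel gain under the 2x2 condition gating contract."""
    cg = coordination_gains or SimConfig().coordination_gains
    gains = {name: 1.0 for name in NEURAL_REGRESSORS + ARTIFACT_REGRESSORS}
    if condition.vision == "no":
        gains["other_velocity"] = 0.0
    gains["coordination"] = cg[(condition.vision, condition.music)]
    return gains


def simulate_trial(regressors: dict[str, np.ndarray],
                   kernels: dict[str, KernelSpec],
                   condition: ConditionLabel, snr: float, seed: int,
                   fs: float = 100.0,
                   coordination_gains: dict | None = None,
                   n_noise_sources: int = 12,
                   sensor_noise_frac: float = 0.1,
                   sources: dict[str, np.ndarray] | None = None,
                   lag_span_ms: tuple[float, float] = (-250.0, 300.0),
                   ) -> TrialRecord:
    """Forward model: EEG = sum_k topo_k (x) (kernel_k * regressor_k) + noise.

    Each regressor is scaled to unit SD before convolution so that kernel
    amplitudes are comparable across processes. ``snr`` is channel-mean
    neural-signal variance over noise variance (``np.inf`` for noiseless).
    Condition gating zeroes the partner kernel without visual contact and
    scales the coordination kernel per the configured gains.
    """
    lengths = {len(v) for v in regressors.values()}
    if len(lengths) != 1:
        raise ValueError("regressors must be length-matched")
    n = lengths.pop()
    lags = np.arange(int(round(lag_span_ms[0] * fs / 1000.0)),
                     int(round(lag_span_ms[1] * fs / 1000.0)) + 1)
    rng = default_rng(seed)
    gains = condition_gains(condition, coordination_gains)

    n_channels = len(next(iter(kernels.values())).topography)
    neural = np.zeros((n_channels, n))
    artifact = np.zeros((n_channels, n))
    for name, x in regressors.items():
        if name not in kernels:
            continue
        spec = kernels[name]
        for lat, _a, _w in spec.peaks:
            if not (lag_span_ms[0] <= lat <= lag_span_ms[1]):
                raise ValueError(f"kernel latency {lat} ms outside lag window")
        sd = np.std(x)
        xs = x / sd if sd > 0 else x
        contrib = convolve_kernel(xs, spec.sample(lags, fs), lags)
        target = neural if name in NEURAL_REGRESSORS else artifact
        target += gains.get(name, 1.0) * np.outer(spec.topography, contrib)

    eeg = neural + artifact
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        neural_var = np.mean(np.var(neural, axis=1))
        if neural_var > 0:
            noise = _background_noise(rng, n_channels, n, n_noise_sources,
                                      sensor_noise_frac)
            eeg = eeg + noise * np.sqrt(neural_var / snr)
    return TrialRecord(eeg=eeg, regressors=dict(regressors),
                       condition=condition, fs=fs, sources=dict(sources or {}))


def _condition_sequence(config: SimConfig, rng) -> list[ConditionLabel]:
    seq: list[ConditionLabel] = []
    for _ in range(config.n_blocks):
        block = [c for c in CONDITIONS for _ in range(2)]
        rng.shuffle(block)
        seq.extend(block)
    return seq


def _trial_sources(condition: ConditionLabel, tempo: float, config: SimConfig,
                   child: SeedSequence) -> dict[str, np.ndarray]:
    """Raw per-trial source signals for one dyad trial (shared across both)."""
    s_train, s_bounce, s_phys = (int(c.generate_state(1)[0]) for c in child.spawn(3))
    dur, fs = config.duration_s, config.fs
    if condition.music == "same":
        tempo_a = tempo_b = tempo
        train_a = train_b = make_event_train(tempo, dur, s_train, fs,
                                             config.event_amp_sigma)
    else:
        tempo_a, tempo_b = tempo, tempo * (1.0 + config.tempo_diff)
        train_a = make_event_train(tempo_a, dur, s_train, fs,
                                   config.event_amp_sigma)
        train_b = make_event_train(tempo_b, dur, s_train + 1, fs,
                                   config.event_amp_sigma)
    coupling = "coupled" if condition.vision == "yes" else "uncoupled"
    v_a, v_b = make_bounce_pair(
        tempo_a, tempo_b, coupling, dur, s_bounce, fs,
        phase_jitter_rad=config.phase_jitter_rad,
        jitter_tau_s=config.jitter_tau_s, amp_jitter=config.amp_jitter,
        reset_interval_s=config.reset_interval_s,
        coupling_strength=config.coupling_strength)

    n = int(round(dur * fs))
    rng = default_rng(s_phys)
    sos = signal.butter(2, [1.0, 8.0], btype="bandpass", fs=fs, output="sos")

    def smooth_noise(size):
        return signal.sosfiltfilt(sos, rng.normal(size=size), axis=-1)

    out = {"train_a": train_a, "train_b": train_b, "v_a": v_a, "v_b": v_b}
    for p in ("a", "b"):
        sacc = np.zeros(n)
        n_sacc = rng.poisson(0.5 * dur)
        pos = rng.integers(0, n, n_sacc)
        sacc[pos] = rng.normal(0.0, 1.0, n_sacc)
        sacc = signal.sosfiltfilt(sos, sacc)
        out[f"eog_left_{p}"] = sacc + 0.3 * smooth_noise(n)
        out[f"eog_right_{p}"] = -sacc + 0.3 * smooth_noise(n)
        out[f"emg_cheek_{p}"] = smooth_noise(n)
        out[f"emg_neck_{p}"] = smooth_noise(n)
    return out


def make_session(config: SimConfig | None = None, seed: int = 0) -> DyadSession:
    """Generate one dyad's session: 32 trials per participant, 8 per condition."""
    config = config or SimConfig()
    root = SeedSequence(seed)
    seq_child, *trial_children = root.spawn(1 + 8 * config.n_blocks)
    rng = default_rng(seq_child)
    sequence = _condition_sequence(config, rng)
    kernels = config.kernel_presets()
    tempos = list(config.base_tempos_bpm)

    trials: dict[str, list[TrialRecord]] = {"p0": [], "p1": []}
    for i, condition in enumerate(sequence):
        child = trial_children[i]
        tempo = tempos[i % len(tempos)]
        src = _trial_sources(condition, tempo, config, child)
        eeg_seeds = [int(c.generate_state(1)[0]) for c in child.spawn(2)]
        coordination = coordination_signal(src["v_a"], src["v_b"])
        for part, me, other, es in (("p0", "a", "b", eeg_seeds[0]),
                                    ("p1", "b", "a", eeg_seeds[1])):
            regs = {
                "music_flux": src[f"train_{me}"],
                "self_velocity": np.abs(src[f"v_{me}"]),
                "other_velocity": np.abs(src[f"v_{other}"]),
                "coordination": coordination,
                "eog_left": src[f"eog_left_{me}"],
                "eog_right": src[f"eog_right_{me}"],
                "emg_cheek": src[f"emg_cheek_{me}"],
                "emg_neck": src[f"emg_neck_{me}"],
            }
            trial = simulate_trial(
                regs, kernels, condition, config.snr, es, config.fs,
                coordination_gains=config.coordination_gains,
                n_noise_sources=config.n_noise_sources,
                sensor_noise_frac=config.sensor_noise_frac,
                sources={"v_self": src[f"v_{me}"], "v_other": src[f"v_{other}"]},
            )
            trials[part].append(trial)
    return DyadSession(trials=trials, ground_truth=kernels, config=config,
                       seed=seed)


def make_cohort(n_dyads: int, config: SimConfig | None = None,
                seed: int = 0) -> list[DyadSession]:
    """Independent dyad sessions with seeds derived from one cohort seed."""
    children = SeedSequence(seed).spawn(n_dyads)
    return [make_session(config, int(c.generate_state(1)[0]))
            for c in children]
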