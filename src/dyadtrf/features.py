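"""Extraction of the encoding-model input variables.

Implements the feature definitions used throughout the analysis: gammatone
spectral flux for music, velocity magnitude for movement, the +/-1
coordination sign product, PCA movement primitives ("principal movements"),
per-participant standardization, and anti-aliased resampling/trimming to
the 100 Hz EEG rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

#: gammatone filterbank defaults: 128 log-spaced bands, 100-8000 Hz
N_BANDS = 128
BAND_LO_HZ = 100.0
BAND_HI_HZ = 8000.0

TARGET_FS = 100.0


@dataclass
class RegressorSet:
    """Named regressor series per participant per trial, with scale factors.

    ``series[participant][trial_index][name]`` is a standardized series;
    ``scale[participant][name]`` is the SD (across that participant's
    concatenated trials) that was divided out.
    """

    series: dict[str, list[dict[str, np.ndarray]]]
    scale: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class PrincipalMovements:
    """PCA movement primitives: orthonormal loadings, scores, variance shares."""

    basis: np.ndarray  # 66 x n_components
    scores: np.ndarray  # time x n_components, 6 Hz low-passed
    variance_explained: np.ndarray  # proportion per component, nonincreasing


def spectral_flux(audio: np.ndarray, fs_audio: float,
                  fs_out: float = TARGET_FS, n_bands: int = N_BANDS,
                  f_lo: float = BAND_LO_HZ, f_hi: float = BAND_HI_HZ,
                  rectify: bool = True) -> np.ndarray:
    """Broadband spectral flux of an audio waveform, at ``fs_out``.

    The waveform is passed through a bank of ``n_bands`` fourth-order
    gammatone filters with log-spaced center frequencies in [f_lo, f_hi];
    each band's envelope (analytic-signal magnitude) is differentiated,
    half-wave rectified (configurable), and the result averaged across
    bands and resampled. The output is nonnegative when ``rectify``.
    """
    if fs_audio < 16000:
        raise ValueError("audio sampling rate must be >= 16 kHz")
    audio = np.asarray(audio, dtype=float)
    if audio.ndim > 1:
        audio = audio.mean(axis=1)
    if len(audio) < int(0.05 * fs_audio):
        raise ValueError("audio shorter than filter startup period")
    centers = np.geomspace(f_lo, f_hi, n_bands)
    # a band centred exactly at Nyquist (16 kHz audio) is nudged just below
    centers = np.minimum(centers, 0.5 * fs_audio * (1.0 - 1e-6))
    flux = np.zeros(len(audio))
    for fc in centers:
        b, a = signal.gammatone(fc, "iir", fs=fs_audio)
        band = signal.lfilter(b, a, audio)
        env = np.abs(signal.hilbert(band))
        d = np.diff(env, prepend=env[0]) * fs_audio
        if rectify:
            d = np.maximum(d, 0.0)
        flux += d
    flux /= n_bands
    out = resample_trim(flux, fs_audio, fs_out, 0.0, len(audio) / fs_audio)
    # anti-alias ringing can undershoot zero; the flux is nonnegative by
    # construction, so clip
    return np.maximum(out, 0.0) if rectify else out


def velocity_magnitude(position: np.ndarray, fs: float) -> np.ndarray:
    """|first derivative| of a position series; same length, nonnegative."""
    position = np.asarray(position, dtype=float)
    if len(position) < 2:
        raise ValueError("need at least two samples")
    v = np.abs(np.diff(position)) * fs
    return np.concatenate([v, v[-1:]])


def coordination_signal(v_self: np.ndarray, v_other: np.ndarray) -> np.ndarray:
    """sign(v_self) * sign(v_other), exactly +/-1.

    Exact zeros in either velocity inherit the previous nonzero product
    (+1 at the first sample), keeping the output in {-1, +1}.
    """
    v_self = np.asarray(v_self, dtype=float)
    v_other = np.asarray(v_other, dtype=float)
    if v_self.shape != v_other.shape:
        raise ValueError("velocity series must have equal length")
    prod = np.sign(v_self) * np.sign(v_other)
    nz = prod != 0
    idx = np.where(nz, np.arange(len(prod)), -1)
    np.maximum.accumulate(idx, out=idx)
    out = np.where(idx >= 0, prod[idx], 1.0)
    return out


def velocity_sign(v: np.ndarray) -> np.ndarray:
    """Movement direction series in {-1, +1}; zeros carry the previous sign."""
    return coordination_signal(v, np.ones_like(np.asarray(v, dtype=float)))


def pca_movements(postures: np.ndarray, n_keep: int = 15, fs: float = TARGET_FS,
                  lowpass_hz: float = 6.0) -> PrincipalMovements:
    """Principal movements of concatenated 66-dim posture data.

    Mean-centered PCA over all time samples (trials/participants stacked
    along time); score series are zero-phase low-pass filtered below 6 Hz
    (Butterworth, order 2). Rank-deficient input yields fewer components
    with a warning.
    """
    postures = np.asarray(postures, dtype=float)
    if postures.shape[0] <= postures.shape[1]:
        raise ValueError("need more time samples than dimensions")
    rank = np.linalg.matrix_rank(postures - postures.mean(axis=0))
    if rank < n_keep:
        warnings.warn(f"input rank {rank} < n_keep={n_keep}; returning "
                      f"{rank} components")
        n_keep = rank
    pca = PCA(n_components=n_keep)
    scores = pca.fit_transform(postures)
    sos = signal.butter(2, lowpass_hz, btype="low", fs=fs, output="sos")
    scores = signal.sosfiltfilt(sos, scores, axis=0)
    return PrincipalMovements(
        basis=pca.components_.T,
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
    )


def standardize(series: dict[str, list[dict[str, np.ndarray]]]) -> RegressorSet:
    """Divide each series by its participant-level SD across all trials.

    The mean is left untouched. A zero SD raises an error naming the
    participant and series.
    """
    out: dict[str, list[dict[str, np.ndarray]]] = {}
    scales: dict[str, dict[str, float]] = {}
    for participant, trials in series.items():
        names = trials[0].keys()
        scales[participant] = {}
        for name in names:
            concat = np.concatenate([t[name] for t in trials])
            sd = float(np.std(concat))
            if sd == 0.0:
                raise ValueError(
                    f"series {name!r} of participant {participant!r} has zero SD")
            scales[participant][name] = sd
        out[participant] = [
            {name: t[name] / scales[participant][name] for name in names}
            for t in trials
        ]
    return RegressorSet(series=out, scale=scales)


def resample_trim(series: np.ndarray, fs_in: float, fs_out: float = TARGET_FS,
                  t_start: float = 0.0, t_end: float | None = None) -> np.ndarray:
    """Polyphase anti-aliased resampling, then trim to [t_start, t_end).

    Output length is round((t_end - t_start) * fs_out).
    """
    series = np.asarray(series, dtype=float)
    if t_end is None:
        t_end = len(series) / fs_in
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if fs_in < fs_out:
        raise ValueError("fs_in must be >= fs_out")
    if fs_in == fs_out:
        resampled = series
    else:
        frac = Fraction(fs_out / fs_in).limit_denominator(10000)
        resampled = signal.resample_poly(series, frac.numerator,
                                         frac.denominator)
    i0 = int(round(t_start * fs_out))
    n = int(round((t_end - t_start) * fs_out))
    out = resampled[i0:i0 + n]
    if len(out) < n:  # pad by edge value if rounding left us short
        out = np.concatenate([out, np.full(n - len(out), out[-1])])
    return out
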