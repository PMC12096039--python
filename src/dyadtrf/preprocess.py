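"""EEG cleaning: 1-8 Hz filtering, bad-channel flagging, CAR, interpolation.

Implements the stated cleaning criteria: zero-phase Butterworth (order 3)
band-pass between 1 and 8 Hz; channels flagged bad on prolonged flat lines
(> 5 s), abnormal neighbour correlation (< 0.8), or amplitude metrics (mean,
SD, peak-to-peak) deviating more than 3 SD from the scalp average; common
average reference computed over good channels only; bad channels replaced
by the average of neighbours within 20 mm (widened to the nearest good
neighbour with a warning when none falls inside the radius). Subspace
artifact-removal and ICA-based ocular cleaning are external published
algorithms; ``asr_hook`` lets a caller splice such a stage in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class ChannelQuality:
    """Per-channel quality flags and the metrics behind them."""

    channel: str
    flags: set[str] = field(default_factory=set)
    longest_flat_s: float = 0.0
    max_neighbor_correlation: float = 1.0
    amplitude_z: dict[str, float] = field(default_factory=dict)

    @property
    def bad(self) -> bool:
        return bool(self.flags)


def bandpass(eeg: np.ndarray, fs: float, lo: float = 1.0, hi: float = 8.0,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied along the last axis."""
    if fs <= 16.0:
        raise ValueError("sampling rate too low for a 1-8 Hz band-pass")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, eeg, axis=-1)


def _longest_flat_run(x: np.ndarray, eps: float) -> int:
    flat = np.abs(np.diff(x)) <= eps
    if not flat.any():
        return 1
    # length of longest run of True, +1 to convert step count to samples
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = edges[1::2] - edges[0::2]
    return int(runs.max()) + 1


def flag_bad_channels(eeg: np.ndarray, fs: float,
                      channel_names: list[str] | None = None,
                      flat_s: float = 5.0, corr_min: float = 0.8,
                      z_max: float = 3.0, window_s: float = 5.0,
                      flat_eps_frac: float = 1e-8) -> list[ChannelQuality]:
    """Flag flatline, low-correlation, and amplitude-outlier channels.

    Correlation uses the maximum absolute correlation with any other channel,
    computed in 5 s windows and aggregated by the median across windows.
    Amplitude metrics (mean, SD, peak-to-peak) are z-scored against the
    across-channel distribution. The flatline epsilon is 1e-8 of the channel
    SD, so an exactly constant segment is flat regardless of scale.
    """
    n_ch, n = eeg.shape
    if n_ch < 4:
        raise ValueError("need at least 4 channels")
    names = channel_names or [f"ch{i}" for i in range(n_ch)]

    reports = [ChannelQuality(channel=names[i]) for i in range(n_ch)]

    # flat lines
    for i in range(n_ch):
        eps = flat_eps_frac * float(np.std(eeg[i]))
        run = _longest_flat_run(eeg[i], eps)
        reports[i].longest_flat_s = run / fs
        if run / fs > flat_s:
            reports[i].flags.add("flatline")

    # neighbour correlation, windowed
    win = max(int(window_s * fs), 2)
    starts = range(0, max(n - win + 1, 1), win)
    best_by_window = []
    for s in starts:
        seg = eeg[:, s:s + win]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 0.0)
        best = np.max(np.abs(c), axis=1)
        best[sd == 0] = 0.0
        best_by_window.append(best)
    median_best = np.median(np.stack(best_by_window), axis=0)
    for i in range(n_ch):
        reports[i].max_neighbor_correlation = float(median_best[i])
        if median_best[i] < corr_min:
            reports[i].flags.add("low_correlation")

    # amplitude metrics vs scalp distribution
    metrics = {
        "mean": eeg.mean(axis=1),
        "sd": eeg.std(axis=1),
        "ptp": np.ptp(eeg, axis=1),
    }
    for key, values in metrics.items():
        mu, sd = values.mean(), values.std()
        z = (values - mu) / sd if sd > 0 else np.zeros_like(values)
        for i in range(n_ch):
            reports[i].amplitude_z[key] = float(z[i])
            if abs(z[i]) > z_max:
                reports[i].flags.add("amplitude_outlier")
    return reports


def rereference_car(eeg: np.ndarray, bad: set[int] | None = None) -> np.ndarray:
    """Common average reference over good channels, subtracted everywhere."""
    bad = bad or set()
    good = [i for i in range(eeg.shape[0]) if i not in bad]
    if len(good) < 2:
        raise ValueError("need at least two good channels for CAR")
    ref = eeg[good].mean(axis=0)
    return eeg - ref


def interpolate_bad(eeg: np.ndarray, bad: set[int],
                    channel_names: list[str], positions: np.ndarray,
                    radius_m: float = 0.020) -> np.ndarray:
    """Replace bad channels by the mean of good neighbours within a radius.

    When no good neighbour lies within the radius, the search widens to the
    nearest good channel with a warning; with no good channels at all the
    call fails.
    """
    good = [i for i in range(eeg.shape[0]) if i not in bad]
    if not good:
        raise ValueError("no good channels to interpolate from")
    out = eeg.copy()
    for i in sorted(bad):
        d = np.linalg.norm(positions - positions[i], axis=1)
        neighbors = [j for j in good if j != i and d[j] <= radius_m]
        if not neighbors:
            j = min(good, key=lambda j: d[j])
            warnings.warn(
                f"channel {channel_names[i]} has no good neighbour within "
                f"{radius_m * 1000:.0f} mm; using nearest ({channel_names[j]})")
            neighbors = [j]
        out[i] = eeg[neighbors].mean(axis=0)
    return out


def asr_hook(eeg: np.ndarray, fs: float, stage=None) -> np.ndarray:
    """Optional external artifact-removal stage (e.g. subspace reconstruction).

    ``stage`` is a callable ``(eeg, fs) -> eeg``; the identity when absent.
    """
    if stage is None:
        return eeg
    return stage(eeg, fs)
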