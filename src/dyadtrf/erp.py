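"""Event-locked ERP extraction and group contrasts.

Events are peaks of the regressor time series (acoustic peaks additionally
filtered at 3 SD salience) or sign flips of the coordination series; epochs
span the same -250..+300 ms window as the TRFs. External-stimulus epochs
(music, partner movement) are baselined on the prestimulus interval,
internally initiated ones (self movement, coordination) on the whole epoch.
Group contrasts (loud/soft, fast/slow, to-in-phase/to-anti-phase) are
assessed with a paired cluster-based permutation test over time at a single
channel: pointwise paired t, clusters of contiguous suprathreshold samples
of one sign, cluster mass = summed t, null = max |mass| over sign-flip
permutations of the participant-wise differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy import stats

from dyadtrf.trf import LagWindow


@dataclass
class OnsetList:
    """Detected event onsets with amplitudes and labels."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    event_class: str = "acoustic"
    transition_sign: np.ndarray | None = None  # +1 to_inphase, -1 to_antiphase
    attribution: np.ndarray | None = None  # 'self' | 'other' | 'both' | 'none'

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("onset times must be strictly increasing")


@dataclass
class EpochSet:
    """Event-locked epochs: (n_events, n_lags, n_channels), plus labels."""

    epochs: np.ndarray
    window: LagWindow
    baseline_mode: str
    group: np.ndarray | None = None
    dropped: int = 0
    kept: np.ndarray | None = None  # indices into the onset list


@dataclass
class ClusterResult:
    """Clusters of a paired contrast over time with permutation-corrected p."""

    clusters: list[dict] = field(default_factory=list)
    t_series: np.ndarray | None = None
    n_permutations: int = 1000


def detect_onsets(series: np.ndarray, fs: float,
                  salience_sd: float | None = None,
                  event_class: str = "acoustic") -> OnsetList:
    """Local maxima of a series, optionally keeping only salient peaks.

    A peak is strictly greater than both neighbours; a plateau counts once,
    at its first sample. With ``salience_sd`` set (3 for acoustic events),
    only peaks exceeding mean + salience_sd * SD of the trial survive.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= 2:
        raise ValueError("series too short for peak detection")
    rising = np.concatenate([[False], np.diff(x) > 0])
    # value at plateau start must exceed the next differing value
    peaks = []
    i = 1
    while i < len(x):
        if x[i] < x[i - 1] or (x[i] == x[i - 1]):
            i += 1
            continue
        # x[i] > x[i-1]: candidate; find end of plateau
        j = i
        while j + 1 < len(x) and x[j + 1] == x[j]:
            j += 1
        if j + 1 < len(x) and x[j + 1] < x[j]:
            peaks.append(i)
        i = j + 1
    idx = np.asarray(peaks, dtype=int)
    if salience_sd is not None and idx.size:
        thr = x.mean() + salience_sd * x.std()
        idx = idx[x[idx] > thr]
    return OnsetList(times_s=idx / fs, amplitudes=x[idx],
                     event_class=event_class)


def coordination_transitions(coordination: np.ndarray, v_self: np.ndarray,
                             v_other: np.ndarray, fs: float,
                             align_tol: int = 1) -> OnsetList:
    """Onsets at in-phase/anti-phase flips, attributed to self or other.

    A flip is attributed to the dancer whose velocity changes sign within
    ``align_tol`` samples of it; if both do, the event is labeled 'both'
    (excluded from self/other contrasts), if neither, 'none'.
    """
    c = np.asarray(coordination, dtype=float)
    if not np.all(np.isin(c, (-1.0, 1.0))):
        raise ValueError("coordination series must be exactly +/-1")
    flips = np.flatnonzero(np.diff(c) != 0) + 1
    sign_changes_self = _sign_change_samples(v_self)
    sign_changes_other = _sign_change_samples(v_other)
    attribution = []
    for f in flips:
        near_self = np.any(np.abs(sign_changes_self - f) <= align_tol)
        near_other = np.any(np.abs(sign_changes_other - f) <= align_tol)
        if near_self and near_other:
            attribution.append("both")
        elif near_self:
            attribution.append("self")
        elif near_other:
            attribution.append("other")
        else:
            attribution.append("none")
    return OnsetList(times_s=flips / fs, amplitudes=c[flips],
                     event_class="coordination_transition",
                     transition_sign=c[flips].astype(int),
                     attribution=np.asarray(attribution, dtype=object))


def _sign_change_samples(v: np.ndarray) -> np.ndarray:
    from dyadtrf.features import velocity_sign

    s = velocity_sign(np.asarray(v, dtype=float))
    return np.flatnonzero(np.diff(s) != 0) + 1


def epoch(eeg: np.ndarray, onsets: OnsetList, window: LagWindow | None = None,
          baseline_mode: str = "prestim") -> EpochSet:
    """Cut event-locked epochs and baseline-correct them.

    ``baseline_mode``: 'prestim' subtracts the mean of the -250..0 ms span
    (external stimuli), 'whole_epoch' the mean of the full window
    (internally initiated actions). Events too close to the trial edges are
    dropped (counted in ``dropped``).
    """
    if baseline_mode not in ("prestim", "whole_epoch"):
        raise ValueError("baseline_mode must be 'prestim' or 'whole_epoch'")
    window = window or LagWindow()
    fs = window.fs
    lags = window.lags
    n = eeg.shape[1]
    samples = np.round(onsets.times_s * fs).astype(int)
    keep = (samples + lags[0] >= 0) & (samples + lags[-1] < n)
    dropped = int((~keep).sum())
    epochs = np.stack([eeg[:, s + lags[0]: s + lags[-1] + 1].T
                       for s in samples[keep]]) if keep.any() else \
        np.empty((0, window.n_lags, eeg.shape[0]))
    if not keep.any():
        warnings.warn("no events fit inside the trial; empty epoch set")
    if epochs.size:
        if baseline_mode == "prestim":
            span = lags <= 0
            base = epochs[:, span, :].mean(axis=1, keepdims=True)
        else:
            base = epochs.mean(axis=1, keepdims=True)
        epochs = epochs - base
    return EpochSet(epochs=epochs, window=window, baseline_mode=baseline_mode,
                    dropped=dropped, kept=np.flatnonzero(keep))


def split_extremes(amplitudes: np.ndarray, q: float = 0.20
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the lowest-q and highest-q amplitude events (disjoint)."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 10:
        raise ValueError("need at least 10 events for an extreme split")
    lo_thr = np.quantile(a, q, method="inverted_cdf")
    hi_thr = np.quantile(a, 1.0 - q, method="higher")
    low = np.flatnonzero(a <= lo_thr)
    high = np.flatnonzero(a >= hi_thr)
    if np.intersect1d(low, high).size:
        raise ValueError("extreme groups overlap; amplitudes too discrete")
    return low, high


def _cluster_masses(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Contiguous same-sign suprathreshold runs: (start, stop, summed t)."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * t > thr
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[0::2], edges[1::2]):
            out.append((int(s), int(e), float(t[s:e].sum())))
    return out


def cluster_perm_test(group_a: np.ndarray, group_b: np.ndarray,
                      n_perm: int = 1000, seed: int = 0,
                      alpha_cluster: float = 0.05,
                      window: LagWindow | None = None) -> ClusterResult:
    """Paired cluster-based permutation test over time at one channel.

    ``group_a``/``group_b`` are (n_participants, n_times) per-participant
    mean epochs. Pointwise paired t-statistics are thresholded at the
    two-sided ``alpha_cluster`` critical t for n-1 df; cluster mass is the
    summed t, and the null is the max |mass| under sign flips of the
    participant differences. Corrected p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("groups must be matched participant-wise")
    n = a.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants with both groups")
    d = a - b
    t_obs = _paired_t(d)
    df = n - 1
    thr = stats.t.ppf(1.0 - alpha_cluster / 2.0, df)
    observed = _cluster_masses(t_obs, thr)

    rng = default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        t_p = _paired_t(signs[p][:, None] * d)
        masses = _cluster_masses(t_p, thr)
        if masses:
            null_max[p] = max(abs(m) for _, _, m in masses)

    window = window or LagWindow()
    clusters = []
    for s, e, mass in observed:
        pval = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append({
            "start_ms": window.lag_times_ms[s],
            "stop_ms": window.lag_times_ms[e - 1],
            "mass": mass,
            "p": float(pval),
        })
    return ClusterResult(clusters=clusters, t_series=t_obs,
                         n_permutations=n_perm)


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t
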