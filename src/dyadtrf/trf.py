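"""Multivariate temporal response functions (mTRF) via lagged ridge regression.

An encoding model maps a set of stimulus/feature time series onto each EEG
channel through per-regressor kernels over time lags -250..+300 ms (56 lags
at 100 Hz). Ridge regularization strength is chosen per trial by
leave-one-trial-out cross-validation over the grid {0} U {10^k, k=-4..8};
subject TRFs are the average of the leave-one-trial-out fold fits, and
prediction accuracy uses the "generic" approach: each participant's trials
are predicted from the average TRF of all other participants. The unique
contribution of a regressor (delta r) is the drop in generic prediction
accuracy when it is removed from the model.

The intercept is never penalized; this is implemented by column/target
centering, which is algebraically identical to zeroing the intercept entry
of the penalty. Cross-validation and prediction work entirely from
per-trial Gram matrices (X'X, X'y, and the column/target sums), with one
eigendecomposition per fold, so sweeping the whole lambda grid and scoring
held-out correlations costs almost nothing beyond the Gram products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: ridge CV grid: zero plus the thirteen powers of ten from 1e-4 to 1e8
LAMBDA_GRID: tuple[float, ...] = (0.0,) + tuple(10.0 ** k for k in range(-4, 9))


@dataclass(frozen=True)
class LagWindow:
    """Time-lag window for the lagged design (default -250..+300 ms, 100 Hz)."""

    t_min_ms: float = -250.0
    t_max_ms: float = 300.0
    fs: float = 100.0

    @property
    def lags(self) -> np.ndarray:
        lo = int(round(self.t_min_ms * self.fs / 1000.0))
        hi = int(round(self.t_max_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


@dataclass
class TRFModel:
    """Fitted TRF: flat coefficients plus metadata to index kernels.

    ``coef`` is (n_features, n_channels) excluding the intercept, where
    features are regressor-major, lag-ascending; ``weights`` reshapes to
    (n_regressors, n_lags, n_channels) when names and window are known.
    """

    coef: np.ndarray
    intercept: np.ndarray
    lam: float | np.ndarray
    regressor_names: list[str] | None = None
    window: LagWindow | None = None

    @property
    def weights(self) -> np.ndarray:
        if self.regressor_names is None or self.window is None:
            raise ValueError("weights need regressor names and a lag window")
        n_reg = len(self.regressor_names)
        return self.coef.reshape(n_reg, self.window.n_lags, -1)

    def kernel(self, name: str) -> np.ndarray:
        """(n_lags, n_channels) kernel estimate for one regressor."""
        i = self.regressor_names.index(name)
        return self.weights[i]

    def predict(self, design: np.ndarray) -> np.ndarray:
        """(n_samples, n_channels) prediction from a lag design (no intercept
        column)."""
        return design @ self.coef + self.intercept


@dataclass
class PredictionResult:
    """Per-channel Pearson r of predicted vs actual EEG for one model."""

    r: np.ndarray
    model_id: str = "full"
    participant: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def lagged_matrix(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Columns of lagged copies of ``x``: column for lag l holds x(t - l).

    Edges are zero-padded so every trial keeps its length.
    """
    n = len(x)
    out = np.zeros((n, len(lags)))
    for j, lag in enumerate(lags):
        if lag >= 0:
            out[lag:, j] = x[: n - lag]
        else:
            out[: n + lag, j] = x[-lag:]
    return out


def build_design(regressors: dict[str, np.ndarray], window: LagWindow,
                 add_intercept: bool = True) -> np.ndarray:
    """Lagged design matrix: (time, n_reg * n_lags [+ intercept]).

    Column blocks are regressor-major with lags ascending; the intercept
    (all-ones) column comes last.
    """
    series = list(regressors.values())
    n = len(series[0])
    if n < window.n_lags:
        raise ValueError("regressors shorter than the lag window")
    blocks = [lagged_matrix(np.asarray(x, dtype=float), window.lags)
              for x in series]
    if add_intercept:
        blocks.append(np.ones((n, 1)))
    return np.hstack(blocks)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, k) arrays; zero-variance -> 0."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = np.einsum("ij,ij->j", a, b)
    den = np.sqrt(np.einsum("ij,ij->j", a, a) * np.einsum("ij,ij->j", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0)


def ridge_fit(design: np.ndarray, eeg: np.ndarray, lam: float,
              regressor_names: list[str] | None = None,
              window: LagWindow | None = None,
              has_intercept: bool = True) -> TRFModel:
    """Ridge solution (D'D + lam I*)^-1 D'y with the intercept unpenalized.

    ``design`` is (n_samples, n_features); when ``has_intercept`` the last
    column must be the constant one. ``eeg`` is (n_samples, n_channels) or a
    1-D series. At lam = 0 a singular system falls back to the minimum-norm
    least-squares solution with a warning.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(eeg, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if has_intercept:
        if not np.allclose(design[:, -1], 1.0):
            raise ValueError("last design column must be the intercept (ones)")
        X = design[:, :-1]
    else:
        X = design
    xm = X.mean(axis=0)
    ym = y.mean(axis=0)
    Xc = X - xm
    yc = y - ym
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    B = Xc.T @ yc
    try:
        if lam == 0 and np.linalg.matrix_rank(G) < G.shape[0]:
            raise np.linalg.LinAlgError("singular at lambda=0")
        coef = np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        warnings.warn("singular system at lambda=0; returning minimum-norm "
                      "solution")
        coef = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    intercept = ym - xm @ coef
    return TRFModel(coef=coef, intercept=intercept, lam=lam,
                    regressor_names=regressor_names, window=window)


# ---------------------------------------------------------------------------
# Gram-matrix sufficient statistics


class TrialData:
    """Sufficient statistics of one trial for ridge fitting and scoring.

    Holds X'X, X'y, column/target sums and target energies; the raw design
    can optionally be retained (``keep_data``) for direct prediction.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, keep_data: bool = True):
        from scipy.linalg import blas

        self.n = X.shape[0]
        Gu = blas.dsyrk(1.0, np.asfortranarray(X), trans=1)  # upper X'X
        self.G = np.triu(Gu) + np.triu(Gu, 1).T
        self.B = X.T @ y
        self.sx = X.sum(axis=0)
        self.sy = y.sum(axis=0)
        self.syy = np.einsum("ij,ij->j", y, y)
        self.X = X if keep_data else None
        self.y = y if keep_data else None

    @property
    def n_features(self) -> int:
        return self.G.shape[0]

    def subset(self, idx: np.ndarray) -> "TrialData":
        """Column-subset sharing precomputed Gram blocks (no copy of data)."""
        sub = object.__new__(TrialData)
        sub.n = self.n
        sub.G = self.G[np.ix_(idx, idx)]
        sub.B = self.B[idx]
        sub.sx = self.sx[idx]
        sub.sy = self.sy
        sub.syy = self.syy
        sub.X = self.X[:, idx] if self.X is not None else None
        sub.y = self.y
        return sub

    def centered(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Gc, Bc, var_y*n) with the trial means removed."""
        Gc = self.G - np.outer(self.sx, self.sx) / self.n
        Bc = self.B - np.outer(self.sx, self.sy) / self.n
        yyc = self.syy - self.sy ** 2 / self.n
        return Gc, Bc, yyc


def trial_data(regressors: dict[str, np.ndarray], eeg: np.ndarray,
               window: LagWindow, keep_data: bool = True) -> TrialData:
    """Build TrialData from named regressors and channels-x-time EEG."""
    X = build_design(regressors, window, add_intercept=False)
    return TrialData(X=X, y=np.asarray(eeg, dtype=float).T,
                     keep_data=keep_data)


def pool_trials(trials: list["TrialData"]) -> "TrialData":
    """Concatenate trials at the sufficient-statistics level (no raw data)."""
    pooled = object.__new__(TrialData)
    pooled.n, pooled.G, pooled.B, pooled.sx, pooled.sy, pooled.syy = \
        _pool(trials)
    pooled.X = pooled.y = None
    return pooled


def _pool(trials: list[TrialData]):
    n = sum(t.n for t in trials)
    G = sum(t.G for t in trials)
    B = sum(t.B for t in trials)
    sx = sum(t.sx for t in trials)
    sy = sum(t.sy for t in trials)
    syy = sum(t.syy for t in trials)
    return n, G, B, sx, sy, syy


class _FoldSolver:
    """Centered ridge solver over a set of trials, cheap across lambdas."""

    def __init__(self, trials: list[TrialData]):
        n, G, B, sx, sy, _ = _pool(trials)
        self.xm = sx / n
        self.ym = sy / n
        Gc = G - np.outer(sx, sx) / n
        self.Bc = B - np.outer(sx, sy) / n
        self.evals, self.evecs = np.linalg.eigh(Gc)
        self.VB = self.evecs.T @ self.Bc
        self._scale = max(float(self.evals.max()), 1.0)

    def coef(self, lam: float) -> np.ndarray:
        d = self.evals + lam
        inv = np.where(d > 1e-12 * self._scale, 1.0 / np.maximum(d, 1e-300),
                       0.0)
        return self.evecs @ (self.VB * inv[:, None])

    def intercept(self, coef: np.ndarray) -> np.ndarray:
        return self.ym - self.xm @ coef


def _score_on_trial(coef: np.ndarray, held_centered) -> np.ndarray:
    """Per-channel Pearson r of the ridge prediction on a held-out trial,
    computed from the trial's sufficient statistics (intercepts cancel)."""
    Gc, Bc, yyc = held_centered
    num = np.einsum("fc,fc->c", coef, Bc)
    quad = np.einsum("fc,fc->c", coef, Gc @ coef)
    den = np.sqrt(np.maximum(quad, 0.0) * np.maximum(yyc, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0)


def cv_subject_fit(trials: list[TrialData],
                   grid: tuple[float, ...] = LAMBDA_GRID,
                   regressor_names: list[str] | None = None,
                   window: LagWindow | None = None,
                   ) -> tuple[TRFModel, np.ndarray]:
    """Leave-one-trial-out lambda selection and fold-averaged subject TRF.

    For each held-out trial, the remaining trials are fit at every grid
    value; the lambda maximizing the channel-mean held-out Pearson r is
    kept (ties toward smaller lambda) and the fold's coefficients at that
    lambda enter the subject average. Returns the averaged model and the
    per-trial lambdas.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    grid = tuple(sorted(grid))
    coefs, intercepts, lambdas = [], [], np.empty(len(trials))
    for i, held in enumerate(trials):
        solver = _FoldSolver([t for j, t in enumerate(trials) if j != i])
        held_centered = held.centered()
        scores = np.empty(len(grid))
        cached = {}
        for k, lam in enumerate(grid):
            c = solver.coef(lam)
            cached[lam] = c
            scores[k] = _score_on_trial(c, held_centered).mean()
        best = grid[int(np.argmax(scores))]  # first max = smallest lambda
        lambdas[i] = best
        coefs.append(cached[best])
        intercepts.append(solver.intercept(cached[best]))
    model = TRFModel(coef=np.mean(coefs, axis=0),
                     intercept=np.mean(intercepts, axis=0),
                     lam=lambdas, regressor_names=regressor_names,
                     window=window)
    return model, lambdas


def select_lambda(trials: list[TrialData],
                  grid: tuple[float, ...] = LAMBDA_GRID) -> np.ndarray:
    """Optimal lambda per held-out trial by leave-one-trial-out CV."""
    _, lambdas = cv_subject_fit(trials, grid)
    return lambdas


def fit_subject_trf(trials: list[TrialData], lambdas: np.ndarray,
                    regressor_names: list[str] | None = None,
                    window: LagWindow | None = None) -> TRFModel:
    """Average of leave-one-trial-out fold fits, each at its own lambda."""
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    if len(lambdas) != len(trials):
        raise ValueError("one lambda per trial required")
    coefs, intercepts = [], []
    for i in range(len(trials)):
        solver = _FoldSolver([t for j, t in enumerate(trials) if j != i])
        c = solver.coef(float(lambdas[i]))
        coefs.append(c)
        intercepts.append(solver.intercept(c))
    return TRFModel(coef=np.mean(coefs, axis=0),
                    intercept=np.mean(intercepts, axis=0),
                    lam=np.asarray(lambdas, dtype=float),
                    regressor_names=regressor_names, window=window)


def generic_predict(subject_trfs: list[TRFModel], trials: list[TrialData],
                    model_id: str = "full", participant: str | None = None,
                    condition: str | None = None) -> PredictionResult:
    """Predict one participant's trials from the mean TRF of the others.

    Pearson r per channel is computed on the trial-concatenated series
    (constant offsets cancel in the correlation).
    """
    if len(subject_trfs) < 1:
        raise ValueError("need at least one other participant's TRF")
    coef = np.mean([m.coef for m in subject_trfs], axis=0)
    n, G, B, sx, sy, syy = _pool(trials)
    Gc = G - np.outer(sx, sx) / n
    Bc = B - np.outer(sx, sy) / n
    yyc = syy - sy ** 2 / n
    num = np.einsum("fc,fc->c", coef, Bc)
    quad = np.einsum("fc,fc->c", coef, Gc @ coef)
    den = np.sqrt(np.maximum(quad, 0.0) * np.maximum(yyc, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return PredictionResult(r=np.clip(r, -1.0, 1.0), model_id=model_id,
                            participant=participant, condition=condition)


def delta_r(full: PredictionResult, reduced: PredictionResult) -> np.ndarray:
    """Unique contribution: r_full - r_reduced, elementwise per channel."""
    if full.participant != reduced.participant or full.condition != reduced.condition:
        raise ValueError("full/reduced predictions are not matched")
    if full.r.shape != reduced.r.shape:
        raise ValueError("channel mismatch between full and reduced model")
    return full.r - reduced.r


# ---------------------------------------------------------------------------
# Peak-latency readout


def peak_latencies(weight_series: np.ndarray, window: LagWindow,
                   polarity: str = "positive",
                   prominence_frac: float = 0.2) -> np.ndarray:
    """Latencies (ms) of salient local extrema of a TRF weight series.

    Only deflections with prominence at least ``prominence_frac`` of the
    series' absolute maximum count as peaks, mirroring how salient TRF
    deflections are read off grand-average weight curves.
    """
    w = np.asarray(weight_series, dtype=float)
    if polarity == "negative":
        w = -w
    prom = prominence_frac * np.max(np.abs(weight_series))
    idx, _ = find_peaks(w, prominence=prom)
    return window.lag_times_ms[idx]


def feature_indices(names: list[str], keep: list[str],
                    window: LagWindow) -> np.ndarray:
    """Flat design-column indices (no intercept) for a subset of regressors."""
    L = window.n_lags
    idx = []
    for name in keep:
        i = names.index(name)
        idx.extend(range(i * L, (i + 1) * L))
    return np.asarray(idx, dtype=int)


def long_format(weights_by_condition: dict[str, np.ndarray],
                regressor_names: list[str], window: LagWindow,
                channel_names: list[str]) -> pd.DataFrame:
    """Grand-average TRF weights as a long table for export."""
    frames = []
    lag_ms = window.lag_times_ms
    for cond, w in weights_by_condition.items():
        n_reg, n_lag, n_ch = w.shape
        frames.append(pd.DataFrame({
            "condition": cond,
            "regressor": np.repeat(regressor_names, n_lag * n_ch),
            "lag_ms": np.tile(np.repeat(lag_ms, n_ch), n_reg),
            "channel": np.tile(channel_names, n_reg * n_lag),
            "weight": w.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
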