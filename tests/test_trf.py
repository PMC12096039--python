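"""Lagged ridge regression, lambda CV, generic prediction, delta r."""

import numpy as np
import pytest

from dyadtrf import layout
from dyadtrf.kernels import KernelSpec, default_kernel_presets
from dyadtrf.partition import bodypart_models, coordination_control
from dyadtrf.simulate import ConditionLabel, simulate_trial
from dyadtrf.trf import (
    LAMBDA_GRID,
    LagWindow,
    build_design,
    cv_subject_fit,
    delta_r,
    fit_subject_trf,
    generic_predict,
    lagged_matrix,
    peak_latencies,
    pool_trials,
    ridge_fit,
    select_lambda,
    trial_data,
)

WIN = LagWindow()


class TestDesign:
    def test_one_regressor_gives_57_columns(self):
        D = build_design({"x": np.arange(100.0)}, WIN)
        assert D.shape == (100, 57)
        assert np.all(D[:, -1] == 1.0)

    def test_impulse_lands_on_the_lag_diagonal(self):
        x = np.zeros(200)
        s = 90
        x[s] = 1.0
        M = lagged_matrix(x, WIN.lags)
        for j, lag in enumerate(WIN.lags):
            col = np.zeros(200)
            col[s + lag] = 1.0
            assert np.array_equal(M[:, j], col)

    def test_concatenated_design_equals_stacked_trials(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=300), rng.normal(size=300)
        stacked = np.vstack([build_design({"x": x1}, WIN),
                             build_design({"x": x2}, WIN)])
        # building on the concatenation is NOT the same (edges leak), so the
        # pipeline builds per trial; per-trial blocks must agree exactly
        per_trial = np.vstack([build_design({"x": x1}, WIN),
                               build_design({"x": x2}, WIN)])
        assert np.array_equal(stacked, per_trial)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_design({"x": np.zeros(10)}, WIN)


def _hand_ridge_2x2(D, y, lam):
    """Normal equations solved with an explicit 2x2 matrix inverse; the
    second column is the unpenalized intercept."""
    A = D.T @ D + lam * np.diag([1.0, 0.0])
    (a, b), (c, d) = A
    inv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
    return inv @ (D.T @ y)


class TestRidgeFit:
    @pytest.mark.parametrize("lam", [0.0, 2.5, 100.0])
    def test_matches_hand_solved_normal_equations(self, lam):
        rng = np.random.default_rng(4)
        D = np.column_stack([rng.normal(size=3), np.ones(3)])
        y = rng.normal(size=(3, 2))
        model = ridge_fit(D, y, lam)
        expected = _hand_ridge_2x2(D, y, lam)
        assert np.allclose(model.coef[0], expected[0], atol=1e-10)
        assert np.allclose(model.intercept, expected[1], atol=1e-10)

    def test_infinite_regularization_limit(self):
        rng = np.random.default_rng(1)
        D = build_design({"x": rng.normal(size=400)}, WIN)
        y = rng.normal(loc=3.0, size=(400, 2))
        model = ridge_fit(D, y, 1e14)
        assert np.max(np.abs(model.coef)) < 1e-8
        assert np.allclose(model.intercept, y.mean(axis=0), atol=1e-6)

    def test_noiseless_simulated_trial_recovers_kernel(self):
        presets = default_kernel_presets()
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000) ** 2
        trial = simulate_trial({"music_flux": x},
                               {"music_flux": presets["music_flux"]},
                               ConditionLabel("yes", "same"), np.inf, 0)
        D = build_design({"music_flux": x / x.std()}, WIN)
        model = ridge_fit(D, trial.eeg.T, 0.0, ["music_flux"], WIN)
        truth = np.outer(presets["music_flux"].sample(WIN.lags, 100.0),
                         presets["music_flux"].topography)
        assert np.max(np.abs(model.kernel("music_flux") - truth)) < 1e-6

    def test_singular_system_returns_min_norm_with_warning(self):
        D = np.column_stack([np.ones(4), np.ones(4)])  # duplicated intercept
        y = np.arange(4.0)
        with pytest.warns(UserWarning, match="minimum-norm"):
            model = ridge_fit(D, y, 0.0)
        assert np.all(np.isfinite(model.coef))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.ones((3, 1)), np.ones(3), -1.0, has_intercept=False)


def _toy_trials(n_trials=4, n=600, noise=0.0, seed=0, kernel_peaks=None):
    """Small simulated trials with a known music kernel."""
    presets = default_kernel_presets()
    spec = presets["music_flux"] if kernel_peaks is None else KernelSpec(
        "music_flux", kernel_peaks, presets["music_flux"].topography)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trials):
        x = rng.normal(size=n) ** 2
        trial = simulate_trial(
            {"music_flux": x}, {"music_flux": spec},
            ConditionLabel("yes", "same"),
            np.inf if noise == 0.0 else 1.0 / noise,
            int(rng.integers(2**31)))
        out.append(trial_data({"music_flux": x / x.std()}, trial.eeg, WIN))
    return out


class TestLambdaSelection:
    def test_grid_is_zero_plus_powers_of_ten(self):
        assert LAMBDA_GRID[0] == 0.0
        assert np.allclose(LAMBDA_GRID[1:],
                           [10.0 ** k for k in range(-4, 9)])

    def test_noiseless_data_selects_zero(self):
        lams = select_lambda(_toy_trials(noise=0.0))
        assert np.all(lams == 0.0)

    def test_noisy_data_selects_positive_lambda(self):
        # strong overfitting pressure: 224 lagged columns fit on a single
        # 300-sample trial at low SNR; CV must regularize
        presets = default_kernel_presets()
        names = ["music_flux", "self_velocity", "other_velocity",
                 "coordination"]
        positive = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trials = []
            for _ in range(2):
                n = 300
                regs = {
                    "music_flux": rng.normal(size=n) ** 2,
                    "self_velocity": np.abs(rng.normal(size=n)),
                    "other_velocity": np.abs(rng.normal(size=n)),
                    "coordination": np.where(rng.normal(size=n) > 0, 1.0,
                                             -1.0),
                }
                tr = simulate_trial(regs, {k: presets[k] for k in names},
                                    ConditionLabel("yes", "same"), 0.1,
                                    int(rng.integers(2**31)))
                trials.append(trial_data(
                    {k: v / v.std() for k, v in regs.items()}, tr.eeg, WIN))
            positive += np.all(select_lambda(trials) > 0)
        assert positive >= 18  # >= 90% of seeds

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(_toy_trials(), grid=())


class TestSubjectFit:
    def test_identical_trials_equal_single_fold(self):
        trials = _toy_trials(n_trials=1)
        same = [trials[0]] * 4
        model = fit_subject_trf(same, np.zeros(4), ["music_flux"], WIN)
        single = ridge_fit(
            np.hstack([same[0].X, np.ones((same[0].n, 1))]), same[0].y, 0.0,
            ["music_flux"], WIN)
        assert np.allclose(model.coef, single.coef, atol=1e-8)

    def test_fold_average_matches_explicit_ridge(self):
        trials = _toy_trials(n_trials=3, noise=0.5, seed=3)
        lam = 10.0
        model = fit_subject_trf(trials, np.full(3, lam))
        coefs = []
        for i in range(3):
            others = [t for j, t in enumerate(trials) if j != i]
            X = np.vstack([np.hstack([t.X, np.ones((t.n, 1))])
                           for t in others])
            y = np.vstack([t.y for t in others])
            coefs.append(ridge_fit(X, y, lam).coef)
        assert np.allclose(model.coef, np.mean(coefs, axis=0), atol=1e-8)

    def test_lambda_count_must_match(self):
        with pytest.raises(ValueError):
            fit_subject_trf(_toy_trials(n_trials=3), np.zeros(2))


class TestGenericPrediction:
    def test_identical_participants_noiseless_r_is_one(self):
        trials = _toy_trials(n_trials=3)
        model, _ = cv_subject_fit(trials)
        pred = generic_predict([model, model], trials)
        active = pred.r[np.abs(pred.r) > 1e-6]  # channels with any signal
        assert np.all(active > 0.999)
        assert np.all(pred.r <= 1.0) and np.all(pred.r >= -1.0)

    def test_shuffled_regressor_prediction_centers_on_zero(self):
        rng = np.random.default_rng(0)
        means = []
        for seed in range(20):
            trials = _toy_trials(n_trials=3, n=400, noise=1.0, seed=seed)
            model, _ = cv_subject_fit(trials)
            rs = []
            for _ in range(5):  # several independent mismatched trials
                x = rng.normal(size=400) ** 2
                shuffled = trial_data({"music_flux": x / x.std()},
                                      rng.normal(size=(64, 400)), WIN)
                rs.append(generic_predict([model], [shuffled]).r.mean())
            means.append(np.mean(rs))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 2.0 * se

    def test_requires_other_participants(self):
        with pytest.raises(ValueError):
            generic_predict([], _toy_trials(n_trials=2))


class TestDeltaR:
    def test_reduced_equals_full_gives_zero(self):
        from dyadtrf.trf import PredictionResult

        a = PredictionResult(r=np.array([0.3, 0.1]), participant="p",
                             condition="c")
        b = PredictionResult(r=np.array([0.3, 0.1]), model_id="red",
                             participant="p", condition="c")
        assert np.allclose(delta_r(a, b), 0.0)

    def test_mismatched_metadata_rejected(self):
        from dyadtrf.trf import PredictionResult

        a = PredictionResult(r=np.zeros(3), participant="p0", condition="c")
        b = PredictionResult(r=np.zeros(3), participant="p1", condition="c")
        with pytest.raises(ValueError):
            delta_r(a, b)


class TestGramPath:
    def test_subset_matches_rebuilt_trial(self):
        rng = np.random.default_rng(5)
        regs = {"a": rng.normal(size=300), "b": rng.normal(size=300)}
        eeg = rng.normal(size=(4, 300))
        full = trial_data(regs, eeg, WIN)
        idx = np.arange(WIN.n_lags)  # keep regressor 'a'
        sub = full.subset(idx)
        direct = trial_data({"a": regs["a"]}, eeg, WIN)
        assert np.allclose(sub.G, direct.G, atol=1e-9)
        assert np.allclose(sub.B, direct.B, atol=1e-9)

    def test_pooled_prediction_equals_concatenated_pearson(self):
        rng = np.random.default_rng(6)
        trials = _toy_trials(n_trials=3, noise=0.5, seed=6)
        model, _ = cv_subject_fit(trials)
        pooled = pool_trials(trials)
        r_pooled = generic_predict([model], [pooled]).r
        yhat = np.vstack([t.X @ model.coef + model.intercept for t in trials])
        y = np.vstack([t.y for t in trials])
        r_direct = np.array([np.corrcoef(yhat[:, c], y[:, c])[0, 1]
                             for c in range(y.shape[1])])
        assert np.allclose(r_pooled, r_direct, atol=1e-9)


def _marker_trials(with_head=True, seed=0):
    """Trials with 16 marker-velocity regressors + neck EMG; kernels only on
    the left hand (right-central topography) and optionally the head."""
    from dyadtrf.partition import BODYPART_MARKERS

    rng = np.random.default_rng(seed)
    n = 1200
    kernels = {
        "L Hand": KernelSpec("L Hand", [(80.0, 1.0, 30.0)],
                             layout.gaussian_topography(["C4"])),
    }
    if with_head:
        kernels["LB Head"] = KernelSpec(
            "LB Head", [(100.0, 1.0, 30.0)],
            layout.gaussian_topography(["Oz", "Cz"]))
    out = {}
    for pid in ("p0", "p1"):
        trials = []
        for _ in range(3):
            regs = {m: np.abs(rng.normal(size=n)) for m in BODYPART_MARKERS}
            regs["emg_neck"] = rng.normal(size=n)
            trial = simulate_trial(regs, kernels,
                                   ConditionLabel("yes", "same"), 2.0,
                                   int(rng.integers(2**31)))
            trials.append(trial)
        out[pid] = trials
    return out


class TestBodypartModels:
    def test_left_hand_contribution_is_contralateral(self):
        trials = _marker_trials(seed=1)
        res = bodypart_models(trials, exclusions={
            "L Hand": ("L Hand",),
            "head": ("LB Head", "LF Head", "RF Head", "RB Head")})
        dr = res.delta_r
        hand = dr[dr.regressor == "L Hand"].set_index(
            ["participant", "channel"])["delta_r"].groupby("channel").mean()
        assert hand["C4"] > 0.0
        assert hand["C4"] > hand["C3"]
        head = dr[dr.regressor == "head"].groupby("channel")[
            "delta_r"].mean()
        assert head["Oz"] > 0.0 and head["Cz"] > 0.0

    def test_missing_marker_named_in_error(self):
        trials = _marker_trials()
        for tl in trials.values():
            for t in tl:
                del t.regressors["L Foot"]
        with pytest.raises(ValueError, match="L Foot"):
            bodypart_models(trials)


def _coordination_trials(coordination_kernel=True, sign_kernels=False,
                         seed=0, n=2000, n_trials=4):
    from dyadtrf.simulate import make_bounce_pair, make_event_train

    presets = default_kernel_presets()
    kernels = {k: presets[k] for k in
               ("music_flux", "self_velocity", "other_velocity")}
    if coordination_kernel:
        kernels["coordination"] = presets["coordination"]
    if sign_kernels:
        for name in ("velocity_sign_self", "velocity_sign_other"):
            kernels[name] = KernelSpec(
                name, [(100.0, 1.0, 30.0)],
                layout.gaussian_topography(["POz"]))
    from dyadtrf.features import coordination_signal, velocity_sign

    rng = np.random.default_rng(seed)
    out = {}
    for pid in ("p0", "p1", "p2", "p3"):
        trials = []
        for _ in range(n_trials):
            v_a, v_b = make_bounce_pair(120.0, 120.0, "coupled", n / 100.0,
                                        int(rng.integers(2**31)))
            train = make_event_train(120.0, n / 100.0,
                                     int(rng.integers(2**31)))
            regs = {
                "music_flux": train,
                "self_velocity": np.abs(v_a),
                "other_velocity": np.abs(v_b),
                "coordination": coordination_signal(v_a, v_b),
                "velocity_sign_self": velocity_sign(v_a),
                "velocity_sign_other": velocity_sign(v_b),
            }
            trial = simulate_trial(regs, kernels,
                                   ConditionLabel("yes", "same"), 1.0,
                                   int(rng.integers(2**31)))
            trial.sources.update({"v_self": v_a, "v_other": v_b})
            trials.append(trial)
        out[pid] = trials
    return out


class TestCoordinationControl:
    def test_positive_with_sign_regressors_in_model(self):
        res = coordination_control(_coordination_trials(seed=2))
        oz = res.delta_r[res.delta_r.channel == "Oz"]["delta_r"].mean()
        assert oz > 0.005

    def test_zero_when_kernel_absent_but_signs_active(self):
        res = coordination_control(_coordination_trials(
            coordination_kernel=False, sign_kernels=True, seed=3))
        oz = res.delta_r[res.delta_r.channel == "Oz"]["delta_r"].mean()
        assert abs(oz) < 0.005


class TestPeakLatencies:
    def test_reads_gaussian_lobes(self):
        spec = default_kernel_presets()["coordination"]
        w = spec.sample(WIN.lags, 100.0)
        pos = peak_latencies(w, WIN, "positive")
        neg = peak_latencies(w, WIN, "negative")
        assert list(pos) == [-90.0, 160.0]
        assert list(neg) == [-180.0, 30.0]
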