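"""Synthetic dyad generator: event trains, bounce dynamics, forward model."""

import numpy as np
import pytest

from dyadtrf import layout
from dyadtrf.features import coordination_signal
from dyadtrf.kernels import KernelSpec, default_kernel_presets
from dyadtrf.simulate import (
    CONDITIONS,
    ConditionLabel,
    SimConfig,
    make_bounce_pair,
    make_event_train,
    make_fullbody,
    make_session,
    simulate_trial,
)
from dyadtrf.trf import LagWindow


class TestEventTrain:
    def test_count_and_spacing(self):
        train = make_event_train(120.0, 10.0, seed=0)
        idx = np.flatnonzero(train)
        assert idx.size == 20
        assert np.all(np.diff(idx) == 50)  # 0.5 s at 100 Hz

    def test_deterministic_given_seed(self):
        a = make_event_train(120.0, 10.0, seed=5)
        b = make_event_train(120.0, 10.0, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_event_train(120.0, 10.0, seed=6))

    def test_amplitudes_match_lognormal_moments(self):
        sigma = 0.5
        train = make_event_train(600.0, 1000.0, seed=2, amp_sigma=sigma)
        amps = train[train > 0]
        assert amps.size == 10_000
        true_mean = np.exp(sigma ** 2 / 2.0)
        true_sd = np.sqrt((np.exp(sigma ** 2) - 1.0) * np.exp(sigma ** 2))
        se = true_sd / np.sqrt(amps.size)
        assert abs(amps.mean() - true_mean) < 3.0 * se

    @pytest.mark.parametrize("tempo,duration", [(0.0, 10.0), (-5.0, 10.0),
                                                (120.0, 0.0)])
    def test_invalid_arguments(self, tempo, duration):
        with pytest.raises(ValueError):
            make_event_train(tempo, duration, seed=0)


class TestBouncePair:
    def test_phase_locked_limit_is_all_inphase(self):
        v_a, v_b = make_bounce_pair(
            120.0, 120.0, "coupled", 20.0, seed=0, phase_jitter_rad=0.0,
            amp_jitter=0.0, attract_targets=(0.0,), init_phases=(0.0, 0.0))
        prod = coordination_signal(v_a, v_b)
        assert np.all(prod == 1.0)

    def test_relative_tempo_difference(self):
        # default different-music tempo ratio is exactly 8.5%
        assert SimConfig().tempo_diff == 0.085
        v_a, v_b = make_bounce_pair(120.0, 120.0 * 1.085, "uncoupled", 60.0,
                                    seed=1, phase_jitter_rad=0.0,
                                    amp_jitter=0.0)
        f_a = np.sum(np.abs(np.diff(np.signbit(v_a)))) / 2 / 60.0
        f_b = np.sum(np.abs(np.diff(np.signbit(v_b)))) / 2 / 60.0
        assert f_b / f_a == pytest.approx(1.085, abs=0.01)

    def test_coupled_run_produces_phase_transitions(self):
        v_a, v_b = make_bounce_pair(120.0, 120.0, "coupled", 40.0, seed=3)
        prod = coordination_signal(v_a, v_b)
        transitions = np.sum(np.diff(prod) != 0)
        assert transitions >= 3

    def test_duration_shorter_than_beat_rejected(self):
        with pytest.raises(ValueError):
            make_bounce_pair(30.0, 30.0, "uncoupled", 1.0, seed=0)


class TestFullbody:
    def test_rank_one_case(self):
        v, _ = make_bounce_pair(120.0, 120.0, "uncoupled", 20.0, seed=0)
        body = make_fullbody(v, n_primitives=1, noise_frac=0.0, seed=1)
        centered = body.postures - body.postures.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        var = s ** 2 / np.sum(s ** 2)
        assert var[0] == pytest.approx(1.0, abs=1e-12)

    def test_basis_orthonormal_and_shapes(self):
        v, _ = make_bounce_pair(120.0, 120.0, "uncoupled", 20.0, seed=0)
        body = make_fullbody(v, seed=2)
        assert body.postures.shape == (len(v), 66)
        assert np.allclose(body.basis.T @ body.basis, np.eye(15), atol=1e-10)

    def test_noise_frac_bounds(self):
        v = np.sin(np.linspace(0, 50, 2000))
        with pytest.raises(ValueError):
            make_fullbody(v, noise_frac=1.0, seed=0)
        with pytest.raises(ValueError):
            make_fullbody(v, n_primitives=0, seed=0)


class TestSimulateTrial:
    def _impulse_setup(self):
        n = 1000
        x = np.zeros(n)
        x[300] = 1.0
        kernels = {"music_flux": default_kernel_presets()["music_flux"]}
        return x, kernels

    def test_noiseless_impulse_reproduces_kernel(self):
        x, kernels = self._impulse_setup()
        cond = ConditionLabel("yes", "same")
        trial = simulate_trial({"music_flux": x}, kernels, cond, np.inf, 0)
        win = LagWindow()
        k = kernels["music_flux"].sample(win.lags, 100.0)
        expected = np.outer(kernels["music_flux"].topography, k) / x.std()
        got = trial.eeg[:, 300 + win.lags]
        assert np.allclose(got, expected, atol=1e-12)

    def test_forward_model_linearity(self):
        x, kernels = self._impulse_setup()
        cond = ConditionLabel("yes", "same")
        base = simulate_trial({"music_flux": x}, kernels, cond, np.inf, 0)
        doubled = {"music_flux": kernels["music_flux"].scaled(2.0)}
        twice = simulate_trial({"music_flux": x}, doubled, cond, np.inf, 0)
        assert np.allclose(twice.eeg, 2.0 * base.eeg, atol=1e-12)

    def test_gating_removes_other_and_coordination_without_vision(self):
        rng = np.random.default_rng(0)
        n = 1000
        presets = default_kernel_presets()
        kernels = {"other_velocity": presets["other_velocity"],
                   "coordination": presets["coordination"]}
        regs = {"other_velocity": np.abs(rng.normal(size=n)),
                "coordination": np.where(rng.normal(size=n) > 0, 1.0, -1.0)}
        for music in ("same", "different"):
            trial = simulate_trial(regs, kernels,
                                   ConditionLabel("no", music), np.inf, 0)
            assert np.all(trial.eeg == 0.0)

    def test_partial_coordination_gain_with_different_music(self):
        rng = np.random.default_rng(1)
        n = 1000
        kernels = {"coordination": default_kernel_presets()["coordination"]}
        regs = {"coordination": np.where(rng.normal(size=n) > 0, 1.0, -1.0)}
        full = simulate_trial(regs, kernels, ConditionLabel("yes", "same"),
                              np.inf, 0)
        quarter = simulate_trial(regs, kernels,
                                 ConditionLabel("yes", "different"), np.inf, 0)
        assert np.allclose(quarter.eeg, 0.25 * full.eeg, atol=1e-12)

    def test_artifact_kernels_are_zero_lag_and_100x(self):
        presets = default_kernel_presets()
        neural_max = max(abs(a) for spec in
                         [presets[k] for k in ("music_flux", "self_velocity",
                                               "other_velocity",
                                               "coordination")]
                         for _, a, _ in spec.peaks)
        for name in ("eog_left", "eog_right", "emg_cheek", "emg_neck"):
            (lat, amp, width), = presets[name].peaks
            assert lat == 0.0 and width == 0.0
            assert amp / neural_max == pytest.approx(100.0)

    def test_kernel_latency_outside_window_rejected(self):
        x = np.zeros(500)
        x[100] = 1.0
        spec = KernelSpec("music_flux", [(280.0, 1.0, 30.0)],
                          layout.gaussian_topography(["Fz"]))
        with pytest.raises(ValueError, match="outside"):
            simulate_trial({"music_flux": x}, {"music_flux": spec},
                           ConditionLabel("yes", "same"), np.inf, 0,
                           lag_span_ms=(-250.0, 250.0))

    def test_kernel_latency_validated_at_construction(self):
        with pytest.raises(ValueError):
            KernelSpec("x", [(400.0, 1.0, 30.0)],
                       layout.gaussian_topography(["Fz"]))


class TestSession:
    def test_eight_trials_per_condition(self):
        session = make_session(SimConfig(duration_s=4.0), seed=0)
        for pid in ("p0", "p1"):
            assert len(session.trials[pid]) == 32
            counts = {c.key: 0 for c in CONDITIONS}
            for t in session.trials[pid]:
                counts[t.condition.key] += 1
            assert all(v == 8 for v in counts.values())

    def test_participants_share_condition_sequence(self, small_session):
        for t0, t1 in zip(small_session.trials["p0"],
                          small_session.trials["p1"]):
            assert t0.condition == t1.condition
            assert t0.fs == t1.fs == 100.0

    def test_same_seed_bit_identical(self):
        config = SimConfig(duration_s=5.0, n_blocks=1)
        a = make_session(config, seed=9)
        b = make_session(config, seed=9)
        for pid in a.trials:
            for ta, tb in zip(a.trials[pid], b.trials[pid]):
                assert np.array_equal(ta.eeg, tb.eeg)
                for name in ta.regressors:
                    assert np.array_equal(ta.regressors[name],
                                          tb.regressors[name])

    def test_coupled_trials_have_coordination_transitions(self, small_session):
        for t in small_session.trials["p0"]:
            if t.condition.vision == "yes":
                flips = np.sum(np.diff(t.regressors["coordination"]) != 0)
                assert flips >= 1

    def test_regressor_and_eeg_shapes(self, small_session):
        t = small_session.trials["p0"][0]
        assert t.eeg.shape == (64, 2000)
        assert set(t.regressors) == {
            "music_flux", "self_velocity", "other_velocity", "coordination",
            "eog_left", "eog_right", "emg_cheek", "emg_neck"}
        assert set(t.sources) == {"v_self", "v_other"}
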