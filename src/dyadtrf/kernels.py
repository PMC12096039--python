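"""Ground-truth temporal kernels and scalp topographies for the simulator.

Each simulated EEG process is a known kernel (a sum of Gaussian lobes over
time lags) projected onto the scalp through a smooth topography. Neural
kernel latencies follow the canonical evoked-response patterns the analysis
is meant to recover: an auditory P50-N100-P200 complex for music, a central
movement-related N(-100)-P(0)-N(+80) triphasic pattern for self-generated
movement, an occipital P70-N160 biphasic visual response for partner
movement, and a quadriphasic occipital pattern for coordination transitions.
Ocular/muscular leakage is modeled as zero-lag impulses two orders of
magnitude larger than the neural kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dyadtrf import layout

#: model regressors carrying neural kernels
NEURAL_REGRESSORS = ("music_flux", "self_velocity", "other_velocity", "coordination")
#: artifact control regressors (zero-lag leakage)
ARTIFACT_REGRESSORS = ("eog_left", "eog_right", "emg_cheek", "emg_neck")
ALL_REGRESSORS = NEURAL_REGRESSORS + ARTIFACT_REGRESSORS

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

LATENCY_MIN_MS = -250.0
LATENCY_MAX_MS = 300.0


@dataclass
class KernelSpec:
    """Per-regressor temporal kernel plus scalp topography.

    peaks: list of ``(latency_ms, amplitude, fwhm_ms)``; a zero width makes a
    single-sample impulse at the nearest lag. Latencies must lie inside the
    modeled lag window [-250, +300] ms. The topography is one weight per
    channel on the 64-channel layout and must have at least one nonzero
    entry.
    """

    regressor_name: str
    peaks: list[tuple[float, float, float]]
    topography: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.ndim != 1 or not np.any(self.topography != 0):
            raise ValueError("topography must be 1-D with a nonzero entry")
        for lat, _amp, _w in self.peaks:
            if not (LATENCY_MIN_MS <= lat <= LATENCY_MAX_MS):
                raise ValueError(
                    f"kernel latency {lat} ms outside [{LATENCY_MIN_MS}, "
                    f"{LATENCY_MAX_MS}] ms"
                )

    def sample(self, lags: np.ndarray, fs: float) -> np.ndarray:
        """Evaluate the kernel at integer sample ``lags`` for rate ``fs``."""
        t_ms = np.asarray(lags, dtype=float) / fs * 1000.0
        k = np.zeros_like(t_ms)
        for lat, amp, width in self.peaks:
            if width == 0:
                k[np.argmin(np.abs(t_ms - lat))] += amp
            else:
                sigma = width * _FWHM_TO_SIGMA
                k += amp * np.exp(-0.5 * ((t_ms - lat) / sigma) ** 2)
        return k

    def scaled(self, gain: float) -> "KernelSpec":
        return KernelSpec(
            self.regressor_name,
            [(lat, amp * gain, w) for lat, amp, w in self.peaks],
            self.topography,
        )


def default_kernel_presets(artifact_gain: float = 100.0,
                           lobe_fwhm_ms: float = 30.0) -> dict[str, KernelSpec]:
    """Default ground-truth kernels for all eight model regressors.

    ``artifact_gain`` sets how much larger the zero-lag EOG/EMG impulses are
    than the unit-amplitude neural lobes (default two orders of magnitude).
    """
    w = lobe_fwhm_ms
    presets = {
        "music_flux": KernelSpec(
            "music_flux",
            [(60.0, 1.0, w), (120.0, -1.0, w), (200.0, 1.0, w)],
            layout.gaussian_topography(["Fz"]),
        ),
        "self_velocity": KernelSpec(
            "self_velocity",
            [(-100.0, -1.0, w), (0.0, 1.0, w), (80.0, -1.0, w)],
            layout.gaussian_topography(["C3", "C4"]),
        ),
        "other_velocity": KernelSpec(
            "other_velocity",
            [(70.0, 1.0, w), (160.0, -1.0, w)],
            layout.gaussian_topography(["Oz"]),
        ),
        "coordination": KernelSpec(
            "coordination",
            [(-180.0, -1.0, w), (-90.0, 1.0, w), (30.0, -1.0, w), (160.0, 1.0, w)],
            layout.gaussian_topography(["Oz"]),
        ),
        "eog_left": KernelSpec(
            "eog_left", [(0.0, artifact_gain, 0.0)],
            layout.gaussian_topography(["AF7"], fwhm_m=0.05),
        ),
        "eog_right": KernelSpec(
            "eog_right", [(0.0, artifact_gain, 0.0)],
            layout.gaussian_topography(["AF8"], fwhm_m=0.05),
        ),
        "emg_cheek": KernelSpec(
            "emg_cheek", [(0.0, artifact_gain, 0.0)],
            layout.gaussian_topography(["T7", "T8"], fwhm_m=0.05),
        ),
        "emg_neck": KernelSpec(
            "emg_neck", [(0.0, artifact_gain, 0.0)],
            layout.gaussian_topography(["Iz", "P9", "P10"], fwhm_m=0.05),
        ),
    }
    return presets
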