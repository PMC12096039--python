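"""Shared fixtures: simulated sessions, cohort recovery runs, EDF writing."""

from __future__ import annotations

import numpy as np
import pytest

from dyadtrf import recovery
from dyadtrf.simulate import SimConfig, make_session


@pytest.fixture(scope="session")
def big_recovery():
    """Default 20-participant cohort fit: the kernel-recovery study."""
    latencies, result = recovery.kernel_recovery_run(n_participants=20, seed=1)
    return latencies, result


@pytest.fixture(scope="session")
def small_session():
    """One small dyad session reused by lightweight tests."""
    return make_session(SimConfig(duration_s=20.0, n_blocks=1), seed=7)


def write_minimal_edf(path, data: np.ndarray, fs: float,
                      labels: list[str]) -> None:
    """Write a tiny single-record EDF file (test fixture generator only)."""
    n_sig, n = data.shape
    duration = n / fs

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80), pad("01.01.20", 8),
        pad("00.00.00", 8), pad(str(256 * (1 + n_sig)), 8), pad("", 44),
        pad("1", 8), pad(f"{duration:g}", 8), pad(str(n_sig), 4),
    ])
    fields = [
        (16, labels), (80, ["" for _ in labels]), (8, ["uV"] * n_sig),
        (8, ["-3200"] * n_sig), (8, ["3200"] * n_sig),
        (8, ["-32768"] * n_sig), (8, ["32767"] * n_sig),
        (80, [""] * n_sig), (8, [str(n)] * n_sig), (32, [""] * n_sig),
    ]
    sig_header = b"".join(pad(v, w) for w, values in fields for v in values)
    scaled = np.clip(data / 3200.0 * 32767.0, -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(header + sig_header)
        f.write(scaled.tobytes())  # one record, signal-major


@pytest.fixture
def edf_file(tmp_path):
    rng = np.random.default_rng(3)
    data = rng.normal(scale=50.0, size=(4, 200))
    labels = ["Fz", "Cz", "Oz", "Pz"]
    path = tmp_path / "tiny.edf"
    write_minimal_edf(path, data, fs=100.0, labels=labels)
    return path, data, labels
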