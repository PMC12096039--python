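"""64-channel scalp layout utilities (BioSemi extended 10-10 system).

Positions come from mne's built-in ``biosemi64`` standard montage, in meters,
head-centered. Topographies for the simulator are smooth Gaussian bumps on
this layout; neighbourhood queries support bad-channel interpolation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd


@lru_cache(maxsize=1)
def _montage_frame() -> pd.DataFrame:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    df = pd.DataFrame(
        [(name, *xyz) for name, xyz in pos.items()], columns=["channel", "x", "y", "z"]
    )
    return df.set_index("channel")


def channel_names() -> list[str]:
    """The 64 channel labels in montage order."""
    return list(_montage_frame().index)


def channel_positions(names: list[str] | None = None) -> np.ndarray:
    """(n, 3) channel positions in meters, head-centered."""
    df = _montage_frame()
    if names is not None:
        df = df.loc[names]
    return df[["x", "y", "z"]].to_numpy()


def load_layout_table(path) -> pd.DataFrame:
    """Read a delimited layout table: columns channel, x, y, z (millimeters)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"channel", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"layout table needs columns {sorted(required)}")
    out = df.set_index("channel")[["x", "y", "z"]].astype(float) / 1000.0
    return out


def gaussian_topography(centers: list[str], fwhm_m: float = 0.06,
                        sign: float = 1.0) -> np.ndarray:
    """Smooth scalp topography: sum of Gaussian bumps centered on electrodes.

    Parameters
    ----------
    centers
        Electrode labels at bump centers (e.g. ``["C3", "C4"]``).
    fwhm_m
        Full width at half maximum of each bump, meters of scalp distance.
    sign
        Overall polarity.
    """
    pos = channel_positions()
    sigma = fwhm_m / 2.3548200450309493
    topo = np.zeros(pos.shape[0])
    for label in centers:
        c = channel_positions([label])[0]
        d2 = np.sum((pos - c) ** 2, axis=1)
        topo += np.exp(-d2 / (2.0 * sigma**2))
    topo /= np.max(np.abs(topo))
    return sign * topo


def neighbors_within(names: list[str], positions: np.ndarray, channel: str,
                     radius_m: float) -> list[str]:
    """Channels (other than ``channel``) within ``radius_m`` of it."""
    idx = names.index(channel)
    d = np.linalg.norm(positions - positions[idx], axis=1)
    return [n for n, di in zip(names, d) if n != channel and di <= radius_m]


def nearest_neighbor(names: list[str], positions: np.ndarray, channel: str,
                     exclude: set[str] | None = None) -> str:
    exclude = exclude or set()
    idx = names.index(channel)
    d = np.linalg.norm(positions - positions[idx], axis=1)
    order = np.argsort(d)
    for j in order:
        n = names[j]
        if n != channel and n not in exclude:
            return n
    raise ValueError("no eligible neighbor found")
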