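"""Condition-level statistics on unique contributions (delta r).

Relevant electrodes per regressor are those with a grand-average prediction
gain (delta r > 0) across the conditions where the process is expected
(all four for music and self movement; the two visual-contact conditions
for partner movement and coordination). Per-participant delta r averaged
over those electrodes enters a 2x2 repeated-measures ANOVA with factors
visual contact and musical input; with 1-df effects each F equals the
squared paired t of the corresponding within-subject contrast, and p values
are Bonferroni-corrected (x4) across the four regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: conditions where each process is expected to produce a gain
EXPECTED_CONDITIONS = {
    "music_flux": ["vision=yes/music=same", "vision=yes/music=different",
                   "vision=no/music=same", "vision=no/music=different"],
    "self_velocity": ["vision=yes/music=same", "vision=yes/music=different",
                      "vision=no/music=same", "vision=no/music=different"],
    "other_velocity": ["vision=yes/music=same", "vision=yes/music=different"],
    "coordination": ["vision=yes/music=same", "vision=yes/music=different"],
}


@dataclass
class AnovaResult:
    """One within-subject effect: F with (1, n-1) df, p, Bonferroni p."""

    effect: str
    F: float
    df: tuple[int, int]
    p: float
    p_bonf: float = np.nan
    followups: list[dict] = field(default_factory=list)


def select_electrodes(delta_r: pd.DataFrame, regressor: str,
                      expected_conditions: list[str]) -> list[str]:
    """Channels whose grand-average delta r over the expected conditions > 0.

    ``delta_r`` is the long table from the partitioning step (columns
    participant, condition, regressor, channel, delta_r). An empty selection
    falls back to the single best channel with a warning.
    """
    if not expected_conditions:
        raise ValueError("expected_conditions must be nonempty")
    sub = delta_r[(delta_r.regressor == regressor)
                  & (delta_r.condition.isin(expected_conditions))]
    if sub.empty:
        raise ValueError(f"no delta_r rows for regressor {regressor!r}")
    grand = sub.groupby("channel", sort=True)["delta_r"].mean()
    chosen = list(grand.index[grand > 0])
    if not chosen:
        warnings.warn(f"no electrode shows a gain for {regressor!r}; "
                      "falling back to the best channel")
        chosen = [grand.idxmax()]
    return chosen


def condition_means(delta_r: pd.DataFrame, regressor: str,
                    channels: list[str]) -> pd.DataFrame:
    """Per-participant, per-condition delta r averaged over given channels."""
    sub = delta_r[(delta_r.regressor == regressor)
                  & (delta_r.channel.isin(channels))]
    table = (sub.groupby(["participant", "condition"])["delta_r"]
             .mean().unstack("condition"))
    return table


def _contrast(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Paired contrast: returns (mean, SE, p) of the weighted combination."""
    c = values @ weights
    n = len(c)
    mean = c.mean()
    se = c.std(ddof=1) / np.sqrt(n)
    t = mean / se if se > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(mean), float(se), float(p)


def rm_anova_2x2(values: pd.DataFrame, followup_on_interaction: bool = True,
                 ) -> list[AnovaResult]:
    """2x2 repeated-measures ANOVA from within-subject contrasts.

    ``values``: participants x 4 condition columns named
    'vision=<yes|no>/music=<same|different>'. Each 1-df effect F is the
    squared paired t of its contrast, with df (1, n-1). When the
    interaction is significant (p < 0.05), follow-up music contrasts within
    each vision level are attached (difference, SE, p).
    """
    cols = ["vision=yes/music=same", "vision=yes/music=different",
            "vision=no/music=same", "vision=no/music=different"]
    missing = [c for c in cols if c not in values.columns]
    if missing:
        raise ValueError(f"missing condition cells: {missing}")
    if values[cols].isna().any().any():
        raise ValueError("missing cells for some participants")
    v = values[cols].to_numpy(dtype=float)
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")

    contrasts = {
        "vision": np.array([0.5, 0.5, -0.5, -0.5]),
        "music": np.array([0.5, -0.5, 0.5, -0.5]),
        "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
    }
    results = []
    for effect, w in contrasts.items():
        c = v @ w
        mean = c.mean()
        var = c.var(ddof=1)
        F = (mean ** 2) * n / var if var > 0 else 0.0
        p = sps.f.sf(F, 1, n - 1)
        results.append(AnovaResult(effect=effect, F=float(F), df=(1, n - 1),
                                   p=float(p)))
    interaction = results[-1]
    if followup_on_interaction and interaction.p < 0.05:
        for level, w in (("music within vision=yes", np.array([1.0, -1.0, 0, 0])),
                         ("music within vision=no", np.array([0, 0, 1.0, -1.0]))):
            mean, se, p = _contrast(v, w)
            interaction.followups.append(
                {"contrast": level, "difference": mean, "se": se, "p": p})
    return results


def bonferroni(p: float, n_tests: int = 4) -> float:
    """Bonferroni-adjusted p, capped at 1."""
    return min(1.0, p * n_tests)


def anova_table(anovas: dict[str, list[AnovaResult]],
                n_tests: int = 4) -> pd.DataFrame:
    """Long results table over regressors, with family-corrected p values."""
    rows = []
    for regressor, results in anovas.items():
        for res in results:
            res.p_bonf = bonferroni(res.p, n_tests)
            rows.append((regressor, res.effect, res.F, res.df[0], res.df[1],
                         res.p, res.p_bonf))
    return pd.DataFrame(rows, columns=["regressor", "effect", "F", "df1",
                                       "df2", "p", "p_bonf"])
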