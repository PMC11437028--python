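"""Model–observation skill statistics in log10 space.

Biogeochemical quantities (Chl-a, Kd, bbp) are approximately log-normally
distributed, so model and observation are log10-transformed before the
indicators are computed:

    bias = mean(m − o)            m = log10(model), o = log10(obs)
    rmse = sqrt(mean((m − o)²))
    corr = Pearson(m, o)

Target-diagram coordinates place each matchup set in a plane whose y axis
is the normalised bias and whose x axis is the signed, normalised unbiased
RMSD (uRMSD² = mean(((m−m̄)−(o−ō))²); sign positive when the model spread
exceeds the observed spread).  Normalisation is by the standard deviation
of the log-transformed observations; population (ddof=0) moments are used
throughout so that bias² + uRMSD² = rmse² holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class SkillStats:
    """Log-space skill indicators plus target-diagram coordinates."""

    n: int
    bias: float           # log10 units
    rmse: float           # log10 units
    corr: float | None    # Pearson on log10 values; None if undefined
    bias_norm: float | None = None
    urmsd_signed_norm: float | None = None


def matchup(
    model: pd.Series, obs: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Pair daily model and observation series by date.

    Inner join on date; pairs where either value is non-positive (outside
    the log-transform domain) or non-finite are dropped and counted.
    Returns ``(pairs, n_dropped)`` with columns ``model`` and ``obs``.
    """
    pairs = pd.concat(
        {"model": model, "obs": obs}, axis=1, join="inner"
    ).astype(float)
    ok = (
        np.isfinite(pairs["model"])
        & np.isfinite(pairs["obs"])
        & (pairs["model"] > 0)
        & (pairs["obs"] > 0)
    )
    n_dropped = int((~ok).sum())
    return pairs[ok], n_dropped


def log_stats(pairs: pd.DataFrame) -> SkillStats:
    """Log10-space BIAS / RMSE / Pearson correlation for a matchup table."""
    if len(pairs) < 1:
        raise DataError("log_stats needs at least one matchup pair")
    m = np.log10(pairs["model"].to_numpy(dtype=float))
    o = np.log10(pairs["obs"].to_numpy(dtype=float))
    d = m - o
    bias = float(d.mean())
    rmse = float(np.sqrt((d**2).mean()))
    corr: float | None = None
    if len(pairs) >= 2:
        if m.std() == 0 or o.std() == 0:
            corr = None  # zero variance: correlation undefined
        else:
            corr = float(np.corrcoef(m, o)[0, 1])
    x, y = (None, None)
    if len(pairs) >= 2 and o.std() > 0:
        x, y = target_coords(pairs)
    return SkillStats(
        n=len(pairs), bias=bias, rmse=rmse, corr=corr,
        bias_norm=y, urmsd_signed_norm=x,
    )


def target_coords(pairs: pd.DataFrame) -> tuple[float, float]:
    """Target-diagram coordinates ``(x, y)`` on log10 data.

    y = bias/σ_obs;  x = sign(σ_model − σ_obs) · uRMSD/σ_obs.
    """
    if len(pairs) < 2:
        raise DataError("target_coords needs at least two pairs")
    m = np.log10(pairs["model"].to_numpy(dtype=float))
    o = np.log10(pairs["obs"].to_numpy(dtype=float))
    s_obs = o.std()  # population
    if s_obs == 0:
        raise DataError("zero observation variance in log space")
    bias = (m - o).mean()
    urmsd = np.sqrt((((m - m.mean()) - (o - o.mean())) ** 2).mean())
    sign = 1.0 if m.std() >= s_obs else -1.0
    return float(sign * urmsd / s_obs), float(bias / s_obs)
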