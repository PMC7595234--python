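"""Pixel screening: trend detection, disturbance exclusions, drought exposure.

Pixels whose EVI series shows a significant long-term monotone trend, or
that are marked disturbed (fire, insect outbreak) in the input mask, are
excluded before sensitivity attribution, so that S' reflects interannual
drought response rather than directional change. Cumulative drought
exposure — the percent of years in a reference period with SPEI at or below
a cutoff — is computed here as a landscape predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ScreenConfig",
    "MannKendallResult",
    "mann_kendall_trend",
    "trend_flags",
    "apply_exclusions",
    "drought_exposure",
]


@dataclass(frozen=True)
class ScreenConfig:
    trend_alpha: float = 0.05
    trend_test: str = "mann-kendall"
    exposure_period: tuple[int, int] = (1990, 2016)
    exposure_timescale: int = 12
    exposure_threshold: float = -1.0  # SPEI cutoff: any drought

    def __post_init__(self) -> None:
        if not 0 < self.trend_alpha < 1:
            raise ValueError("trend_alpha must lie in (0, 1)")
        if self.trend_test != "mann-kendall":
            raise ValueError(f"unsupported trend test {self.trend_test!r}")


@dataclass(frozen=True)
class MannKendallResult:
    s: int
    var_s: float
    z: float
    p_value: float
    sen_slope: float
    trend_flag: bool


def mann_kendall_trend(x: np.ndarray, alpha: float = 0.05) -> MannKendallResult:
    """Mann-Kendall monotone-trend test with Sen slope.

    S = sum_{i<j} sign(x_j - x_i); Var(S) uses the tie correction
    n(n-1)(2n+5)/18 - sum_t t(t-1)(2t+5)/18 over tie groups; Z applies the
    +/-1 continuity correction; the p-value is two-sided standard normal.
    Sen slope is the median of all pairwise slopes (x_j - x_i)/(j - i).

    Requires at least 8 observations (the normal approximation is poor
    below that).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"Mann-Kendall requires >= 8 years, got {n}")
    diff = x[None, :] - x[:, None]  # diff[i, j] = x_j - x_i
    iu = np.triu_indices(n, k=1)
    pair_diffs = diff[iu]
    s = int(np.sign(pair_diffs).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    if var_s <= 0:  # all values tied
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * norm.sf(abs(z))

    lag = (iu[1] - iu[0]).astype(float)
    sen = float(np.median(pair_diffs / lag))
    return MannKendallResult(s, float(var_s), float(z), float(p), sen, bool(p < alpha))


def trend_flags(
    evi: pd.DataFrame, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Run the trend test on every pixel's annual EVI series.

    Returns columns pixel_id, s, z, p_value, sen_slope, trend_flag.
    """
    cfg = config or ScreenConfig()
    rows = []
    for pid, grp in evi.sort_values("year").groupby("pixel_id", sort=True):
        r = mann_kendall_trend(grp["evi_summer"].to_numpy(), cfg.trend_alpha)
        rows.append((pid, r.s, r.z, r.p_value, r.sen_slope, r.trend_flag))
    return pd.DataFrame(
        rows, columns=["pixel_id", "s", "z", "p_value", "sen_slope", "trend_flag"]
    )


def apply_exclusions(
    pixels: pd.DataFrame,
    disturbed: pd.Series | pd.DataFrame,
    trending: pd.Series | pd.DataFrame,
    allowed_landcover: set | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop disturbed, trending, and off-landcover pixels.

    ``disturbed`` / ``trending`` are boolean Series indexed by pixel_id (or
    DataFrames with pixel_id + flag columns). A pixel excluded by several
    rules is attributed to the first matching rule, in the order
    disturbed -> trend -> landcover. Returns (retained pixels, ledger).
    """
    dist = _as_flag_series(disturbed, "disturbed_flag")
    trend = _as_flag_series(trending, "trend_flag")
    pid = pixels["pixel_id"]
    missing = pid[~pid.isin(dist.index)].tolist() + pid[~pid.isin(trend.index)].tolist()
    if missing:
        raise ValueError(f"mask/flags missing pixel ids: {sorted(set(missing))[:10]}")
    is_dist = dist.reindex(pid).to_numpy(dtype=bool)
    is_trend = trend.reindex(pid).to_numpy(dtype=bool)
    if allowed_landcover is not None:
        bad_lc = ~pixels["landcover"].isin(allowed_landcover).to_numpy()
    else:
        bad_lc = np.zeros(len(pixels), dtype=bool)

    reason = np.select(
        [is_dist, is_trend, bad_lc], ["disturbed", "trend", "landcover"], default="retained"
    )
    retained = pixels[reason == "retained"].reset_index(drop=True)
    ledger = {
        "disturbed": int((reason == "disturbed").sum()),
        "trend": int((reason == "trend").sum()),
        "landcover": int((reason == "landcover").sum()),
        "retained": len(retained),
    }
    return retained, ledger


def _as_flag_series(obj: pd.Series | pd.DataFrame, col: str) -> pd.Series:
    if isinstance(obj, pd.DataFrame):
        return obj.set_index("pixel_id")[col]
    return obj


def drought_exposure(
    spei: pd.DataFrame, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Percent of years in the exposure period with SPEI <= threshold.

    Uses the configured timescale (default the 12-month, August-anchored
    SPEI at threshold -1, i.e. any drought year counts).

    Returns columns pixel_id, drought_exp.
    """
    cfg = config or ScreenConfig()
    lo, hi = cfg.exposure_period
    sub = spei[
        (spei["timescale"] == cfg.exposure_timescale)
        & (spei["year"] >= lo)
        & (spei["year"] <= hi)
    ]
    if sub.empty:
        raise ValueError(
            f"SPEI table does not cover timescale {cfg.exposure_timescale} "
            f"over {lo}-{hi}"
        )
    span = sub.groupby("pixel_id")["year"].agg(["min", "max", "count"])
    bad = span[(span["min"] > lo) | (span["max"] < hi)]
    if not bad.empty:
        raise ValueError(
            f"exposure period {lo}-{hi} not covered for pixels "
            f"{bad.index.tolist()[:10]}"
        )
    frac = sub.assign(hit=sub["spei"] <= cfg.exposure_threshold).groupby("pixel_id")["hit"].mean()
    return pd.DataFrame(
        {"pixel_id": frac.index.to_numpy(), "drought_exp": 100.0 * frac.to_numpy()}
    )
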