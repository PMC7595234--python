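"""Multi-timescale SPEI computation and drought classification.

The Standardized Precipitation-Evapotranspiration Index (SPEI) transforms a
k-month aggregated climatic water balance (precipitation minus potential
evapotranspiration, mm) into standard-normal units, so that droughts of a
given severity are comparable across locations with different climatologies.
Annual values are anchored at a configurable end month (default August) so
that the 3-month timescale covers the June-August growing season, the
6-month timescale winter-through-summer, and the 12-month timescale the
entire antecedent year.

Drought classes partition the SPEI axis:

    severe    SPEI <= -1.5
    moderate  -1.5 < SPEI <= -1
    baseline  -1 < SPEI < 1
    pluvial   SPEI >= 1
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SpeiConfig",
    "DroughtThresholds",
    "water_balance",
    "aggregate_balance",
    "standardize",
    "classify",
    "compute_spei",
]

_CLASSES = ("pluvial", "baseline", "moderate", "severe")


@dataclass(frozen=True)
class DroughtThresholds:
    """SPEI cutoffs delimiting the four drought classes.

    Dry-side boundaries are inclusive (``<=``): SPEI of exactly -1 is
    moderate drought and exactly -1.5 is severe. ``baseline_high`` is
    inclusive on the pluvial side (SPEI >= 1 is pluvial).
    """

    baseline_low: float = -1.0
    baseline_high: float = 1.0
    severe_max: float = -1.5

    def __post_init__(self) -> None:
        if not (self.severe_max < self.baseline_low < self.baseline_high):
            raise ValueError(
                "thresholds must satisfy severe_max < baseline_low < baseline_high; "
                f"got {self.severe_max}, {self.baseline_low}, {self.baseline_high}"
            )


@dataclass(frozen=True)
class SpeiConfig:
    """Configuration for annual multi-timescale SPEI.

    Parameters
    ----------
    timescales : tuple of int
        Antecedent aggregation windows in months, each in 1..48.
    end_month : int
        Calendar month (1-12) at which each annual window ends.
    calibration_period : (int, int) or None
        Inclusive year range used to fit the standardizing distribution;
        ``None`` uses the full record of each pixel.
    method : {"log-logistic", "empirical"}
        Standardization: a three-parameter log-logistic distribution fitted
        by unbiased probability-weighted moments, or Gringorten plotting
        positions. A failed log-logistic fit falls back to empirical with a
        warning.
    min_calibration_years : int
        Minimum calibration sample size for standardization.
    """

    timescales: tuple[int, ...] = (3, 6, 12)
    end_month: int = 8
    calibration_period: tuple[int, int] | None = None
    method: str = "log-logistic"
    min_calibration_years: int = 20
    thresholds: DroughtThresholds = field(default_factory=DroughtThresholds)

    def __post_init__(self) -> None:
        if not self.timescales:
            raise ValueError("at least one timescale is required")
        if any(k < 1 or k > 48 for k in self.timescales):
            raise ValueError(f"timescales must lie in 1..48, got {self.timescales}")
        if not 1 <= self.end_month <= 12:
            raise ValueError(f"end_month must be in 1..12, got {self.end_month}")
        if self.method not in ("log-logistic", "empirical"):
            raise ValueError(f"unknown method {self.method!r}")


def water_balance(climate: pd.DataFrame) -> pd.DataFrame:
    """Monthly climatic water balance D = precipitation - PET (mm).

    Parameters
    ----------
    climate : DataFrame
        Long table with columns pixel_id, year, month, precipitation, pet.
        Each pixel must have complete monthly coverage over its record.

    Returns
    -------
    DataFrame with columns pixel_id, year, month, d.
    """
    required = {"pixel_id", "year", "month", "precipitation", "pet"}
    missing_cols = required - set(climate.columns)
    if missing_cols:
        raise ValueError(f"climate table missing columns: {sorted(missing_cols)}")
    _check_monthly_coverage(climate)
    out = climate[["pixel_id", "year", "month"]].copy()
    out["d"] = climate["precipitation"].to_numpy() - climate["pet"].to_numpy()
    return out


def _check_monthly_coverage(climate: pd.DataFrame) -> None:
    """Raise with a gap listing if any pixel has missing months."""
    gaps: list[str] = []
    for pid, grp in climate.groupby("pixel_id", sort=False):
        t = (grp["year"].to_numpy() * 12 + (grp["month"].to_numpy() - 1)).astype(np.int64)
        t = np.sort(t)
        if t.size == 0:
            gaps.append(f"pixel {pid}: empty record")
            continue
        expected = np.arange(t[0], t[-1] + 1)
        if t.size != expected.size or not np.array_equal(t, expected):
            missing = np.setdiff1d(expected, t)
            labels = [f"{m // 12}-{m % 12 + 1:02d}" for m in missing[:6]]
            gaps.append(f"pixel {pid}: missing months {labels}" + (" ..." if missing.size > 6 else ""))
        if len(gaps) >= 10:
            break
    if gaps:
        raise ValueError("incomplete monthly coverage: " + "; ".join(gaps))


def aggregate_balance(
    d: pd.DataFrame, timescale: int, end_month: int = 8
) -> pd.DataFrame:
    """Aggregate the monthly balance over the k months ending at ``end_month``.

    The value for year *y* is the sum of D over the ``timescale`` months
    ending at ``end_month`` of year *y* (windows longer than ``end_month``
    reach into preceding calendar years). Years whose window is not fully
    covered by the record are omitted with a logged warning.

    Returns
    -------
    DataFrame with columns pixel_id, year, balance.
    """
    if timescale < 1:
        raise ValueError("timescale must be >= 1")
    wide = d.pivot_table(index=["year", "month"], columns="pixel_id", values="d", sort=True)
    # reindex onto a contiguous monthly axis so rolling windows align
    years = wide.index.get_level_values(0)
    t0 = int(years.min()) * 12
    t1 = (int(years.max()) + 1) * 12
    tidx = np.arange(t0, t1)
    full = pd.MultiIndex.from_arrays([tidx // 12, tidx % 12 + 1], names=["year", "month"])
    wide = wide.reindex(full)
    rolled = wide.rolling(window=timescale, min_periods=timescale).sum()
    at_end = rolled.xs(end_month, level="month")
    at_end = at_end.dropna(how="all")
    n_dropped = rolled.xs(end_month, level="month").shape[0] - at_end.shape[0]
    if n_dropped:
        logger.warning(
            "aggregate_balance: %d year(s) omitted (insufficient %d-month history)",
            n_dropped,
            timescale,
        )
    out = (
        at_end.stack()
        .rename("balance")
        .reset_index()
        .rename(columns={"level_1": "pixel_id"})
    )
    out = out[["pixel_id", "year", "balance"]].sort_values(["pixel_id", "year"])
    if out["balance"].isna().any():
        out = out.dropna(subset=["balance"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# standardization


def _unbiased_pwm(x_sorted: np.ndarray, s: int) -> float:
    """Unbiased probability-weighted moment W_s = E[X (1-F)^s].

    ``x_sorted`` ascending. Estimator (1/n) sum_i x_(i) C(n-i, s)/C(n-1, s).
    """
    n = x_sorted.size
    i = np.arange(1, n + 1)
    if s == 0:
        w = np.ones(n)
    else:
        # C(n-i, s)/C(n-1, s) as a product of ratios, zero when n-i < s
        w = np.ones(n)
        for j in range(s):
            w *= np.clip(n - i - j, 0, None) / (n - 1 - j)
    return float(np.mean(w * x_sorted))


def _fit_log_logistic(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic CDF F(v)=[1+(alpha/(v-gamma))^beta]^-1.

    Probability-weighted-moment estimators; raises ValueError when the
    moment system has no valid solution (beta <= 1 or alpha <= 0).
    """
    xs = np.sort(x)
    w0 = _unbiased_pwm(xs, 0)
    w1 = _unbiased_pwm(xs, 1)
    w2 = _unbiased_pwm(xs, 2)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        raise ValueError("degenerate PWM system")
    beta = (2.0 * w1 - w0) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        raise ValueError(f"log-logistic shape out of range (beta={beta:.3g})")
    g1 = _gamma_fn(1.0 + 1.0 / beta) * _gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g1
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"log-logistic scale out of range (alpha={alpha:.3g})")
    gamma_loc = w0 - alpha * g1
    return alpha, beta, gamma_loc


def _loglogistic_cdf(v: np.ndarray, alpha: float, beta: float, gamma_loc: float) -> np.ndarray:
    z = v - gamma_loc
    out = np.empty_like(v, dtype=float)
    pos = z > 0
    out[pos] = 1.0 / (1.0 + (alpha / z[pos]) ** beta)
    out[~pos] = 0.0
    return out


def _gringorten_cdf(calibration: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Empirical CDF through Gringorten plotting positions.

    Calibration values receive p_i = (r_i - 0.44)/(n + 0.12); other values
    are placed by monotone linear interpolation (extrapolated at the ends so
    the mapping stays strictly increasing).
    """
    xs, inv_counts = np.unique(calibration, return_counts=True)
    n = calibration.size
    # mean rank of each distinct value
    ranks_hi = np.cumsum(inv_counts)
    ranks = ranks_hi - (inv_counts - 1) / 2.0
    p = (ranks - 0.44) / (n + 0.12)
    if xs.size == 1:
        raise ValueError("degenerate (zero-variance) series")
    slope_lo = (p[1] - p[0]) / (xs[1] - xs[0])
    slope_hi = (p[-1] - p[-2]) / (xs[-1] - xs[-2])
    out = np.interp(v, xs, p)
    below = v < xs[0]
    above = v > xs[-1]
    out[below] = p[0] + slope_lo * (v[below] - xs[0])
    out[above] = p[-1] + slope_hi * (v[above] - xs[-1])
    return np.clip(out, 1e-6, 1.0 - 1e-6)


def standardize(
    balance: np.ndarray,
    calibration: np.ndarray | None = None,
    method: str = "log-logistic",
    min_calibration_years: int = 20,
) -> np.ndarray:
    """Map aggregated water-balance values to SPEI (standard-normal units).

    Parameters
    ----------
    balance : array
        Annual aggregated balances to standardize.
    calibration : array, optional
        Values used to fit the distribution; defaults to ``balance`` itself.
    method : {"log-logistic", "empirical"}

    Returns
    -------
    Array of SPEI values, strictly increasing in the balance.
    """
    v = np.asarray(balance, dtype=float)
    cal = v if calibration is None else np.asarray(calibration, dtype=float)
    cal = cal[np.isfinite(cal)]
    if cal.size < min_calibration_years:
        raise ValueError(
            f"calibration sample of {cal.size} < required {min_calibration_years} years"
        )
    if np.ptp(cal) == 0:
        raise ValueError("degenerate (zero-variance) calibration series")
    if method == "log-logistic":
        try:
            alpha, beta, gamma_loc = _fit_log_logistic(cal)
            f = _loglogistic_cdf(v, alpha, beta, gamma_loc)
            f = np.clip(f, 1e-6, 1.0 - 1e-6)
        except ValueError as exc:
            logger.debug("log-logistic fit failed: %s", exc)
            warnings.warn(
                "log-logistic fit failed; falling back to empirical plotting positions",
                RuntimeWarning,
                stacklevel=2,
            )
            f = _gringorten_cdf(cal, v)
    elif method == "empirical":
        f = _gringorten_cdf(cal, v)
    else:
        raise ValueError(f"unknown method {method!r}")
    return norm.ppf(f)


def classify(
    spei: np.ndarray | float, thresholds: DroughtThresholds | None = None
) -> np.ndarray | str:
    """Assign drought classes; see module docstring for the partition."""
    th = thresholds or DroughtThresholds()
    arr = np.asarray(spei, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("classify: NaN SPEI value(s)")
    out = np.select(
        [arr <= th.severe_max, arr <= th.baseline_low, arr < th.baseline_high],
        ["severe", "moderate", "baseline"],
        default="pluvial",
    )
    if np.isscalar(spei):
        return str(out[()])
    return out


def compute_spei(climate: pd.DataFrame, config: SpeiConfig | None = None) -> pd.DataFrame:
    """Full SPEI table from a monthly climate table.

    Runs water balance -> k-month aggregation -> standardization ->
    classification for every configured timescale.

    Returns
    -------
    DataFrame with columns pixel_id, year, timescale, spei, drought_class.
    """
    cfg = config or SpeiConfig()
    d = water_balance(climate)
    pieces = []
    for k in cfg.timescales:
        agg = aggregate_balance(d, k, cfg.end_month)
        for pid, grp in agg.groupby("pixel_id", sort=False):
            vals = grp["balance"].to_numpy()
            years = grp["year"].to_numpy()
            if cfg.calibration_period is not None:
                lo, hi = cfg.calibration_period
                cal = vals[(years >= lo) & (years <= hi)]
            else:
                cal = vals
            spei = standardize(vals, cal, cfg.method, cfg.min_calibration_years)
            pieces.append(
                pd.DataFrame(
                    {
                        "pixel_id": pid,
                        "year": years,
                        "timescale": k,
                        "spei": spei,
                        "drought_class": classify(spei, cfg.thresholds),
                    }
                )
            )
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["pixel_id", "timescale", "year"]).reset_index(drop=True)
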