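"""Per-pixel drought sensitivity S' from summer EVI and SPEI drought classes.

Drought sensitivity is the percent decrease of summer vegetation greenness
in drought-classified years relative to baseline (non-drought, non-pluvial)
years:

    S' = 100 * (EVI_baseline - EVI_drought) / EVI_baseline

computed separately for moderate and severe drought at each SPEI timescale,
then maximized across timescales. Negative values (greening under drought)
are retained. Each timescale uses its own baseline-year set by default,
since its classification of years differs; a shared baseline restricted to
years that are baseline under every timescale is available by config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityConfig",
    "baseline_evi",
    "timescale_sensitivity",
    "max_sensitivity",
    "sensitivity_table",
]


@dataclass(frozen=True)
class SensitivityConfig:
    """Thresholds and conventions for the S' computation.

    min_baseline_years / min_drought_years are the smallest year counts for
    a valid baseline mean and drought-class mean (records of ~17 years make
    stricter drought minima too lossy). ``stat`` selects the central
    tendency; ``shared_baseline`` pools the baseline over years classified
    baseline at every timescale instead of per-timescale sets.
    """

    timescales: tuple[int, ...] = (3, 6, 12)
    min_baseline_years: int = 3
    min_drought_years: int = 1
    stat: str = "mean"  # or "median"
    shared_baseline: bool = False

    def __post_init__(self) -> None:
        if self.stat not in ("mean", "median"):
            raise ValueError(f"stat must be 'mean' or 'median', got {self.stat!r}")
        if self.min_baseline_years < 1 or self.min_drought_years < 1:
            raise ValueError("year minima must be >= 1")


def _merge(evi: pd.DataFrame, spei: pd.DataFrame, timescale: int) -> pd.DataFrame:
    sub = spei[spei["timescale"] == timescale]
    if sub.empty:
        raise ValueError(f"SPEI table has no rows for timescale {timescale}")
    merged = evi.merge(sub[["pixel_id", "year", "drought_class"]], on=["pixel_id", "year"])
    if merged.empty:
        raise ValueError("EVI and SPEI tables share no pixel-years")
    return merged


def _class_stat(merged: pd.DataFrame, drought_class: str, stat: str) -> pd.DataFrame:
    sub = merged[merged["drought_class"] == drought_class]
    g = sub.groupby("pixel_id")["evi_summer"]
    out = g.agg(value=stat, n="count")
    return out


def baseline_evi(
    evi: pd.DataFrame,
    spei: pd.DataFrame,
    timescale: int,
    min_baseline_years: int = 3,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-pixel baseline EVI: central tendency over baseline-class years.

    Returns columns pixel_id, baseline_evi, n_baseline_years, valid. Pixels
    with fewer than ``min_baseline_years`` baseline years are flagged
    invalid (baseline_evi NaN).
    """
    merged = _merge(evi, spei, timescale)
    stats = _class_stat(merged, "baseline", stat)
    all_pixels = merged["pixel_id"].unique()
    stats = stats.reindex(all_pixels, fill_value=0)
    valid = stats["n"] >= min_baseline_years
    return pd.DataFrame(
        {
            "pixel_id": stats.index.to_numpy(),
            "baseline_evi": np.where(valid, stats["value"], np.nan),
            "n_baseline_years": stats["n"].astype(int).to_numpy(),
            "valid": valid.to_numpy(),
        }
    ).reset_index(drop=True)


def timescale_sensitivity(
    evi: pd.DataFrame,
    spei: pd.DataFrame,
    timescale: int,
    drought_class: str,
    config: SensitivityConfig | None = None,
) -> pd.DataFrame:
    """S' (percent) at one timescale for one drought class.

    Returns columns pixel_id, s_prime, n_drought_years, baseline_evi, valid.
    Invalid where the baseline is invalid or non-positive, or where the
    pixel has fewer than ``min_drought_years`` years of the class.
    """
    if drought_class not in ("moderate", "severe"):
        raise ValueError("drought_class must be 'moderate' or 'severe'")
    cfg = config or SensitivityConfig()
    base = baseline_evi(evi, spei, timescale, cfg.min_baseline_years, cfg.stat)
    merged = _merge(evi, spei, timescale)
    dr = _class_stat(merged, drought_class, cfg.stat).reindex(base["pixel_id"], fill_value=0)
    b = base["baseline_evi"].to_numpy()
    valid = base["valid"].to_numpy() & (b > 0) & (dr["n"].to_numpy() >= cfg.min_drought_years)
    s = np.where(valid, 100.0 * (b - dr["value"].to_numpy()) / b, np.nan)
    return pd.DataFrame(
        {
            "pixel_id": base["pixel_id"],
            "s_prime": s,
            "n_drought_years": dr["n"].astype(int).to_numpy(),
            "baseline_evi": b,
            "valid": valid,
        }
    )


def max_sensitivity(per_timescale: dict[int, pd.Series]) -> pd.DataFrame:
    """Maximum S' across timescales, recording the attaining timescale.

    ``per_timescale`` maps timescale -> Series of S' indexed by pixel_id
    (NaN = invalid). Rows with no valid timescale are flagged invalid.
    """
    wide = pd.DataFrame(per_timescale)
    valid = wide.notna().any(axis=1)
    s_max = wide.max(axis=1)
    at = pd.Series(np.nan, index=wide.index, dtype=float)
    if valid.any():
        at[valid] = wide.loc[valid].idxmax(axis=1)
    return pd.DataFrame(
        {
            "pixel_id": wide.index.to_numpy(),
            "s_max": s_max.where(valid).to_numpy(),
            "timescale": at.to_numpy(),
            "valid": valid.to_numpy(),
        }
    ).reset_index(drop=True)


def sensitivity_table(
    evi: pd.DataFrame,
    spei: pd.DataFrame,
    config: SensitivityConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full per-pixel sensitivity table plus an exclusion summary.

    One row per pixel present in both inputs, with per-timescale baseline
    EVI, S'_mod and S'_sev columns (suffix ``_<k>``), the across-timescale
    maxima, the attaining timescales, and validity flags. The summary counts
    pixels whose S'_mod or S'_sev could not be computed at any timescale.
    """
    cfg = config or SensitivityConfig()
    pixel_ids = np.sort(evi["pixel_id"].unique())
    out = pd.DataFrame({"pixel_id": pixel_ids}).set_index("pixel_id")

    shared_base: pd.DataFrame | None = None
    if cfg.shared_baseline:
        shared_base = _shared_baseline(evi, spei, cfg)

    per_mod: dict[int, pd.Series] = {}
    per_sev: dict[int, pd.Series] = {}
    for k in cfg.timescales:
        base = baseline_evi(evi, spei, k, cfg.min_baseline_years, cfg.stat).set_index("pixel_id")
        if shared_base is not None:
            base = shared_base
        out[f"baseline_evi_{k}"] = base["baseline_evi"]
        out[f"n_baseline_{k}"] = base["n_baseline_years"].reindex(out.index).fillna(0).astype(int)
        for cls, store in (("moderate", per_mod), ("severe", per_sev)):
            st = timescale_sensitivity(evi, spei, k, cls, cfg).set_index("pixel_id")
            if shared_base is not None:
                merged = _merge(evi, spei, k)
                dr = _class_stat(merged, cls, cfg.stat).reindex(base.index, fill_value=0)
                b = base["baseline_evi"].to_numpy()
                v = base["valid"].to_numpy() & (b > 0) & (dr["n"].to_numpy() >= cfg.min_drought_years)
                st = pd.DataFrame(
                    {
                        "s_prime": np.where(v, 100.0 * (b - dr["value"].to_numpy()) / b, np.nan),
                        "n_drought_years": dr["n"].astype(int).to_numpy(),
                        "valid": v,
                    },
                    index=base.index,
                )
            tag = "mod" if cls == "moderate" else "sev"
            out[f"s_{tag}_{k}"] = st["s_prime"]
            out[f"n_{tag}_{k}"] = st["n_drought_years"].reindex(out.index).fillna(0).astype(int)
            store[k] = st["s_prime"].reindex(out.index)

    for tag, store in (("mod", per_mod), ("sev", per_sev)):
        mx = max_sensitivity(store).set_index("pixel_id")
        out[f"s_{tag}_max"] = mx["s_max"]
        out[f"s_{tag}_max_timescale"] = mx["timescale"]
        out[f"valid_{tag}"] = mx["valid"].reindex(out.index).fillna(False)

    summary = {
        "n_pixels": len(out),
        "n_invalid_mod": int((~out["valid_mod"]).sum()),
        "n_invalid_sev": int((~out["valid_sev"]).sum()),
    }
    if summary["n_invalid_mod"] or summary["n_invalid_sev"]:
        logger.info("sensitivity_table exclusions: %s", summary)
    return out.reset_index(), summary


def _shared_baseline(
    evi: pd.DataFrame, spei: pd.DataFrame, cfg: SensitivityConfig
) -> pd.DataFrame:
    """Baseline over years classified baseline under every timescale."""
    sub = spei[spei["timescale"].isin(cfg.timescales)]
    is_base = (
        sub.assign(b=sub["drought_class"] == "baseline")
        .groupby(["pixel_id", "year"])["b"]
        .all()
        .reset_index()
    )
    merged = evi.merge(is_base, on=["pixel_id", "year"])
    stats = (
        merged[merged["b"]]
        .groupby("pixel_id")["evi_summer"]
        .agg(value=cfg.stat, n="count")
    )
    all_pixels = np.sort(evi["pixel_id"].unique())
    stats = stats.reindex(all_pixels, fill_value=0)
    valid = stats["n"] >= cfg.min_baseline_years
    return pd.DataFrame(
        {
            "baseline_evi": np.where(valid, stats["value"], np.nan),
            "n_baseline_years": stats["n"].astype(int),
            "valid": valid,
        },
        index=stats.index.rename("pixel_id"),
    )
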