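"""Summary statistics of drought-sensitivity results by biome and ecosystem.

Medians and interquartile ranges of S'_mod and S'_sev per biome, the rank
correlation between the two sensitivities, the fraction of pixels more
sensitive to severe than to moderate drought (with the mean positive
excess), per-ecosystem medians/IQRs, and the pixel-level table assigning
each pixel its ecosystem median. Quantiles use linear (type-7)
interpolation throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = ["biome_summary", "ecosystem_summary", "density_table"]


def _q(x: np.ndarray, p: float) -> float:
    return float(np.quantile(x, p))  # linear (type-7) interpolation


def biome_summary(sens: pd.DataFrame, biomes: pd.DataFrame) -> pd.DataFrame:
    """Per-biome summary of maximal drought sensitivities.

    ``sens`` is a sensitivity table with s_mod_max / s_sev_max and validity
    flags; ``biomes`` maps pixel_id -> biome. Rows where either statistic
    is invalid are omitted from the paired comparisons. Empty biomes are
    skipped with a warning.

    Returns one row per biome: medians and IQR bounds of S'_mod and S'_sev,
    Spearman correlation between them, the fraction of pixels with
    s_sev_max > s_mod_max, the mean positive excess (percentage points),
    and the fraction of pixels with declining EVI under each intensity.
    """
    df = sens.drop(columns=["biome"], errors="ignore").merge(
        biomes[["pixel_id", "biome"]], on="pixel_id"
    )
    rows = []
    for biome, grp in df.groupby("biome", sort=True):
        both = grp[grp["valid_mod"] & grp["valid_sev"]]
        if both.empty:
            logger.warning("biome %r has no valid pixels; omitted", biome)
            continue
        mod = both["s_mod_max"].to_numpy()
        sev = both["s_sev_max"].to_numpy()
        excess = sev - mod
        pos = excess[excess > 0]
        if len(both) > 1 and np.ptp(mod) > 0 and np.ptp(sev) > 0:
            rho = float(spearmanr(mod, sev)[0])
        else:
            rho = np.nan
        rows.append(
            {
                "biome": biome,
                "n_pixels": len(both),
                "median_s_mod": _q(mod, 0.5),
                "iqr_lo_s_mod": _q(mod, 0.25),
                "iqr_hi_s_mod": _q(mod, 0.75),
                "median_s_sev": _q(sev, 0.5),
                "iqr_lo_s_sev": _q(sev, 0.25),
                "iqr_hi_s_sev": _q(sev, 0.75),
                "spearman_mod_sev": rho,
                "frac_sev_gt_mod": float((excess > 0).mean()),
                "mean_excess_sev": float(pos.mean()) if pos.size else np.nan,
                "frac_declining_mod": float((mod > 0).mean()),
                "frac_declining_sev": float((sev > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def ecosystem_summary(
    sens: pd.DataFrame, ecosystems: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ecosystem medians/IQRs plus the pixel-level median-assignment table.

    ``ecosystems`` maps pixel_id -> ecosystem code. Every pixel must carry a
    known ecosystem code. The second return value assigns each labeled
    pixel its ecosystem's median sensitivities (the map-product analogue).
    """
    if ecosystems["ecosystem"].isna().any():
        raise ValueError("unknown (missing) ecosystem code for some pixels")
    df = sens.drop(columns=["ecosystem"], errors="ignore").merge(
        ecosystems[["pixel_id", "ecosystem"]], on="pixel_id"
    )
    base_col = next(
        (c for c in df.columns if c.startswith("baseline_evi")), None
    )
    rows = []
    for eco, grp in df.groupby("ecosystem", sort=True):
        row = {"ecosystem": eco, "n_pixels": len(grp)}
        for col, tag in ((base_col, "baseline_evi"), ("s_mod_max", "s_mod"), ("s_sev_max", "s_sev")):
            if col is None:
                continue
            v = grp[col].dropna().to_numpy()
            if v.size:
                row[f"median_{tag}"] = _q(v, 0.5)
                row[f"iqr_lo_{tag}"] = _q(v, 0.25)
                row[f"iqr_hi_{tag}"] = _q(v, 0.75)
            else:
                row[f"median_{tag}"] = np.nan
                row[f"iqr_lo_{tag}"] = np.nan
                row[f"iqr_hi_{tag}"] = np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    assigned = df[["pixel_id", "ecosystem"]].merge(
        summary[["ecosystem", "median_s_mod", "median_s_sev"]], on="ecosystem"
    )
    return summary, assigned


def density_table(
    sens: pd.DataFrame, bins: int = 50, value_range: tuple[float, float] | None = None
) -> pd.DataFrame:
    """2-D histogram of s_mod_max vs s_sev_max (density-plot data).

    Returns a long table with bin centers and counts.
    """
    both = sens[sens["valid_mod"] & sens["valid_sev"]]
    mod = both["s_mod_max"].to_numpy()
    sev = both["s_sev_max"].to_numpy()
    if value_range is None:
        lo = float(min(mod.min(), sev.min()))
        hi = float(max(mod.max(), sev.max()))
        value_range = (lo, hi)
    h, xe, ye = np.histogram2d(mod, sev, bins=bins, range=[value_range, value_range])
    xc = (xe[:-1] + xe[1:]) / 2
    yc = (ye[:-1] + ye[1:]) / 2
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame(
        {"s_mod_center": xx.ravel(), "s_sev_center": yy.ravel(), "count": h.ravel().astype(int)}
    )
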