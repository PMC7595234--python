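"""Synthetic landscapes, climates, and EVI series with known truth.

Emulates the statistical structure the drought-sensitivity analysis assumes,
so every downstream stage can be verified against injected truth:

* spatially autocorrelated landscape covariates on a regular 1-km grid, with
  a 30-m-style subgrid of heat-load index (HLI) and landcover per pixel for
  the shade-density / majority-landcover / mean-CTI aggregation;
* seasonal monthly precipitation (gamma-distributed) and PET (sinusoid plus
  noise), with optional forced-drought years;
* summer-mean EVI generated as a multiplicative reduction of a per-pixel
  baseline in drought-classified years, with log-normal noise, plus injected
  step disturbances and linear trends in configurable pixel subsets.

The injected moderate-drought sensitivity is a linear function of
standardized covariates (elevation and soil bulk density dominant by
default), clipped to [0, s_mod_cap]; severe sensitivity is an affine
amplification of moderate sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LandscapeConfig",
    "BiomeRule",
    "SensitivityRule",
    "ClimateConfig",
    "Landscape",
    "generate_landscape",
    "aggregate_subgrid",
    "make_truth",
    "generate_climate",
    "generate_evi",
    "make_attribution_dataset",
]

#: covariate -> (min, max) in native units
DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "elev": (0.0, 3000.0),  # m
    "aet": (200.0, 800.0),  # mm
    "deficit": (0.0, 800.0),  # mm
    "soil_awc": (0.05, 0.35),  # volumetric fraction
    "soil_bd": (800.0, 1800.0),  # kg/m^3
    "wtd": (1.0, 50.0),  # m
    "cti": (3.0, 12.0),  # unitless
    "hli": (0.3, 1.0),  # unitless
}

#: ecosystem code -> label (forest codes 1-3, shrub-steppe codes 4-5)
ECOSYSTEM_LABELS = {
    1: "lowland_conifer",
    2: "mixed_conifer",
    3: "subalpine_conifer",
    4: "big_sagebrush",
    5: "montane_sagebrush",
}

FOREST = "forest"
SHRUB_STEPPE = "shrub-steppe"


@dataclass(frozen=True)
class BiomeRule:
    """Deficit/elevation thresholds assigning biome and ecosystem codes.

    Pixels with climatic water deficit above ``shrub_deficit_threshold`` are
    shrub-steppe, others forest. Within each biome, elevation thresholds
    split ecosystems (three forest, two shrub-steppe types).
    """

    shrub_deficit_threshold: float = 450.0  # mm
    forest_elev_breaks: tuple[float, float] = (800.0, 1800.0)  # m
    shrub_elev_break: float = 1400.0  # m

    def assign(self, deficit: np.ndarray, elev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        shrub = deficit > self.shrub_deficit_threshold
        biome = np.where(shrub, SHRUB_STEPPE, FOREST)
        eco = np.where(
            shrub,
            np.where(elev > self.shrub_elev_break, 5, 4),
            np.select(
                [elev > self.forest_elev_breaks[1], elev > self.forest_elev_breaks[0]],
                [3, 2],
                default=1,
            ),
        )
        return biome, eco.astype(int)


@dataclass(frozen=True)
class LandscapeConfig:
    n_rows: int = 50
    n_cols: int = 50
    smoothing_length: float = 5.0  # correlation scale, pixels; 0 -> iid
    subgrid_size: int = 33  # ~30-m cells per 1-km pixel
    covariate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES)
    )
    biome_rule: BiomeRule = field(default_factory=BiomeRule)
    hli_subgrid_sd: float = 0.15  # within-pixel HLI variability
    landcover_minority_frac: float = 0.1  # off-type 30-m cells per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.subgrid_size < 1:
            raise ValueError("subgrid_size must be >= 1")
        for name, (lo, hi) in self.covariate_ranges.items():
            if lo > hi:
                raise ValueError(f"covariate {name!r}: min {lo} > max {hi}")


@dataclass
class Landscape:
    """A generated landscape: pixel table plus 30-m-style subgrids.

    ``pixels`` holds one row per 1-km pixel with all predictors, including
    the subgrid-aggregated shade density, majority landcover, and mean CTI.
    Subgrid arrays have shape (n_pixels, subgrid_size, subgrid_size), in
    pixel_id order.
    """

    pixels: pd.DataFrame
    hli_subgrid: np.ndarray
    landcover_subgrid: np.ndarray
    cti_subgrid: np.ndarray
    config: LandscapeConfig


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """White noise, moving-average smoothed, rank-preserved, rescaled to [0,1]."""
    z = rng.standard_normal(shape)
    if length > 0:
        size = max(1, int(round(2 * length + 1)))
        z = ndimage.uniform_filter(z, size=size, mode="wrap")
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (z - lo) / (hi - lo)


def generate_landscape(config: LandscapeConfig | None = None) -> Landscape:
    """Generate covariates, biome/ecosystem labels, and per-pixel subgrids.

    Covariates are independently smoothed noise fields rescaled to their
    configured ranges; output is bit-reproducible under a fixed seed.
    """
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    n = cfg.n_rows * cfg.n_cols
    cols: dict[str, np.ndarray] = {}
    for name, (lo, hi) in cfg.covariate_ranges.items():
        u = _smoothed_field(rng, shape, cfg.smoothing_length)
        cols[name] = (lo + (hi - lo) * u).ravel()
    biome, eco = cfg.biome_rule.assign(cols["deficit"], cols["elev"])

    s = cfg.subgrid_size
    hli_sub = cols["hli"][:, None, None] + cfg.hli_subgrid_sd * rng.standard_normal((n, s, s))
    hli_sub = np.clip(hli_sub, 0.0, 1.5)
    cti_sub = cols["cti"][:, None, None] + 0.5 * rng.standard_normal((n, s, s))
    lc_sub = np.broadcast_to(eco[:, None, None], (n, s, s)).copy()
    minority = rng.random((n, s, s)) < cfg.landcover_minority_frac
    other = rng.integers(1, len(ECOSYSTEM_LABELS) + 1, size=(n, s, s))
    lc_sub[minority] = other[minority]

    shade, majority_lc, mean_cti = aggregate_subgrid(hli_sub, lc_sub, cti_sub)

    rows, cols_idx = np.divmod(np.arange(n), cfg.n_cols)
    pixels = pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "row": rows,
            "col": cols_idx,
            **cols,
            "biome": biome,
            "ecosystem": eco,
            "shade_dens": shade,
            "landcover": majority_lc,
        }
    )
    # mean CTI over the subgrid replaces the pixel-level draw, mirroring the
    # 30-m -> 1-km averaging of the real predictor
    pixels["cti"] = mean_cti
    return Landscape(pixels, hli_sub, lc_sub, cti_sub, cfg)


def aggregate_subgrid(
    hli_subgrid: np.ndarray,
    landcover_subgrid: np.ndarray,
    cti_subgrid: np.ndarray,
    hli_shade_threshold: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate 30-m subgrids to 1-km pixel predictors.

    Returns (shade_density_percent, majority_landcover, mean_cti).
    Shade density is 100 x the fraction of subcells with HLI <= 0.6 (the
    threshold inclusive); majority landcover is the modal code (ties broken
    toward the smallest code); CTI is the arithmetic mean.

    Accepts a single (s, s) subgrid or a stack (n, s, s).
    """
    hli = np.asarray(hli_subgrid, dtype=float)
    lc = np.asarray(landcover_subgrid)
    cti = np.asarray(cti_subgrid, dtype=float)
    single = hli.ndim == 2
    if single:
        hli, lc, cti = hli[None], lc[None], cti[None]
    if hli.size == 0 or hli.shape[1] == 0 or hli.shape[2] == 0:
        raise ValueError("empty subgrid")
    shade = 100.0 * np.mean(hli <= hli_shade_threshold, axis=(1, 2))
    mean_cti = cti.mean(axis=(1, 2))
    flat = lc.reshape(lc.shape[0], -1)
    majority = np.empty(flat.shape[0], dtype=flat.dtype)
    for i, row in enumerate(flat):
        codes, counts = np.unique(row, return_counts=True)
        majority[i] = codes[np.argmax(counts)]
    if single:
        return float(shade[0]), majority[0], float(mean_cti[0])
    return shade, majority, mean_cti


# ---------------------------------------------------------------------------
# truth table


@dataclass(frozen=True)
class SensitivityRule:
    """Linear link from standardized covariates to injected sensitivity.

    s_mod_true = clip(intercept + sum_j coef_j * z(cov_j) + eps, 0, s_mod_cap)
    s_sev_true = clip(sev_gain * s_mod_true + sev_offset, s_mod_true, s_sev_cap)

    Elevation and soil bulk density dominate by default. ``noise_sd`` is
    truth-level scatter (drought response unexplained by the covariates).
    """

    intercept: float = 0.15
    coefs: dict[str, float] = field(
        default_factory=lambda: {
            "elev": 0.05,
            "soil_bd": 0.04,
            "deficit": 0.012,
            "aet": -0.008,
        }
    )
    noise_sd: float = 0.0
    s_mod_cap: float = 0.5
    sev_gain: float = 1.3
    sev_offset: float = 0.02
    s_sev_cap: float = 0.6


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def make_truth(
    pixels: pd.DataFrame,
    rule: SensitivityRule | None = None,
    timescale_choices: tuple[int, ...] = (3, 6, 12),
    disturbed_frac: float = 0.0,
    trend_frac: float = 0.0,
    trend_slope: float = 0.01,
    baseline_evi_range: tuple[float, float] = (0.15, 0.65),
    seed: int = 0,
) -> pd.DataFrame:
    """Build the truth table: injected baselines, sensitivities, contamination.

    Baseline EVI increases linearly with AET across ``baseline_evi_range``
    (greenness tracks productivity). Each pixel is assigned one true SPEI
    timescale from ``timescale_choices``, and independent Bernoulli draws
    mark disturbance and trend contamination.
    """
    rule = rule or SensitivityRule()
    rng = np.random.default_rng(seed)
    n = len(pixels)
    lin = np.full(n, rule.intercept)
    for name, beta in rule.coefs.items():
        lin = lin + beta * _zscore(pixels[name].to_numpy(dtype=float))
    if rule.noise_sd > 0:
        lin = lin + rule.noise_sd * rng.standard_normal(n)
    s_mod = np.clip(lin, 0.0, rule.s_mod_cap)
    s_sev = np.clip(rule.sev_gain * s_mod + rule.sev_offset, s_mod, rule.s_sev_cap)

    aet01 = _zscore(pixels["aet"].to_numpy(dtype=float))
    aet01 = (aet01 - aet01.min()) / max(np.ptp(aet01), 1e-12) if n > 1 else np.full(n, 0.5)
    b_lo, b_hi = baseline_evi_range
    baseline = b_lo + (b_hi - b_lo) * aet01

    return pd.DataFrame(
        {
            "pixel_id": pixels["pixel_id"].to_numpy(),
            "baseline_evi_true": baseline,
            "s_mod_true": s_mod,
            "s_sev_true": s_sev,
            "true_timescale": rng.choice(timescale_choices, size=n),
            "disturbed_flag": rng.random(n) < disturbed_frac,
            "trend_flag": rng.random(n) < trend_frac,
            "trend_slope": np.full(n, trend_slope),
        }
    )


# ---------------------------------------------------------------------------
# climate


@dataclass(frozen=True)
class ClimateConfig:
    """Seasonal monthly climate model.

    Precipitation is gamma-distributed around a winter-peaked seasonal mean
    (Mediterranean-type regime); PET follows a summer-peaked sinusoid with
    Gaussian noise. ``drought_years`` maps calendar years to precipitation
    scaling factors applied to the 12 months ending in August of that year
    (factor 1 is a no-op; 0.3 is a deep drought).
    """

    start_year: int = 1980
    n_years: int = 37
    precip_annual_mean: float = 600.0  # mm
    precip_seasonal_amp: float = 0.6  # relative winter/summer contrast
    precip_cv: float = 0.5  # monthly coefficient of variation
    pet_annual_mean: float = 700.0  # mm
    pet_seasonal_amp: float = 0.9
    pet_noise_sd: float = 5.0  # mm/month
    drought_years: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_years < 5:
            raise ValueError("n_years < 5: SPEI distribution unfittable")


def generate_climate(
    pixel_ids: np.ndarray | pd.Series,
    config: ClimateConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monthly precipitation and PET per pixel; deterministic under seed.

    Returns a long table with columns pixel_id, year, month, precipitation,
    pet (mm). Pixels are climatically independent draws from the same
    seasonal model, so each pixel has its own interannual variability.
    """
    cfg = config or ClimateConfig()
    if cfg.n_years < 30:
        import warnings

        warnings.warn(
            f"{cfg.n_years} climate years is below the recommended 30-year "
            "calibration minimum for SPEI",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pids = np.asarray(pixel_ids)
    n_pix = pids.size
    months = np.arange(1, 13)
    # winter-peaked precipitation (max in December), summer-peaked PET (max in July)
    p_season = 1.0 + cfg.precip_seasonal_amp * np.cos(2 * np.pi * (months - 12) / 12)
    p_mean = cfg.precip_annual_mean * p_season / p_season.sum()
    pet_season = 1.0 + cfg.pet_seasonal_amp * np.cos(2 * np.pi * (months - 7) / 12)
    pet_mean = cfg.pet_annual_mean * pet_season / pet_season.sum()

    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    n_t = cfg.n_years * 12
    shape_k = 1.0 / cfg.precip_cv**2
    mu = np.tile(p_mean, cfg.n_years)  # (n_t,)
    precip = rng.gamma(shape_k, scale=1.0, size=(n_pix, n_t)) * (mu / shape_k)
    pet = np.tile(pet_mean, cfg.n_years) + cfg.pet_noise_sd * rng.standard_normal((n_pix, n_t))
    pet = np.clip(pet, 0.0, None)

    if cfg.drought_years:
        year_grid = np.repeat(years, 12)
        month_grid = np.tile(months, cfg.n_years)
        # the water year ending in August of Y: Sep(Y-1)..Aug(Y)
        wy = np.where(month_grid >= 9, year_grid + 1, year_grid)
        factor = np.ones(n_t)
        for yy, f in cfg.drought_years.items():
            factor[wy == yy] = f
        precip = precip * factor[None, :]

    out = pd.DataFrame(
        {
            "pixel_id": np.repeat(pids, n_t),
            "year": np.tile(np.repeat(years, 12), n_pix),
            "month": np.tile(np.tile(months, cfg.n_years), n_pix),
            "precipitation": precip.ravel(),
            "pet": pet.ravel(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# EVI


def generate_evi(
    truth: pd.DataFrame,
    spei_table: pd.DataFrame,
    years: tuple[int, int] = (2000, 2016),
    noise_sd: float = 0.02,
    disturbance_drop: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Summer-mean EVI per pixel-year from injected truth and SPEI classes.

    EVI_{i,t} = baseline_i * (1 - s_i(class_t)) * exp(eps), with s = 0 in
    baseline and pluvial years, s_mod_true in moderate-drought years and
    s_sev_true in severe years, classified on each pixel's true timescale.
    Disturbed pixels get a permanent multiplicative drop of
    ``disturbance_drop`` starting at a uniform-random year in the window;
    trend pixels get an additive linear drift of ``trend_slope`` per year.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    n_years = yr.size

    cls = spei_table[(spei_table["year"] >= y0) & (spei_table["year"] <= y1)]
    cls_wide = cls.pivot_table(
        index="pixel_id",
        columns=["timescale", "year"],
        values="drought_class",
        aggfunc="first",
    )

    records = []
    for t in truth.itertuples(index=False):
        pid = t.pixel_id
        if pid not in cls_wide.index:
            raise ValueError(f"SPEI table missing pixel {pid}")
        try:
            classes = cls_wide.loc[pid, t.true_timescale].reindex(yr).to_numpy()
        except KeyError as exc:
            raise ValueError(
                f"SPEI table lacks timescale {t.true_timescale} for pixel {pid}"
            ) from exc
        if pd.isna(classes).any():
            raise ValueError(f"SPEI table missing years for pixel {pid}")
        s = np.where(classes == "severe", t.s_sev_true, np.where(classes == "moderate", t.s_mod_true, 0.0))
        evi = t.baseline_evi_true * (1.0 - s)
        if noise_sd > 0:
            evi = evi * np.exp(noise_sd * rng.standard_normal(n_years))
        else:
            rng.standard_normal(n_years)  # keep the stream aligned across configs
        if t.disturbed_flag:
            k = rng.integers(1, n_years)  # drop begins after at least one clean year
            evi = evi * np.where(np.arange(n_years) >= k, 1.0 - disturbance_drop, 1.0)
        else:
            rng.integers(1, n_years)
        if t.trend_flag:
            evi = evi + t.trend_slope * (yr - y0)
        records.append(pd.DataFrame({"pixel_id": pid, "year": yr, "evi_summer": np.clip(evi, -0.19, 0.999)}))
    return pd.concat(records, ignore_index=True)


def make_attribution_dataset(
    n_pixels: int = 10_000,
    target_r2: float = 0.6,
    rule: SensitivityRule | None = None,
    config: LandscapeConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictor table plus an S' response with controlled signal strength.

    Generates a landscape of at least ``n_pixels`` pixels, computes the
    injected linear sensitivity signal, and adds Gaussian truth noise whose
    variance is set so that var(signal)/var(response) equals ``target_r2``.
    The response column ``s_response`` is on the percent scale of S'.
    Used to exercise the attribution protocol with a known answer.
    """
    if config is None:
        side = int(np.ceil(np.sqrt(n_pixels)))
        config = LandscapeConfig(n_rows=side, n_cols=side, subgrid_size=5, seed=seed)
    land = generate_landscape(config)
    pixels = land.pixels.iloc[:n_pixels].copy()
    rule = rule or SensitivityRule()
    rng = np.random.default_rng(seed + 1)
    lin = np.full(len(pixels), rule.intercept)
    for name, beta in rule.coefs.items():
        lin = lin + beta * _zscore(pixels[name].to_numpy(dtype=float))
    sig_var = lin.var()
    noise_sd = np.sqrt(sig_var * (1.0 - target_r2) / target_r2) if target_r2 < 1 else 0.0
    resp = np.clip(lin + noise_sd * rng.standard_normal(len(pixels)), 0.0, rule.s_mod_cap)
    pixels["s_response"] = 100.0 * resp
    return pixels
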