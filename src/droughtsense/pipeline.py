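"""Configuration, validated I/O, and orchestration of the full analysis.

One :class:`RunConfig` ties the stages together:

    simulate (optional) -> spei -> sensitivity -> screen -> attribute
    (one model per biome x drought-intensity roster entry) -> report

Every stage reads and writes delimited tables with validated headers (CSV,
UTF-8, "." decimal); monthly climate may alternatively be a NetCDF file
with pixel/time dimensions. A manifest JSON records the config hash, the
derived per-stage seeds, row counts, and output paths, which suffices to
re-run the analysis bit-identically.

Stage seeds are derived from the global seed as
``sha256(f"{seed}:{stage}:{index}") mod 2**31`` so no stage silently
reuses another's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, reporting, screening, sensitivity, spei, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "read_climate",
    "write_climate_netcdf",
    "derive_seed",
    "run_all",
]

#: required columns per interchange table
TABLE_SCHEMAS: dict[str, list[str]] = {
    "pixels": ["pixel_id", "row", "col", "elev", "aet", "deficit", "soil_awc",
               "soil_bd", "wtd", "cti", "hli", "biome", "ecosystem",
               "shade_dens", "landcover"],
    "truth": ["pixel_id", "baseline_evi_true", "s_mod_true", "s_sev_true",
              "true_timescale", "disturbed_flag", "trend_flag", "trend_slope"],
    "climate": ["pixel_id", "year", "month", "precipitation", "pet"],
    "evi": ["pixel_id", "year", "evi_summer"],
    "spei": ["pixel_id", "year", "timescale", "spei", "drought_class"],
}

PRELIMINARY_PREDICTORS = [
    "elev", "deficit", "aet", "soil_bd", "soil_awc", "wtd", "cti", "hli",
    "shade_dens", "drought_exp", "ecosystem",
]

DEFAULT_ROSTER = [
    ("forest", "mod"),
    ("forest", "sev"),
    ("shrub-steppe", "mod"),
    ("shrub-steppe", "sev"),
]


def derive_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Stage seed from the global seed via a stable hash split."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything needed for one reproducible end-to-end run."""

    out_dir: str = "droughtsense_run"
    seed: int = 0
    simulate: bool = True
    # synthetic-mode knobs
    n_rows: int = 40
    n_cols: int = 40
    smoothing_length: float = 5.0
    subgrid_size: int = 9
    climate_start_year: int = 1980
    climate_n_years: int = 37
    evi_years: tuple[int, int] = (2000, 2016)
    evi_noise_sd: float = 0.02
    disturbed_frac: float = 0.05
    trend_frac: float = 0.05
    # real-mode inputs (used when simulate is False)
    climate_path: str | None = None
    evi_path: str | None = None
    pixels_path: str | None = None
    disturbance_path: str | None = None
    # stage configs
    spei_config: spei.SpeiConfig = field(default_factory=spei.SpeiConfig)
    screen_config: screening.ScreenConfig = field(default_factory=screening.ScreenConfig)
    sens_config: sensitivity.SensitivityConfig = field(default_factory=sensitivity.SensitivityConfig)
    brt_params: attribution.BrtParams = field(default_factory=attribution.BrtParams)
    predictors: list[str] = field(default_factory=lambda: list(PRELIMINARY_PREDICTORS))
    roster: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_ROSTER))
    n_runs: int = 20
    sample_size: int = 10_000
    prune_threshold_pct: float = 5.0
    min_model_rows: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {
            "spei_config": spei.SpeiConfig,
            "screen_config": screening.ScreenConfig,
            "sens_config": sensitivity.SensitivityConfig,
            "brt_params": attribution.BrtParams,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in nested and isinstance(val, dict):
                for tup in ("timescales", "exposure_period", "calibration_period"):
                    if tup in val and isinstance(val[tup], list):
                        val[tup] = tuple(val[tup])
                kwargs[key] = nested[key](**val)
            elif key == "roster":
                kwargs[key] = [tuple(r) for r in val]
            elif key == "evi_years":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validated I/O


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and check its header against the named schema."""
    df = pd.read_csv(path)
    required = TABLE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for schema {schema!r}")
    logger.info("read %s: %d rows (%s)", path, len(df), schema)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a CSV (UTF-8, '.' decimal), optionally validating the header."""
    path = Path(path)
    if schema is not None:
        required = TABLE_SCHEMAS[schema]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"refusing to write {path}: missing column(s) {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    logger.info("wrote %s: %d rows", path, len(df))
    return path


def write_climate_netcdf(climate: pd.DataFrame, path: str | Path) -> Path:
    """Write the monthly climate table as a gridded NetCDF (pixel x time)."""
    import xarray as xr

    time = climate["year"] * 12 + (climate["month"] - 1)
    wide_p = climate.assign(t=time).pivot_table(index="pixel_id", columns="t", values="precipitation")
    wide_e = climate.assign(t=time).pivot_table(index="pixel_id", columns="t", values="pet")
    t = wide_p.columns.to_numpy()
    ds = xr.Dataset(
        {
            "precipitation": (("pixel_id", "time"), wide_p.to_numpy()),
            "pet": (("pixel_id", "time"), wide_e.to_numpy()),
        },
        coords={
            "pixel_id": wide_p.index.to_numpy(),
            "time": t,
            "year": ("time", (t // 12).astype(int)),
            "month": ("time", (t % 12 + 1).astype(int)),
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return Path(path)


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read monthly climate from CSV or NetCDF into the long-table schema."""
    path = Path(path)
    if path.suffix in (".nc", ".nc4", ".cdf"):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        df = ds.to_dataframe().reset_index()
        out = df[["pixel_id", "year", "month", "precipitation", "pet"]].copy()
        out["year"] = out["year"].astype(int)
        out["month"] = out["month"].astype(int)
        return out.sort_values(["pixel_id", "year", "month"]).reset_index(drop=True)
    return read_table(path, "climate")


# ---------------------------------------------------------------------------
# orchestration


def _outputs_exist(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped and
    its outputs are read back, so deleting an intermediate file regenerates
    only that stage and everything downstream.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "seeds": {},
        "row_counts": {},
        "outputs": [],
        "stages_run": [],
        "exclusions": {},
        "models": {},
    }

    def record(name: str, df: pd.DataFrame, path: Path) -> None:
        manifest["row_counts"][name] = len(df)
        manifest["outputs"].append(str(path))

    # -- stage 1: simulate -------------------------------------------------
    p_pixels, p_truth, p_climate, p_evi = (
        out / "pixels.csv", out / "truth.csv", out / "climate.csv", out / "evi.csv",
    )
    if cfg.simulate:
        sim_paths = [p_pixels, p_truth, p_climate, p_evi]
        if resume and _outputs_exist(sim_paths):
            pixels = read_table(p_pixels, "pixels")
            truth = read_table(p_truth, "truth")
            climate = read_table(p_climate, "climate")
            evi = read_table(p_evi, "evi")
        else:
            s_land = derive_seed(cfg.seed, "landscape")
            s_truth = derive_seed(cfg.seed, "truth")
            s_clim = derive_seed(cfg.seed, "climate")
            s_evi = derive_seed(cfg.seed, "evi")
            manifest["seeds"].update(
                {"landscape": s_land, "truth": s_truth, "climate": s_clim, "evi": s_evi}
            )
            land = synthetic.generate_landscape(
                synthetic.LandscapeConfig(
                    n_rows=cfg.n_rows, n_cols=cfg.n_cols,
                    smoothing_length=cfg.smoothing_length,
                    subgrid_size=cfg.subgrid_size, seed=s_land,
                )
            )
            pixels = land.pixels
            truth = synthetic.make_truth(
                pixels,
                disturbed_frac=cfg.disturbed_frac,
                trend_frac=cfg.trend_frac,
                seed=s_truth,
            )
            n_years = cfg.evi_years[1] - cfg.climate_start_year + 1
            climate = synthetic.generate_climate(
                pixels["pixel_id"].to_numpy(),
                synthetic.ClimateConfig(start_year=cfg.climate_start_year, n_years=max(n_years, cfg.climate_n_years)),
                seed=s_clim,
            )
            spei_for_evi = spei.compute_spei(climate, cfg.spei_config)
            evi = synthetic.generate_evi(
                truth, spei_for_evi, years=cfg.evi_years,
                noise_sd=cfg.evi_noise_sd, seed=s_evi,
            )
            write_table(pixels, p_pixels, "pixels")
            write_table(truth, p_truth, "truth")
            write_table(climate, p_climate, "climate")
            write_table(evi, p_evi, "evi")
            manifest["stages_run"].append("simulate")
        for name, df, p in (("pixels", pixels, p_pixels), ("truth", truth, p_truth),
                            ("climate", climate, p_climate), ("evi", evi, p_evi)):
            record(name, df, p)
    else:
        pixels = read_table(cfg.pixels_path, "pixels")
        climate = read_climate(cfg.climate_path)
        evi = read_table(cfg.evi_path, "evi")
        truth = None

    # -- stage 2: spei -----------------------------------------------------
    p_spei = out / "spei.csv"
    if resume and p_spei.exists():
        spei_table = read_table(p_spei, "spei")
    else:
        spei_table = spei.compute_spei(climate, cfg.spei_config)
        write_table(spei_table, p_spei, "spei")
        manifest["stages_run"].append("spei")
    record("spei", spei_table, p_spei)

    # -- stage 3: sensitivity ---------------------------------------------
    p_sens = out / "sensitivity.csv"
    if resume and p_sens.exists():
        sens = pd.read_csv(p_sens)
    else:
        sens, sens_summary = sensitivity.sensitivity_table(evi, spei_table, cfg.sens_config)
        manifest["exclusions"]["sensitivity"] = sens_summary
        write_table(sens, p_sens)
        manifest["stages_run"].append("sensitivity")
    record("sensitivity", sens, p_sens)

    # -- stage 4: screen ---------------------------------------------------
    p_retained = out / "retained_pixels.csv"
    p_ledger = out / "exclusion_ledger.csv"
    p_model = out / "model_table.csv"
    if resume and _outputs_exist([p_retained, p_ledger, p_model]):
        model_table = pd.read_csv(p_model)
    else:
        flags = screening.trend_flags(evi, cfg.screen_config)
        if truth is not None:
            mask = truth[["pixel_id", "disturbed_flag"]]
        elif cfg.disturbance_path:
            mask = pd.read_csv(cfg.disturbance_path)[["pixel_id", "disturbed_flag"]]
        else:
            mask = pd.DataFrame(
                {"pixel_id": pixels["pixel_id"], "disturbed_flag": False}
            )
        retained, ledger = screening.apply_exclusions(pixels, mask, flags)
        exposure = screening.drought_exposure(spei_table, cfg.screen_config)
        model_table = (
            retained.merge(exposure, on="pixel_id").merge(sens, on="pixel_id")
        )
        write_table(retained, p_retained)
        write_table(pd.DataFrame([ledger]), p_ledger)
        write_table(model_table, p_model)
        manifest["exclusions"]["screening"] = ledger
        manifest["stages_run"].append("screen")
    record("model_table", model_table, p_model)

    # -- stage 5: attribute ------------------------------------------------
    for i, (biome, intensity) in enumerate(cfg.roster):
        tag = f"{biome.replace(' ', '_').replace('-', '_')}_{intensity}"
        resp = f"s_{intensity}_max"
        sub = model_table[
            (model_table["biome"] == biome) & model_table[f"valid_{intensity}"]
        ].dropna(subset=[resp])
        p_ri = out / f"relative_influence_{tag}.csv"
        p_fit = out / f"fit_stats_{tag}.csv"
        p_pd = out / f"partial_dependence_{tag}.csv"
        p_sum = out / f"model_summary_{tag}.json"
        if resume and _outputs_exist([p_ri, p_fit, p_pd, p_sum]):
            manifest["outputs"] += [str(p_ri), str(p_fit), str(p_pd), str(p_sum)]
            continue
        min_rows = max(cfg.min_model_rows, 100)  # BRT fit requires >= 100 rows
        if len(sub) < min_rows:
            logger.warning(
                "roster entry %s: only %d rows (< %d); skipped", tag, len(sub), min_rows
            )
            manifest["models"][tag] = {"skipped": True, "n_rows": len(sub)}
            continue
        s_ens = derive_seed(cfg.seed, "attribute", i)
        manifest["seeds"][f"attribute_{tag}"] = s_ens
        ens = attribution.ensemble_runs(
            sub, cfg.predictors, resp, cfg.brt_params,
            n_runs=cfg.n_runs, sample_size=min(cfg.sample_size, len(sub)),
            seed=s_ens,
        )
        kept, dropped = attribution.prune_predictors(ens, cfg.prune_threshold_pct)
        write_table(ens.relative_influence.assign(run=range(len(ens.relative_influence))), p_ri)
        write_table(ens.fit_stats.assign(run=range(len(ens.fit_stats))), p_fit)
        pd_long = pd.concat(
            [c.assign(predictor=p) for p, c in ens.pd_curves.items()], ignore_index=True
        )
        write_table(pd_long, p_pd)
        summary = {
            "biome": biome,
            "intensity": intensity,
            "n_rows": len(sub),
            "n_runs": ens.n_runs,
            "sample_size": ens.sample_size,
            "fit_summary": json.loads(ens.fit_summary().to_json()),
            "influence_median": ens.relative_influence.median().to_dict(),
            "pruned_kept": kept,
            "pruned_dropped": dropped,
        }
        p_sum.write_text(json.dumps(summary, indent=2))
        manifest["models"][tag] = {
            "n_rows": len(sub), "n_runs": ens.n_runs,
            "kept": kept, "dropped": dropped,
        }
        manifest["outputs"] += [str(p_ri), str(p_fit), str(p_pd), str(p_sum)]
        manifest["stages_run"].append(f"attribute:{tag}")

    # -- stage 6: report ---------------------------------------------------
    p_biome = out / "biome_summary.csv"
    p_eco = out / "ecosystem_summary.csv"
    if not (resume and _outputs_exist([p_biome, p_eco])):
        labels = model_table[["pixel_id", "biome", "ecosystem"]]
        bs = reporting.biome_summary(model_table, labels)
        es, _assigned = reporting.ecosystem_summary(model_table, labels)
        write_table(bs, p_biome)
        write_table(es, p_eco)
        manifest["stages_run"].append("report")
    manifest["outputs"] += [str(p_biome), str(p_eco)]

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    p_manifest = out / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
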