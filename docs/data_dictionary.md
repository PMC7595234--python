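# Data dictionary

All interchange files are UTF-8, comma-delimited CSV with "." decimals.
Monthly climate may alternatively be netCDF3 (`pixel_id` × `time`
dimensions with `year`/`month` coordinate arrays and `precipitation`/`pet`
variables).

## pixels.csv — one row per 1-km pixel

| column      | units        | description |
|-------------|--------------|-------------|
| pixel_id    | —            | integer pixel identifier |
| row, col    | pixels       | grid position |
| elev        | m            | elevation |
| aet         | mm           | actual evapotranspiration (climate normal) |
| deficit     | mm           | climatic water deficit (PET − AET normal) |
| soil_awc    | vol. fraction| soil available water capacity |
| soil_bd     | kg/m³        | soil bulk density |
| wtd         | m            | water-table depth |
| cti         | unitless     | compound topographic index, mean of subgrid |
| hli         | unitless     | heat-load index, pixel level |
| biome       | —            | "forest" or "shrub-steppe" |
| ecosystem   | code         | ecosystem type (1–5, see `synthetic.ECOSYSTEM_LABELS`) |
| shade_dens  | percent      | share of subgrid cells with HLI ≤ 0.6 |
| landcover   | code         | majority landcover of the subgrid |

## truth.csv — synthetic truth per pixel

| column            | units      | description |
|-------------------|------------|-------------|
| pixel_id          | —          | |
| baseline_evi_true | EVI        | injected baseline, in (0, 1) |
| s_mod_true        | fraction   | injected moderate-drought EVI reduction |
| s_sev_true        | fraction   | injected severe reduction (≥ s_mod_true) |
| true_timescale    | months     | SPEI timescale driving this pixel (3/6/12) |
| disturbed_flag    | bool       | permanent step disturbance injected |
| trend_flag        | bool       | linear trend injected |
| trend_slope       | EVI/yr     | injected trend slope |

## climate.csv — monthly climate, long format

pixel_id, year, month (1–12), precipitation (mm), pet (mm).

## evi.csv — annual summer greenness

pixel_id, year, evi_summer (unitless mean June–August EVI).

## spei.csv — standardized drought index

pixel_id, year, timescale (months), spei (standard-normal units),
drought_class ∈ {pluvial, baseline, moderate, severe}.

## sensitivity.csv — per-pixel S'

Per timescale k ∈ {3, 6, 12}: `baseline_evi_k`, `n_baseline_k`, `s_mod_k`,
`n_mod_k`, `s_sev_k`, `n_sev_k`. Across timescales: `s_mod_max`,
`s_sev_max` (percent), `s_mod_max_timescale`, `s_sev_max_timescale`,
`valid_mod`, `valid_sev`.

## model_table.csv

Retained pixels (screened) with covariates, `drought_exp` (percent), and
the sensitivity columns merged.

## Attribution outputs (per roster entry `<biome>_<intensity>`)

- `relative_influence_*.csv`: one row per ensemble run, one column per
  predictor (percent, rows sum to 100), plus `run`.
- `fit_stats_*.csv`: per run `cv_correlation`, `pct_deviance_explained`,
  `n_trees`.
- `partial_dependence_*.csv`: `value`, `mean`, `q25`, `q75`, `predictor`
  (grid between the 5th and 95th percentiles).
- `model_summary_*.json`: fit summary, median influences, pruning result.

## Summary outputs

- `biome_summary.csv`: medians/IQRs of `s_mod_max`/`s_sev_max`, Spearman
  correlation between them, fraction with `s_sev_max > s_mod_max`, mean
  positive excess, fraction declining.
- `ecosystem_summary.csv`: per-ecosystem `n_pixels`, medians and IQRs of
  baseline EVI and sensitivities.
- `exclusion_ledger.csv`: pixels excluded per rule (disturbed, trend,
  landcover) plus retained count.
- `manifest.json`: config hash and full config, derived stage seeds, row
  counts per stage, model summaries, output file list.
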