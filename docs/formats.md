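# File formats

All tables are UTF-8 CSV with `.` decimal separators and ISO `YYYY-MM`
month strings. Output files written by the CLI start with a comment line
`# amews=<version> seed=<seed> config_hash=<hash>`; readers skip lines
starting with `#`. Columns suffixed `_pct` are percentages in [0, 100];
validation metrics on the RMSD scale use proportions in [0, 1].

## households.csv

| column | type | range |
|---|---|---|
| id | string, unique | |
| ward_id | string | |
| x, y | float | planar units; ward i occupies x ∈ [i, i+1) in generated data |
| cap_own, cap_network, cap_market | float | [0, 1] — capability per livelihood dimension |
| h_p | float | [0, 1] — health factor |
| h_a | float | [0, 1] — asset factor |
| n_children | int | ≥ 1 |

## stressors.csv

One row per (ward_id, month); keys must be unique; baselines are constant
per ward.

| column | type | range |
|---|---|---|
| ward_id | string | |
| month | string | YYYY-MM |
| ndvi | float | |
| ndvi_lt_mean | float | long-term ward mean |
| ndvi_lt_sd | float | > 0 |
| price | float | ≥ 0, currency per 100 g staple |
| price_baseline | float | > 0, 10-year ward baseline |

## prevalence tables

`observed_prevalence.csv` (input) and `prevalence_out.csv` (output); one
row per (ward_id, month).

| column | type | range |
|---|---|---|
| ward_id | string | |
| month | string | YYYY-MM |
| prevalence_pct | float | [0, 100] |
| ipc_phase | int | 1–5 (output only; optional on input) |

## Configuration (YAML)

All sections optional; values merge over package defaults.

```yaml
model:
  lambda: 0.05            # learning rate, box [0.01, 0.1]
  spawn_rate: 0.05
  n_0: 0.5                # sufficiency threshold
  K: 2                    # persistence window (rounds)
  neighborhood_k: 8
  selection_floor: 0.05
  ema_alpha: 0.3
  init_set_size: 3
  max_set_size: 8
  spawn_scale: 0.1
stressors:
  beta_c: 0.25
  beta_m: 0.5
  climate_floor: 0.1
  market_floor: 0.1
catalog:
  grid_step: 0.25
  zone_masks:             # per-zone per-dimension weight bounds
    pastoral: {own_production: [0.0, 0.5]}
  ward_zones:             # ward id -> zone name
    w1: pastoral
calibration:
  lambdas: [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1]
  spawns: [0.05]
  replicates: 20
  burn_in: 6
run:
  months: 24
  seed: 0
  replicates: 20
synth:                    # GeneratorConfig fields, e.g.
  n_wards: 5
  months: 24
  households_per_site: 30
```

## Other outputs

- `manifest.json` — command, seed, config hash, package version, input
  file SHA-256 checksums, timestamp. Written by every CLI run.
- `best_params.json` — calibrated parameters plus the in-sample
  validation report.
- `grid_scores.csv` — one row per calibration cell: `learning_rate,
  spawn_rate, n_0, rmsd, replicate_rmsd_mean, f1_macro`.
- `window_reports.csv`, `forecast_errors.csv` — per-window validation
  reports and ward-month forecast errors from `split-eval` / `forecast`.
- `scenarios.csv`, `summary.csv` — tidy counterfactual trajectories
  (scenario × ward × month × replicate) and replicate mean with
  2.5/97.5-percentile bands.
- `truth.json` — the generator's ground-truth parameters and config.
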