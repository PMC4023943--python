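# sourcesink

Source-sink reconstruction for passively dispersed propagules: estimate
per-source productivity, sparse source→sink linkage, and smooth
release-time curves from sink-side abundance plus simulated drift
trajectories.

The model for region `i` and year `t` is

    y[i,t] = Σ_j w[j] · θ[j,i] · Σ_d f[j,d] · G[j,d,i,t] + ε[i,t]

where `G[j,d,i,t]` is the mean fraction of tracked time a propagule from
source `j`, released at event `d` of year `t`, spends inside sink region
`i`; `θ[j,·] ≥ 0` sums to 1 (sink effects), `f[j,·] ≥ 0` sums to 1 (release
timing, a cubic-spline curve), and `w[j] ≥ 0` is the per-source annual
production index. Fitting is penalized constrained least squares with an
adaptive-lasso-style weighted outer-product penalty, solved by cyclic block
relaxation with non-negative soft-thresholding (plus a bound-constrained
quasi-Newton polish), tuned by AIC over a λ grid. Inference covers a
residual bootstrap (zero-probabilities and 90% intervals), a
structural-change permutation test on two-period AIC sums, changepoint
estimation, and sensitivity experiments (trajectory shifting, ±5% covariate
perturbation).

## Layout

| module | contents |
|---|---|
| `sourcesink.data_model` | typed containers + CSV/GeoJSON I/O: trajectories, regions, abundance, exposure tensor; station→region CPUE aggregation (`log(CPUE+1)`) |
| `sourcesink.exposure` | region assignment, exposure tensor `G` from trajectories, trajectory shifting, covariate perturbation |
| `sourcesink.basis` | non-negative cubic B-spline / Bernstein basis (partition of unity) |
| `sourcesink.estimation` | penalized constrained least squares, adaptive weights, AIC tuning, prediction |
| `sourcesink.inference` | residual bootstrap, permutation test, changepoint estimation |
| `sourcesink.sensitivity` | shift and perturbation experiments, misclassification rates |
| `sourcesink.synthetic` | toy advection simulator, model-based abundance generator, paper-scale release design |
| `sourcesink.cli` | `sourcesink` command-line front end |

## CLI

Every subcommand takes a YAML config (`--config`) plus flags; flags win.
Outputs carry a config hash, seed, and package version for reproducibility.

```sh
# write a demo synthetic scenario (trajectories, regions, exposure, abundance, truth)
sourcesink simulate --out-dir runs/demo

# covariates from your own trajectory/region files
sourcesink exposure --trajectories traj.csv --regions regions.geojson --out-dir runs/exp

# AIC-tuned fit -> fit.json + reconstruction-table CSV
sourcesink fit --abundance runs/demo/abundance.csv --exposure runs/demo/exposure.csv --out-dir runs/fit

# uncertainty / structural change
sourcesink bootstrap --abundance ... --exposure ... --B 400 --out-dir runs/boot
sourcesink permtest  --abundance ... --exposure ... --t0 1990 --B 500 --out-dir runs/perm
sourcesink changepoint --abundance ... --exposure ... --out-dir runs/cp

# sensitivity experiments
sourcesink sensitivity-shift   --trajectories ... --regions ... --abundance ... --out-dir runs/shift
sourcesink sensitivity-perturb --abundance ... --exposure ... --n-reps 300 --out-dir runs/pert

# release-time curves with point-wise 90% bands
sourcesink report --abundance ... --exposure ... --out-dir runs/curves
```

Config keys (all optional): `basis_df` (default 10), `lambda_grid`,
`seed`, `bootstrap_B` (400), `permutation_B` (500), `shift_grid`
(0.05–0.20), `perturb_frac` (0.05), `perturb_reps` (300), `min_years` (4),
`schedule` (release-window layout), and a `sim` block for custom synthetic
scenarios (see `tests/test_cli.py` for a worked example).

## File formats

- trajectories: CSV `year,source_id,site_id,depth_level,release_index,day_offset,lon,lat`
- regions: GeoJSON FeatureCollection of polygons with integer `region_id`
- stations: CSV `year,lon,lat,cpue`; aggregated abundance: region × year CSV
- exposure: long CSV `source_id,release_index,region_id,year,g`
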