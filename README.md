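# persistlab

Quantitative analysis of bacterial antibiotic-persistence experiments:

- **`persistlab.dilution`** — most-probable-number (limiting-dilution) viable
  density estimation (`Nv = ln(W/k) / (y·d)` under Poisson allocation),
  killing-curve assembly with log-scale mean ± SE per time point, surviving
  fractions with propagated errors, and the geometric-mean OD MIC rule.
- **`persistlab.decay`** — multi-exponential killing-curve models
  `f_n(t) = Σ a_j exp(−d_j t)` fitted by multi-start Levenberg–Marquardt on
  natural-log residuals, with the phase count selected by the Gaussian AIC
  `N ln 2π + N + N ln(SSR/N) + 2k`.
- **`persistlab.lineage`** — single-cell lineage statistics from tracking
  tables: division rates D(σ)/T(σ), random-sister independent lineage
  sampling, growing/non-growing classification over a pre-exposure window,
  binomial fractions with Wald SEs, persister frequency from chamber counts,
  shape metrics (area, perimeter, circularity 4πA/P²), and Wilcoxon rank-sum
  comparisons.
- **`persistlab.survival`** — the two-subpopulation survival model
  `f = s·Pn`: estimate `s` at an anchoring condition with error propagation,
  predict frequencies across conditions, and classify observations against
  the prediction band.
- **`persistlab.simulate`** — synthetic generators for every input: replicate
  killing curves with lognormal noise, Poisson limiting-dilution plates, and
  chamber lineage forests from a two-state (growing/non-growing) switching
  process with state-dependent survival, including per-frame cell areas.
- **`persistlab.io` / `persistlab.cli`** — CSV/TSV schemas, validated JSON
  run configuration, and the end-to-end report generator.

## Command line

```bash
persistlab mpn --wells 12 --non-turbid 3 --dilution 1e-6
persistlab simulate plates --density 2e6 -d 1e-5 -d 1e-6 --seed 0 --out plates.csv
persistlab killcurve summarize --plates plates.csv --out curve.csv
persistlab killcurve fit --curve curve.csv --n-max 3 --starts 20 --seed 1
persistlab simulate lineages --config sim.json --out-cells cells.tsv --out-frames frames.tsv
persistlab lineage classify --cells cells.tsv --frames frames.tsv --t-exposure 1.5
persistlab lineage stats --cells cells.tsv --t-exposure 1.5 --seed 0
persistlab survival-model --conditions conditions.csv --anchor post_late
persistlab report --config run.json
```

All randomized commands accept `--seed`; `report` consumes a JSON
configuration (paths, protocol, analysis options) and writes a versioned
JSON report plus plots.

## Table schemas

| file | format | columns |
| --- | --- | --- |
| plates | CSV | `replicate,time_h,dilution,wells,non_turbid,volume_ml` |
| curve | CSV | `replicate,time_h,density` |
| lineage cells | TSV | `cell_id,parent_id,chamber_id,birth_h,end_h,fate,persister` |
| lineage frames | TSV | `cell_id,t_h,area_um2[,outline_wkt]` |
| conditions | CSV | `condition,Pn,Pn_se,f,f_lower,f_upper` |

Times are hours, areas µm², densities cells/mL; fates are one of
`division,lysis,tracking_lost,censored`.

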