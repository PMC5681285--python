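# sedigrass

Linking catchment sediment loads to the extent of seagrass suitable habitat
in a coastal embayment.

Land clearing, agriculture and urbanisation increase river sediment loads;
suspended sediment makes coastal water turbid, cuts the light reaching the
seafloor, and shrinks the area where light-limited habitats such as seagrass
meadows can persist.  Managers weighing catchment restoration against marine
protection need a quantitative link from *tonnes of sediment delivered* to
*hectares of habitat supported*.  `sedigrass` provides that link as a
tested, reusable four-stage pipeline, aimed at coastal ecologists and
land–sea conservation planners:

1. **Sediment** — daily per-river TSS series aggregated to monthly, wet-season
   (Nov–Mar) and water-year (July–June) loads.
2. **Water clarity / light** — a linear model of Secchi depth,
   `Z_SD = b0 + bS·S + bz·z + bDO·D_O + bDR·D_R`, driven by the monthly load
   `S` and maps of depth and least-cost over-water distance to river mouths
   and the open ocean; converted to benthic light via Lambert–Beer,
   `I(z)/I0 = exp(−K_d z)` with `K_d = 1.7/Z_SD`.
3. **Habitat suitability** — a binomial GLM,
   `logit(p) = b0 + b_L·L + b_H·H_s + b_HL·(H_s×L)`, where `L` is the log of
   mean percent benthic irradiance over the prior six months and `H_s` the
   90th-percentile significant wave height; probability maps are classified
   by thresholds optimised for Cohen's kappa, accuracy, sensitivity =
   specificity, or a 0.5 default, and validated with a confusion matrix.
4. **Dose–response** — wet-season mean habitat area per water year regressed
   on annual load with BIC selection among {∅, S, S², S+S²}, plus a
   4-threshold × 2-timescale sensitivity analysis.

A synthetic-bay generator fabricates all inputs (bathymetry, wave climate,
river mouths, daily loads, monitoring stations, a presence/absence
calibration map) with the statistical structure the chain assumes, so the
whole analysis runs and is tested without any external data.  Published
model coefficients from a subtropical embayment ship as the reference
configuration and as the generator's ground truth.

## Worked example

```python
from sedigrass import BayConfig, run_pipeline

result = run_pipeline(BayConfig(seed=1))
m = result.secchi_model
print("Secchi: " + ", ".join(f"{k}={v:.3g}" for k, v in m.coefficients().items()))
print("adj R^2 = %.3f on %d observations" % (m.adj_r2_, m.n_obs_))
print("Thresholds:", result.thresholds)
print("Calibration PCC = %.1f%%, kappa = %.2f"
      % (100 * result.validation.pcc, result.validation.kappa))
print(result.sensitivity[["timescale", "metric", "threshold", "intercept",
                          "sediment", "sediment2", "terms"]].to_string(index=False))
```

prints

```
Secchi: intercept=0.752, sediment=-4.29e-06, depth=-0.216, d_ocean=-1.9e-06, d_river=8.67e-05
adj R^2 = 0.522 on 9209 observations
Thresholds: {'kappa': 0.46, 'maxPC': 0.46, 'sens_spec': 0.58, 'default': 0.5}
Calibration PCC = 77.5%, kappa = 0.56
timescale    metric  threshold   intercept  sediment     sediment2 terms
   annual     kappa       0.46 5889.530854 -0.000648  0.000000e+00     S
   annual     maxPC       0.46 5889.530854 -0.000648  0.000000e+00     S
   annual sens_spec       0.58 5306.832038 -0.002600  0.000000e+00     S
   annual   default       0.50 5770.018080 -0.000798 -3.343878e-10  S+S2
  monthly     kappa       0.46 5629.941935  0.000000  0.000000e+00     1
  monthly     maxPC       0.46 5629.941935  0.000000  0.000000e+00     1
  monthly sens_spec       0.58 4397.262426  0.000000 -5.921672e-08    S2
  monthly   default       0.50 5384.367742  0.000000  0.000000e+00     1
```

Reading this: the refitted clarity model recovers coefficients close to the
generating truth (0.842, −4.56e-6, −0.226, −7.32e-6, +8.30e-5) and explains
~52% of Secchi variance at the configured observation noise.  The
kappa-optimal presence threshold on the calibration map is 0.46, classifying
77.5% of cells correctly.  Each sensitivity row is the BIC-selected model of
habitat area (ha) against sediment load (t): every selected quadratic
coefficient is ≤ 0 — larger loads remove disproportionately more habitat —
and area at any load shrinks as the threshold rises.

The same chain is scriptable stage by stage from a shell:

```bash
sedigrass all --seed 1 --outdir run1          # or: simulate, distances,
                                              # sediment, clarity, sdm,
                                              # response, sensitivity
```

Each stage writes plain-text artefacts (ESRI ASCII rasters, CSV, JSON) plus
a manifest with the config hash, seed and input checksums; reruns with the
same seed are byte-identical.

To analyse real data instead of the synthetic bay, construct a `BayGrid`
from your own rasters, read daily loads with `read_daily_tss` (CSV/XLSX,
wide or long), and call the stage functions (`fit_secchi_model`,
`build_light_stack`, `fit_sdm`, `sensitivity_analysis`) directly.

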