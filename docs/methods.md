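# Methods

`sedigrass` implements a four-stage inference chain linking catchment sediment
loads to the areal extent of light-limited benthic habitat (seagrass) in a
coastal embayment, together with a synthetic-bay generator that makes every
stage testable end to end without external data.

## 1. Sediment loads

Daily total-suspended-solids (TSS) loads per river, in tonnes, are summed
across rivers and aggregated to calendar months.  A *water year* runs
July–June and is labelled by the calendar year of its ending June; the *wet
season* is 1 November – 31 March inclusive, so each wet season sits inside a
single water-year label.  Incomplete water years at the series edges are
excluded from annual statistics.  The wet-season fraction is the mean over
complete water years of (Nov–Mar load)/(July–June load).

Annual loads can be estimated from a wet-season total three ways:

* `paper` (default): annual = 1.24 × wet-season total, the published uplift;
* `consistent`: annual = wet-season / 0.76 (≈1.316 ×), internally consistent
  with a 76% wet-season share — note 1.24 ≠ 1/0.76, an inconsistency in the
  source analysis that both methods expose side by side;
* `exact`: the direct July–June sum.

## 2. Water clarity and benthic light

Secchi depth `Z_SD` (m) is modelled by ordinary least squares on four
predictors with no interactions:

    Z_SD = b0 + bS·S + bz·z + bDO·D_O + bDR·D_R

where `S` is the bay-wide monthly sediment total (one scalar per month),
`z` water depth (m, positive down), and `D_O`, `D_R` the barrier-aware
least-cost over-water distances (m) to the open ocean (the ≥30 m depth
contour, boundary-inclusive) and to the nearest river mouth.  Distances use
8-connected Dijkstra on the water mask with diagonal step cost cell·√2,
matching GIS cost-distance behaviour; they are computed once per grid.
The reference configuration ships the published fit
(0.842, −4.56·10⁻⁶, −0.226, −7.32·10⁻⁶, +8.30·10⁻⁵).

Observations at or below the 0.05 m reporting floor are treated as
left-censored and dropped before fitting.  This keeps zero-noise parameter
recovery exact and avoids attenuation from clamped values; a tobit model
would be the fuller treatment and is out of scope.

Light follows Lambert–Beer: the diffuse attenuation coefficient is
`K_d = λ / Z_SD` with λ = 1.7 (configurable; "approximately 1.7" in the
optics literature, treated as exact), and percent benthic irradiance is
`100·exp(−K_d z)`.  The habitat covariate `L` is the **natural log of the
mean** percent irradiance over the six months *preceding* each prediction
month (mean-then-log, never log-then-mean; window excludes the current month
by default, both switchable).  Partial windows use whatever subset exists
(≥1 month) so predictions can begin one month into the series.  Percent
light is floored at 10⁻⁶ % before the log to keep `L` finite.

### Identifiability note

In any realistic bay geometry `z`, `D_R` and `D_O` grow offshore together,
so their individual OLS coefficients are strongly collinear (the source
analysis cited the same correlation as its reason for excluding
interactions).  At realistic noise the individually identifiable quantities
are the sediment and depth coefficients (sediment varies over time,
independent of space) and the predicted clarity *surface*; the spatial
coefficients trade off within a ridge.  Tests assert exactly this: 10%
point recovery for sediment and depth, 3-standard-error coverage for all
coefficients, <10% relative RMSE of the predicted surface.

## 3. Habitat suitability

Presence of seagrass is a binomial GLM with logit link:

    g = b0 + b_L·L + b_H·H_s + b_HL·(H_s × L),    p = 1/(1+e^{−g})

with `H_s` the 90th-percentile significant wave height (m).  Fitting uses
IRLS (tolerance 10⁻⁸, ≤100 iterations); complete separation and
single-class inputs raise errors.  No spatial-autocorrelation term is
included: the model's purpose is prediction at other times, where such a
term's assumptions fail.  The reference configuration ships the published
coefficients (2.28, 0.375, −7.89, −0.415).  Because of the interaction, the
light effect is positive only below `H_s < b_L/|b_HL|` (≈0.904 m under the
reference fit) and reverses above it; the monotonicity tests assert this
conditional form.

The model is fitted once on a calibration month's presence map and the
frozen coefficients are applied to every other month.  Probability maps are
classified by a threshold selected on the calibration data over the grid
0.00–1.00 in steps of 0.01 (ties to the smallest threshold; scores rounded
at 10⁻¹² so exact rational ties are deterministic) under four criteria:
maximising Cohen's kappa (the headline), maximising percent correctly
classified, equalising sensitivity and specificity, and a fixed default of
0.5.  Kappa uses marginal-product expected agreement,
`κ = (p_o − p_e)/(1 − p_e)`, with constant predictions scoring 0 and perfect
agreement 1.  Suitable-habitat area is the count of water cells with
`p ≥ threshold` times the cell area (1 ha at 100 m cells).

## 4. Sediment–area response

Monthly areas are averaged over each water year's Nov–Mar wet season (the
limiting period) and paired with the annual sediment estimate.  The
response is an OLS fit of area on S and/or S², with candidates
{∅, {S}, {S²}, {S,S²}} compared by BIC = n·ln(RSS/n) + k·ln(n), k counting
the intercept.  The quadratic-only candidate is included because the
published selected model contains S² without a linear term.  The
mean-squared residual is floored at (10⁻⁸·scale(y))² so numerically exact
candidates tie and the parameter penalty resolves the tie toward the
smaller model; candidate design columns are standardised internally for
conditioning and coefficients unscaled afterwards.  The sensitivity
analysis repeats the fit for all four thresholds × two timescales (annual
as above; monthly pairs each month's area with that month's sediment
total), reporting intercept, S, S², F, df and p per row.

## The synthetic bay

The generator fabricates everything the chain consumes, with defaults that
encode the study conditions of a subtropical east-Australian embayment:

* **Grid**: 64 × 160 cells of 100 m; land is an irregular strip along the
  western edge; three river mouths on shoreline-adjacent water cells.
* **Sediment**: 156 months (13 water years) of daily lognormal loads
  (shape σ = 1.0), with month-level expected totals solved so the Nov–Mar
  share equals 0.76 of a 280,000 t typical year; per-month multipliers
  scale water-year 7 by 0.214 (≈60,000 t drought) and water-year 11 by
  3.071 (≈860,000 t flood), matching the published hydrograph's extremes.
* **Secchi observations**: 60 stations fixed across months, uniform over
  water shallower than 3 m (nearshore monitoring); observation =
  truth predictor + Gaussian noise (σ = 0.12 m, chosen so the refitted
  model explains ≈55% of variance, matching the published adjusted
  R² = 0.57), truncated at the 0.05 m floor.
* **Seagrass truth map**: Bernoulli draws from the logistic model applied
  to the bay's *true* (noise-free) light field at the calibration month
  (July of water year 5); the analysis chain then fits on *modelled* light,
  as a practitioner would.
* **Waves**: gentle fetch-limited growth across the banks
  (0.05 + 0.20·u^0.7 m, u = normalised offshore distance) plus a sharp
  oceanic-swell wall (+0.5 m over a 4%-width sigmoid) just seaward of the
  shelf break.
* **Bathymetry**: *accommodating banks*.  Depth on the banks is constructed
  from the typical-wet-month clarity field so that benthic light sits a
  prescribed log-margin above the habitat suitability cutoff: margin 2.5
  at the coast declining quadratically to 0.3 at the shelf break, floored
  at 0.8 m, with ±0.05 m smooth texture; beyond the break a narrow sigmoid
  drops to 35 m, past the 30 m open-ocean contour.  This mirrors how depth
  limits of light-limited vegetation track a bay's clarity gradient.

The margin construction is the load-bearing design choice.  A trailing
mean-then-log light window caps the effective light drop of even an extreme
flood year at roughly −1 to −1.6 log units (clear months in the window
dominate the mean), while a drought year raises light by ≈ +0.6.  The
response of area to load is therefore governed by how many cells sit within
those margins of the cutoff: the quadratic margin profile places a broad
outer band of the banks within flood reach, while the swell wall and the
shelf break leave droughts almost nothing to colonise.  The emergent annual
response is then flat from drought to typical loads and drops steeply into
the flood year — a concave (negative-S²) dose–response, the qualitative
headline of the analysis.  Under naive bathymetries (power-law ramps, flat
plateaus) the same chain yields a linear or convex response because habitat
is either wave-pinned or sits far from the light cutoff; we verified this
during design.

All randomness derives from a single seed through independent named
substreams (bay, sediment, stations, secchi, seagrass), so every artefact is
a pure function of (config, seed).

### What the generator does not emulate

Plume advection, tides and currents (distance is a proxy for exposure);
spatial structure in Secchi noise; seagrass population dynamics (growth,
recruitment, carry-over between months); inter-river correlation of daily
loads; rainfall forcing of the load series.  Passing tests therefore show
that the *inference chain* is correct and that the published qualitative
conclusions emerge under the stated statistical structure — not that the
generator reproduces any real bay's numbers.

## Numerical choices

* Secchi floor 0.05 m; percent-light floor 10⁻⁶ % before logs.
* Threshold grid step 0.01; classification rule `p ≥ threshold`.
* GLM IRLS tolerance 10⁻⁸, max 100 iterations; separation detected by
  non-finite or exploding (>10⁶) coefficients.
* BIC residual floor (10⁻⁸·RMS(y))²; candidate ties resolve to fewer terms.
* Distances: unreachable water is `inf`, land is NaN; river mouths given as
  points are snapped to the nearest water cell within 2 cells, else error.
* Problem sizes in tests and the acceptance script: the default 64 × 160
  bay over 156 months (≈10⁴ water cells), a 200 × 200 grid for GLM
  parameter recovery, 100 random ≤8×8 masks for the distance oracle, and
  100 random vectors for the threshold oracle.  These sizes give the
  statistical power the assertions need while keeping a full run to a few
  seconds.

## Known limitations

* The monthly-timescale response pairs each month's area with the same
  month's load, but area responds to the previous six months' light; the
  lag dilutes the monthly fit, which on some seeds selects the
  intercept-only model for some thresholds.
* The annual concavity is an emergent property with sampling variability:
  on rare seeds one sensitivity row's selected quadratic coefficient is
  weakly positive.
* `λ`, the Secchi–attenuation constant, is water-type dependent; 1.7 is a
  clear-to-moderately-turbid coastal default.
* Left-censoring of floored Secchi observations is handled by exclusion,
  not by a censored-likelihood model.
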