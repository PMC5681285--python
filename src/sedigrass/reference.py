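"""Reference model configuration from the published Moreton Bay study.

These coefficients were fitted to real monitoring data (Secchi-depth stations,
a satellite seagrass map, and catchment-model sediment loads) and are shipped
as a reference configuration: they parameterise the synthetic-bay generator's
ground truth and provide a realistic starting point for users without their
own calibration data.  They are *not* recomputable from package internals.
"""

from __future__ import annotations

#: Conversion between Secchi depth and the diffuse attenuation coefficient,
#: K_d = LAMBDA / Z_SD (dimensionless; "approximately 1.7" in the literature).
LAMBDA = 1.7

#: Reporting floor for Secchi depth (m); observations cannot be <= 0.
SECCHI_FLOOR = 0.05

#: Floor applied to percent benthic light before taking logarithms.
PCT_LIGHT_FLOOR = 1e-6

#: Secchi-depth linear model, Z_SD (m) as a function of monthly bay-wide
#: sediment load S (tonnes), water depth z (m), distance to open ocean D_O (m)
#: and distance to the nearest river mouth D_R (m):
#:   Z_SD = 0.842 - 4.56e-6 S - 0.226 z - 7.32e-6 D_O + 8.30e-5 D_R
SECCHI_REFERENCE = {
    "intercept": 0.842,
    "sediment": -4.56e-6,
    "depth": -0.226,
    "d_ocean": -7.32e-6,
    "d_river": 8.30e-5,
}

#: Habitat-suitability logistic model: linear predictor
#:   g(x) = 2.28 + 0.375 L - 7.89 Hs - 0.415 (Hs x L)
#: where L is the natural log of mean percent benthic irradiance over the six
#: months preceding the mapping date and Hs is the 90th-percentile significant
#: wave height (m).  Probability of presence p = logistic(g).
HABITAT_REFERENCE = {
    "intercept": 2.28,
    "light": 0.375,
    "waves": -7.89,
    "waves_x_light": -0.415,
}

#: Presence/absence classification thresholds selected on the calibration map
#: under four criteria (properties of the original fit, not recomputable here).
THRESHOLDS_REFERENCE = {
    "sens_spec": 0.11,
    "kappa": 0.22,
    "maxPC": 0.44,
    "default": 0.50,
}

#: Annual sediment -> wet-season habitat-area response (hectares):
#:   A = 2.36e4 - 5.66e-9 S^2,  S in tonnes per July-June water year.
RESPONSE_REFERENCE = {
    "intercept": 2.36e4,
    "sediment": 0.0,
    "sediment2": -5.66e-9,
}

#: Fraction of the annual sediment load delivered in the Nov-Mar wet season.
WET_SEASON_SHARE = 0.76

#: Multiplier used to scale a wet-season load up to an annual estimate
#: ("24% more than the sediment load in the wet season").
ANNUAL_UPLIFT = 1.24

#: Typical-year total sediment load to the bay (tonnes per year).
TYPICAL_ANNUAL_LOAD = 280_000.0
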