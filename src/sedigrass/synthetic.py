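"""Synthetic bay generator.

Fabricates every input the analysis chain consumes — bathymetry, land/water
mask, wave climate, river mouths, daily per-river sediment series, monthly
station Secchi observations, and a binary seagrass calibration map — with the
statistical structure the downstream models assume:

* Secchi observations follow the linear clarity model plus Gaussian noise,
  truncated at a positive reporting floor.
* Seagrass presence is Bernoulli with probability from the logistic habitat
  model applied to the bay's true (noise-free) light field.
* Daily sediment loads are lognormal with month-specific location parameters
  solved so the expected Nov-Mar share equals the wet-season share; optional
  per-month multipliers superimpose flood and drought years.

Default parameter values emulate the hydrology and monitoring design of a
subtropical east-Australian embayment: 100 m cells, a shoaling shelf reaching
the 30 m open-ocean contour, three rivers, a 76% wet-season sediment share
around a 280,000 t typical year with one drought (~60,000 t) and one major
flood (~860,000 t) water year in thirteen, and shallow-water monitoring
stations observed monthly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from . import reference
from .distance import add_distances, path_distance, snap_to_water
from .grid import BayGrid
from .sediment import SedimentSeries

_STAGES = {"bay": 1, "sediment": 2, "secchi": 3, "stations": 4, "seagrass": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage stream derived from the single top-level seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially smooth Gaussian field."""
    f = gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def default_flood_multipliers(
    n_months: int,
    start: str = "2000-07",
    drought: tuple[int, float] = (7, 0.2143),
    flood: tuple[int, float] = (11, 3.0714),
) -> list[tuple[int, float]]:
    """Per-month multipliers emulating one drought and one major-flood year.

    Water years are counted from the first July-June year of the series; the
    defaults scale the 7th water year to ~60,000 t and the 11th to ~860,000 t
    around a 280,000 t typical year.
    """
    months = pd.period_range(start, periods=n_months, freq="M")
    wy = np.where(months.month >= 7, months.year + 1, months.year)
    first = wy.min()
    out = []
    for year_index, mult in (drought, flood):
        target = first + year_index - 1
        for i in np.nonzero(wy == target)[0]:
            out.append((int(i), float(mult)))
    return out


@dataclass
class BayConfig:
    """Full parameterisation of a synthetic bay and its forcing series."""

    n_rows: int = 64
    n_cols: int = 160
    cell_size: float = 100.0
    depth_max: float = 35.0
    coast_depth: float = 0.8  # minimum water depth at the shoreline
    # The banks bathymetry is constructed so that typical-year benthic light
    # sits a prescribed log-margin above the habitat model's suitability
    # cutoff, declining from margin_inner at the coast to margin_outer at the
    # shelf break.  Depth limits of light-limited vegetation track the
    # clarity gradient in this way in nature: clearer offshore water sits over
    # deeper accommodating banks.
    margin_inner: float = 2.5
    margin_outer: float = 0.3
    design_threshold: float = 0.45  # nominal presence cutoff used for design
    shelf_break_frac: float = 0.75  # where the banks drop to the open shelf
    shelf_break_width: float = 0.04
    ocean_depth_cutoff: float = 30.0
    river_mouths: list[tuple[int, int]] | None = None  # None -> 3 mouths on the shore
    n_rivers: int = 3
    river_shares: tuple[float, ...] = (0.5, 0.3, 0.2)
    n_stations: int = 60
    station_depth_max: float = 3.0  # monitoring happens in nearshore shallows
    n_months: int = 156
    start_month: str = "2000-07"
    seed: int = 0
    secchi_truth: dict = field(default_factory=lambda: dict(reference.SECCHI_REFERENCE))
    sdm_truth: dict = field(default_factory=lambda: dict(reference.HABITAT_REFERENCE))
    secchi_noise_sd: float = 0.12
    secchi_floor: float = reference.SECCHI_FLOOR
    wet_season_share: float = reference.WET_SEASON_SHARE
    mean_annual_load: float = reference.TYPICAL_ANNUAL_LOAD
    daily_sigma: float = 1.0  # lognormal shape of daily loads
    flood_months: list[tuple[int, float]] | None = None  # None -> default pattern
    # wave climate: gentle fetch-limited growth across the sheltered banks,
    # plus a sharp oceanic-swell wall just seaward of the shelf break, so the
    # banks' seaward habitat limit is set by light (hence sediment) inshore of
    # it and by waves beyond it
    hs_base: float = 0.05
    hs_fetch: float = 0.20
    hs_swell: float = 0.50

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_stations, self.n_months) < 1:
            raise ValueError("grid, station and month counts must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0.0 < self.wet_season_share < 1.0:
            raise ValueError("wet_season_share must lie in (0, 1)")
        if self.flood_months is None:
            self.flood_months = default_flood_multipliers(self.n_months, self.start_month)
        if abs(sum(self.river_shares) - 1.0) > 1e-9:
            raise ValueError("river_shares must sum to 1")
        if len(self.river_shares) != self.n_rivers:
            raise ValueError("one share per river is required")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.n_months, freq="M")


def generate_bay(config: BayConfig) -> BayGrid:
    """Deterministic synthetic bay: coastline, waves, bathymetry, distances.

    Land occupies an irregular strip along the western edge, with river
    mouths on water cells adjacent to the shoreline.  Waves grow gently with
    fetch across the sheltered banks and jump at an oceanic-swell wall just
    seaward of the shelf break.  Bank bathymetry is *accommodating*: depth is
    set so typical-year benthic light sits a prescribed log-margin above the
    habitat suitability cutoff (``margin_inner`` at the coast declining to
    ``margin_outer`` at the shelf break), mimicking how depth limits of
    light-limited vegetation track a bay's clarity gradient.  Seaward of the
    break a narrow sigmoid drops past the open-ocean contour.
    """
    rng = _rng(config.seed, "bay")
    n_rows, n_cols = config.n_rows, config.n_cols

    # coastline: land where col < width(row), width varying smoothly alongshore
    profile = gaussian_filter(rng.normal(size=n_rows), sigma=max(2, n_rows // 16),
                              mode="reflect")
    rngw = profile.max() - profile.min()
    profile = (profile - profile.min()) / (rngw if rngw > 0 else 1.0)
    width = np.clip(np.rint(1 + 3 * profile), 1, max(1, n_cols // 8)).astype(int)
    water = np.ones((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        water[r, : width[r]] = False

    dist = distance_transform_edt(water) * config.cell_size
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("grid has no water cells")
    u = dist / dmax

    if config.river_mouths is None:
        rows = [int(round(f * (n_rows - 1))) for f in (0.2, 0.5, 0.8)][: config.n_rivers]
        mouths = [(r, int(width[r])) for r in rows]  # first water cell of the row
    else:
        mouths = [snap_to_water(water, m) for m in config.river_mouths]

    # wave climate: fetch-limited growth over the banks plus an oceanic-swell
    # wall just seaward of the shelf break, with smooth alongshore structure
    hs = config.hs_base + config.hs_fetch * u**0.7
    hs = hs + config.hs_swell / (
        1.0 + np.exp(-(u - (config.shelf_break_frac + 0.10)) / 0.04)
    )
    hs = hs * (1.0 + 0.1 * _smooth_field(rng, water.shape, sigma=4.0))
    hs = np.clip(hs, 0.0, None)

    # clarity field of a typical wet-season month, from the truth model
    # (distance to the open ocean approximated by distance to the shelf
    # break, which is where the real D_O layer will be anchored)
    d_river = path_distance(water, mouths, config.cell_size)
    d_ocean_approx = np.maximum(config.shelf_break_frac + 0.03 - u, 0.0) * dmax
    s_wet = config.mean_annual_load * config.wet_season_share / 5.0
    truth = config.secchi_truth
    clarity = (
        truth["intercept"]
        + truth["sediment"] * s_wet
        + truth["d_river"] * d_river
        + truth["d_ocean"] * d_ocean_approx
    )
    clarity = np.where(np.isfinite(clarity), clarity, 0.0)

    # accommodating bank depth: solve 1.7 z / Z(z) = C for z, where C is the
    # light decay that leaves the prescribed margin above the suitability
    # cutoff of the truth habitat model at the local wave height
    sdm = config.sdm_truth
    gc = np.log(config.design_threshold / (1.0 - config.design_threshold))
    den = sdm["light"] + sdm["waves_x_light"] * hs
    with np.errstate(divide="ignore", invalid="ignore"):
        l_crit = np.where(
            den > 1e-3, (gc - sdm["intercept"] - sdm["waves"] * hs) / den, -np.inf
        )
    # margin declines quadratically toward the break, so a broad outer band
    # of the banks sits within reach of flood-year light reductions while
    # the inner banks stay comfortably suitable
    margin = config.margin_outer + (config.margin_inner - config.margin_outer) * (
        np.clip((config.shelf_break_frac - u) / config.shelf_break_frac, 0.0, 1.0) ** 2
    )
    decay = np.clip(np.log(100.0) - l_crit - margin, 0.5, 12.0)
    lam = reference.LAMBDA
    z_banks = decay * np.maximum(clarity, 0.1) / (lam - truth["depth"] * decay)
    z_banks = np.maximum(z_banks, config.coast_depth)

    shelf_mix = 1.0 / (
        1.0 + np.exp(-(u - config.shelf_break_frac) / config.shelf_break_width)
    )
    depth = z_banks + (config.depth_max - z_banks) * shelf_mix
    depth += 0.05 * _smooth_field(rng, water.shape, sigma=3.0)
    depth = np.clip(depth, 0.05, None)
    # anchor the deepest offshore cell so the configured maximum is attained
    depth[np.unravel_index(np.argmax(dist), dist.shape)] = config.depth_max
    depth[~water] = np.nan
    hs[~water] = np.nan

    if config.depth_max >= config.ocean_depth_cutoff:
        if not np.any(depth[water] >= config.ocean_depth_cutoff):
            raise ValueError("no water cell reaches the open-ocean depth cutoff")
    else:
        raise ValueError(
            "depth_max below ocean_depth_cutoff: no open-ocean source definable"
        )

    grid = BayGrid(
        depth=depth, water_mask=water, hs=hs, cell_size=config.cell_size,
        river_mouths=mouths,
    )
    return add_distances(grid, ocean_cutoff=config.ocean_depth_cutoff)


def generate_sediment_series(config: BayConfig) -> SedimentSeries:
    """Daily lognormal per-river TSS loads with seasonal and flood structure.

    Each wet month (Nov-Mar) carries an expected share ``wet_season_share/5``
    of the typical annual load and each dry month ``(1-share)/7``; month
    multipliers from ``flood_months`` scale individual months.  Daily draws
    are lognormal with the location parameter solved so the daily mean matches
    the month's expected total.
    """
    if config.n_months < 12:
        raise ValueError("need at least 12 months of sediment forcing")
    rng = _rng(config.seed, "sediment")
    months = config.months
    mult = np.ones(config.n_months)
    for idx, m in config.flood_months:
        if 0 <= idx < config.n_months:
            mult[idx] *= m
    wet = np.isin(months.month, (11, 12, 1, 2, 3))
    share = np.where(wet, config.wet_season_share / 5.0,
                     (1.0 - config.wet_season_share) / 7.0)
    month_totals = config.mean_annual_load * share * mult

    sigma = config.daily_sigma
    frames = []
    for j, (period, total) in enumerate(zip(months, month_totals)):
        n_days = period.days_in_month
        dates = pd.date_range(period.to_timestamp(), periods=n_days, freq="D")
        for river_i, river_share in enumerate(config.river_shares):
            mean_daily = total * river_share / n_days
            mu = np.log(mean_daily) - sigma**2 / 2.0
            draws = np.exp(mu + sigma * rng.standard_normal(n_days))
            frames.append(
                pd.DataFrame(
                    {"date": dates, "river": f"river_{river_i + 1}", "tss_tonnes": draws}
                )
            )
    return SedimentSeries(pd.concat(frames, ignore_index=True))


def sample_stations(grid: BayGrid, config: BayConfig) -> pd.DataFrame:
    """Fixed station locations, uniform over shallow water cells."""
    rng = _rng(config.seed, "stations")
    eligible = grid.water_mask & (grid.depth <= config.station_depth_max)
    rr, cc = np.nonzero(eligible)
    if rr.size == 0:
        raise ValueError("no water cells shallow enough to host stations")
    replace = rr.size < config.n_stations
    pick = rng.choice(rr.size, size=config.n_stations, replace=replace)
    return pd.DataFrame(
        {"station_id": [f"st{i:03d}" for i in range(config.n_stations)],
         "row": rr[pick], "col": cc[pick]}
    )


def secchi_truth_raster(grid: BayGrid, s_month: float, truth: dict,
                        floor: float = reference.SECCHI_FLOOR) -> np.ndarray:
    """Noise-free Secchi raster from truth coefficients (floored, land NaN)."""
    grid.require_distances()
    pred = (
        truth["intercept"]
        + truth["sediment"] * s_month
        + truth["depth"] * grid.depth
        + truth["d_ocean"] * grid.d_ocean
        + truth["d_river"] * grid.d_river
    )
    out = np.maximum(pred, floor)
    out[~grid.water_mask] = np.nan
    return out


def generate_secchi_obs(
    grid: BayGrid,
    sediment: SedimentSeries,
    truth: dict,
    config: BayConfig,
    stations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Monthly station Secchi observations: truth predictor + Gaussian noise.

    Station locations are fixed across months.  Observations are truncated
    below at the reporting floor, as a field observer would record them.
    """
    if not grid.water_mask.any():
        raise ValueError("grid has no water cells")
    if stations is None:
        stations = sample_stations(grid, config)
    rng = _rng(config.seed, "secchi")
    monthly = sediment.monthly_totals()
    frames = []
    r = stations["row"].to_numpy()
    c = stations["col"].to_numpy()
    base = (
        truth["intercept"]
        + truth["depth"] * grid.depth[r, c]
        + truth["d_ocean"] * grid.d_ocean[r, c]
        + truth["d_river"] * grid.d_river[r, c]
    )
    for period, s in monthly.items():
        pred = base + truth["sediment"] * float(s)
        noise = (
            rng.normal(0.0, config.secchi_noise_sd, size=len(stations))
            if config.secchi_noise_sd > 0
            else 0.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "station_id": stations["station_id"],
                    "row": r,
                    "col": c,
                    "month": period,
                    "secchi_m": np.maximum(pred + noise, config.secchi_floor),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_seagrass_map(
    light: np.ndarray, hs: np.ndarray, truth: dict, seed: int
) -> np.ndarray:
    """Bernoulli presence map from the logistic habitat model.

    ``light`` is the L raster (log mean percent irradiance) for the mapping
    month; cells where either raster is NaN (land) return NaN.
    """
    light = np.asarray(light, dtype=float)
    hs = np.asarray(hs, dtype=float)
    if light.shape != hs.shape:
        raise ValueError("light and wave rasters must share one shape")
    rng = _rng(seed, "seagrass")
    g = (
        truth["intercept"]
        + truth["light"] * light
        + truth["waves"] * hs
        + truth["waves_x_light"] * hs * light
    )
    p = 1.0 / (1.0 + np.exp(-g))
    out = np.full(light.shape, np.nan)
    valid = np.isfinite(p)
    out[valid] = (rng.random(valid.sum()) < p[valid]).astype(float)
    return out
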