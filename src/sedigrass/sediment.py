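"""Daily river sediment loads and their monthly / seasonal / annual aggregates.

Conventions
-----------
* Loads are total suspended solids (TSS) in tonnes.
* The wet season is 1 November - 31 March inclusive.
* A water year runs July-June and is labelled by the calendar year of its
  ending June, so the Nov-Mar wet season sits inside a single label.
* Partial water years at the edges of a series are excluded from annual
  statistics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ANNUAL_UPLIFT, WET_SEASON_SHARE

WET_MONTHS = (11, 12, 1, 2, 3)


def water_year(months: pd.PeriodIndex | pd.Series) -> np.ndarray:
    """July-June water-year label for monthly periods (year of the ending June)."""
    if isinstance(months, pd.Series):
        months = pd.PeriodIndex(months)
    return np.where(months.month >= 7, months.year + 1, months.year)


class SedimentSeries:
    """Validated daily TSS series for one or more rivers.

    Parameters
    ----------
    daily : DataFrame with columns ``date`` (datetime-like, daily),
        ``river`` (str) and ``tss_tonnes`` (non-negative float).
    """

    def __init__(self, daily: pd.DataFrame):
        daily = daily.copy()
        required = {"date", "river", "tss_tonnes"}
        missing = required - set(daily.columns)
        if missing:
            raise ValueError(f"daily table missing columns: {sorted(missing)}")
        daily["date"] = pd.to_datetime(daily["date"])
        neg = daily.index[daily["tss_tonnes"] < 0]
        if len(neg):
            raise ValueError(f"negative TSS load at row(s) {list(neg[:5])}")
        # every river must cover every date in the overall span, with no gaps
        full = pd.date_range(daily["date"].min(), daily["date"].max(), freq="D")
        for river, sub in daily.groupby("river"):
            have = pd.DatetimeIndex(sub["date"].unique())
            gaps = full.difference(have)
            if len(gaps):
                head = ", ".join(str(d.date()) for d in gaps[:5])
                raise ValueError(
                    f"river {river!r} has {len(gaps)} missing date(s), e.g. {head}"
                )
        self.daily = daily.sort_values(["date", "river"]).reset_index(drop=True)

    # -- aggregation ------------------------------------------------------

    def monthly_totals(self) -> pd.Series:
        """Bay-wide monthly totals (tonnes): summed across rivers and days."""
        month = self.daily["date"].dt.to_period("M")
        return self.daily.groupby(month)["tss_tonnes"].sum().rename("tonnes")

    def monthly_by_river(self) -> pd.DataFrame:
        month = self.daily["date"].dt.to_period("M")
        return self.daily.groupby([month, "river"])["tss_tonnes"].sum().unstack()

    def complete_water_years(self) -> np.ndarray:
        """Water-year labels whose 12 months are fully inside the series span."""
        monthly = self.monthly_totals()
        wy = water_year(monthly.index)
        counts = pd.Series(1, index=monthly.index).groupby(wy).sum()
        return counts.index[counts == 12].to_numpy()

    def annual_totals(self, convention: str = "water") -> pd.Series:
        """Annual totals (tonnes) over complete years.

        convention "water" groups July-June (labelled by ending June);
        "calendar" groups January-December.
        """
        monthly = self.monthly_totals()
        if convention == "water":
            labels = water_year(monthly.index)
            keep = self.complete_water_years()
        elif convention == "calendar":
            labels = monthly.index.year
            counts = pd.Series(1, index=monthly.index).groupby(labels).sum()
            keep = counts.index[counts == 12].to_numpy()
        else:
            raise ValueError(f"unknown year convention {convention!r}")
        totals = monthly.groupby(labels).sum()
        return totals.loc[totals.index.isin(keep)].rename("tonnes")

    def wet_season_totals(self) -> pd.Series:
        """Nov-Mar totals (tonnes) per complete water year."""
        monthly = self.monthly_totals()
        wet = monthly[monthly.index.month.isin(WET_MONTHS)]
        totals = wet.groupby(water_year(wet.index)).sum()
        keep = self.complete_water_years()
        return totals.loc[totals.index.isin(keep)].rename("tonnes")

    def wet_season_fraction(self) -> float:
        """Mean over complete water years of (Nov-Mar load) / (July-June load)."""
        annual = self.annual_totals("water")
        if len(annual) == 0:
            raise ValueError("no complete July-June water year in the series")
        wet = self.wet_season_totals()
        return float((wet / annual).mean())


def read_daily_tss(path: str | Path) -> SedimentSeries:
    """Read a daily per-river TSS file (CSV or XLSX; long or wide layout).

    Long layout: columns ``date, river, tss_tonnes``.  Wide layout: a ``date``
    column plus one load column per river.  Negative loads and date gaps are
    rejected with an error naming the offending rows.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "date" not in cols:
        raise ValueError("input file must contain a 'date' column")
    if "river" in cols and ("tss_tonnes" in cols or "tss" in cols):
        load = cols.get("tss_tonnes", cols.get("tss"))
        frame = frame.rename(
            columns={cols["date"]: "date", cols["river"]: "river", load: "tss_tonnes"}
        )
        daily = frame[["date", "river", "tss_tonnes"]]
    else:  # wide: every non-date column is a river
        rivers = [c for c in frame.columns if c != cols["date"]]
        if not rivers:
            raise ValueError("no river load columns found")
        daily = frame.melt(
            id_vars=[cols["date"]], value_vars=rivers,
            var_name="river", value_name="tss_tonnes",
        ).rename(columns={cols["date"]: "date"})
    return SedimentSeries(daily)


def annual_sediment_estimate(
    wet_total: float, method: str = "paper", wet_share: float = WET_SEASON_SHARE
) -> float:
    """Annual sediment load (tonnes) estimated from a wet-season total.

    method "paper"      : wet_total * 1.24 (the published uplift, as printed);
    method "consistent" : wet_total / wet_share (internally consistent with a
                          76% wet-season share; 1/0.76 > 1.24);
    method "exact"      : the wet_total is already a full July-June sum and is
                          returned unchanged (use with direct annual totals).
    """
    if wet_total < 0:
        raise ValueError("wet-season total must be non-negative")
    if method == "paper":
        return ANNUAL_UPLIFT * wet_total
    if method == "consistent":
        return wet_total / wet_share
    if method == "exact":
        return float(wet_total)
    raise ValueError(f"unknown annual-estimate method {method!r}")
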